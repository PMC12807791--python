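"""Splitting connected spheres and measuring their maximum cross-sections.

At ~20% volume fraction, neighbouring spheres frequently touch in the
binary mask m1.  They are separated by a seeded watershed on the negated
Euclidean distance transform: seeds are local maxima of the distance map
(pairwise separation >= 5 voxels), so each basin corresponds to one sphere
core.  Each label's per-frame area profile is then scanned along the
elevational axis for its maximum cross-section — the frame closest to the
sphere's true equator, which freehand asymmetry can displace from the mass
centroid — and an area band around the ideal equatorial disk area
pi*d^2/4 rejects both unsplit clumps and fragments.

All distances here are in voxel units: the physical elevational spacing of
a freehand sweep is unknown, and the 5-pixel seed rule is defined on the
grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .config import SphereConfig
from .errors import ConfigurationError
from .volume import CineVolume


@dataclass
class SphereMeasurement:
    """One segmented sphere candidate.

    In-plane centre (xi, yi) is in pixels of the maximum cross-section
    frame ``zi``; ``depth_cm`` is the physical depth of yi.  Intensity
    fields (Sf, Sb, sigma_b, lsnr) are filled by the metrics stage.
    """

    label: int
    zi: int
    si_px: int
    si_mm2: float
    xi: float  # lateral, pixels
    yi: float  # depth row, pixels
    depth_cm: float = float("nan")
    touches_edge: bool = False
    area_ok: bool = False
    eligible: bool = False
    Sf: float | None = None
    Sb: float | None = None
    sigma_b: float | None = None
    lsnr: float | None = None
    dropped_reason: str | None = None


def _distance_map(m1: np.ndarray) -> np.ndarray:
    """Per-frame 2D Euclidean distance transform, stacked along elevation.

    The distance to the nearest background pixel is computed within each
    frame, where the pixel unit is well defined; a sphere's map peaks at
    its equatorial frame centre.  A volumetric EDT that treated frame
    units as pixels would saturate at the mask's elevational half-extent
    (a few frames at typical freehand spacings), flattening the in-plane
    neck valleys between touching spheres that the watershed needs.
    """
    out = np.empty(m1.shape, dtype=np.float64)
    for f in range(m1.shape[2]):
        out[:, :, f] = ndi.distance_transform_edt(m1[:, :, f])
    return out


def _find_seeds(distance: np.ndarray, mask: np.ndarray, min_seed_distance: int) -> np.ndarray:
    """Marker image of watershed seeds.

    Candidates are the local maxima of the distance map (26-neighbourhood;
    a connected equal-valued plateau counts as a single candidate at its
    centroid).  Greedy suppression, strongest peak first, then enforces a
    pairwise separation >= ``min_seed_distance`` voxels.
    """
    local_max = (distance == ndi.maximum_filter(distance, size=3)) & mask
    plateaus, n = ndi.label(local_max, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return np.zeros(distance.shape, dtype=np.int32)
    centroids = np.array(ndi.center_of_mass(local_max, plateaus, np.arange(1, n + 1)))
    peak_vals = ndi.maximum(distance, plateaus, np.arange(1, n + 1))

    order = np.argsort(-peak_vals, kind="stable")
    kept: list[np.ndarray] = []
    for i in order:
        c = centroids[i]
        if kept:
            tree = cKDTree(np.array(kept))
            if tree.query(c, k=1)[0] < min_seed_distance:
                continue
        kept.append(c)

    markers = np.zeros(distance.shape, dtype=np.int32)
    for lbl, c in enumerate(kept, start=1):
        idx = tuple(np.clip(np.round(c).astype(int), 0, np.array(distance.shape) - 1))
        markers[idx] = lbl
    return markers


def split_connected(m1: np.ndarray, min_seed_distance: int = 5) -> np.ndarray:
    """Relabel m1 into per-sphere labels via seeded watershed (m2).

    The watershed floods the negated distance transform from the seeds,
    restricted to m1 with 6-connectivity, so the foreground support is
    preserved exactly and only the labelling changes.  Labels are
    contiguous 1..L; an empty mask yields an all-zero map.
    """
    from skimage.segmentation import watershed

    m1 = np.asarray(m1, dtype=bool)
    if not m1.any():
        return np.zeros(m1.shape, dtype=np.int32)
    distance = _distance_map(m1)
    markers = _find_seeds(distance, m1, min_seed_distance)
    if markers.max() == 0:  # pathological: no seed survived; one basin
        markers[np.unravel_index(np.argmax(distance), distance.shape)] = 1
    m2 = watershed(-distance, markers, mask=m1, connectivity=1).astype(np.int32)

    # watershed can only miss voxels in components without a seed; attach them
    missing = m1 & (m2 == 0)
    if missing.any():
        comps, nc = ndi.label(missing, structure=ndi.generate_binary_structure(3, 1))
        nxt = int(m2.max())
        for i in range(1, nc + 1):
            nxt += 1
            m2[comps == i] = nxt
    return _relabel_contiguous(m2)


def _relabel_contiguous(m2: np.ndarray) -> np.ndarray:
    labels = np.unique(m2)
    labels = labels[labels > 0]
    lut = np.zeros(int(m2.max()) + 1, dtype=np.int32)
    lut[labels] = np.arange(1, labels.size + 1, dtype=np.int32)
    return lut[m2]


def max_cross_section(m2: np.ndarray, label: int) -> tuple[int, int, np.ndarray]:
    """(zi, si_px, in-plane mask) of the label's largest elevational slice.

    zi is the frame index maximizing the per-frame pixel count (ties break
    toward the lower index — np.argmax's first-maximum rule).
    """
    lab = m2 == label
    per_frame = lab.sum(axis=(0, 1))
    zi = int(np.argmax(per_frame))
    return zi, int(per_frame[zi]), lab[:, :, zi]


def area_band_mm2(d_mm: float, alpha1: float = 0.5, alpha2: float = 1.25) -> tuple[float, float]:
    """Inclusive [lo, hi] cross-section area band around pi*d^2/4."""
    if d_mm <= 0:
        raise ConfigurationError("sphere diameter must be positive")
    ideal = math.pi * d_mm**2 / 4.0
    return alpha1 * ideal, alpha2 * ideal


def area_filter(
    spheres: list[SphereMeasurement],
    d_mm: float,
    alpha1: float = 0.5,
    alpha2: float = 1.25,
) -> list[SphereMeasurement]:
    """Flag spheres whose maximum cross-section lies in the area band.

    Bounds are inclusive.  Undersized fragments (over-split) and oversized
    clumps (unsplit connected spheres) are rejected.
    """
    lo, hi = area_band_mm2(d_mm, alpha1, alpha2)
    for s in spheres:
        s.area_ok = lo <= s.si_mm2 <= hi
    return [s for s in spheres if s.area_ok]


def measure_spheres(
    m2: np.ndarray, volume: CineVolume, cfg: SphereConfig | None = None
) -> list[SphereMeasurement]:
    """Measure every label of m2 and set eligibility flags.

    A sphere is eligible when its maximum cross-section area is inside the
    band of ``area_filter`` and (by default) it does not touch the first or
    last elevational frame, where the true maximum cross-section may lie
    outside the acquired stack.
    """
    cfg = cfg or SphereConfig()
    cfg.validate()
    pixel_area = volume.axial_spacing * volume.lateral_spacing
    lo, hi = area_band_mm2(cfg.diameter_mm, cfg.alpha1, cfg.alpha2)
    n_frames = m2.shape[2]

    spheres: list[SphereMeasurement] = []
    objs = ndi.find_objects(m2)
    for label, sl in enumerate(objs, start=1):
        if sl is None:
            continue
        sub = m2[sl] == label
        per_frame = sub.sum(axis=(0, 1))
        zi_local = int(np.argmax(per_frame))
        si_px = int(per_frame[zi_local])
        rows, cols = np.nonzero(sub[:, :, zi_local])
        yi = float(rows.mean()) + sl[0].start
        xi = float(cols.mean()) + sl[1].start
        zi = zi_local + sl[2].start
        touches = sl[2].start == 0 or sl[2].stop == n_frames
        si_mm2 = si_px * pixel_area
        s = SphereMeasurement(
            label=label,
            zi=zi,
            si_px=si_px,
            si_mm2=si_mm2,
            xi=xi,
            yi=yi,
            depth_cm=float(volume.row_depth_mm(yi)) / 10.0,
            touches_edge=touches,
            area_ok=lo <= si_mm2 <= hi,
        )
        s.eligible = s.area_ok and not (touches and cfg.exclude_edge_spheres)
        if not s.area_ok:
            s.dropped_reason = "area outside band"
        elif not s.eligible:
            s.dropped_reason = "touches elevational boundary"
        spheres.append(s)
    return spheres
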