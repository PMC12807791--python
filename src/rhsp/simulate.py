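"""Synthetic freehand cine acquisitions of a random hypoechoic sphere phantom.

The simulator works in the image (display) domain rather than simulating
RF physics: the analysis pipeline consumes display-domain B-mode frames,
and the behaviours under test — depth-adaptive thresholding, watershed
splitting, LSNR statistics, freehand asymmetry — depend only on
image-domain statistics.  Each frame is built as

1. a scattering-amplitude map: background 1.0, reduced inside any sphere
   intersected by the slice (amplitude ratio 10^(contrast_db/20), weighted
   by the fraction of the slice thickness the sphere occupies);
2. two-way depth attenuation 10^(-2 * slope * f * depth_cm / 20);
3. multiplicative Rayleigh speckle blurred by an anisotropic in-plane PSF
   (axial sigma < lateral sigma);
4. additive Gaussian electronic noise of constant SD, so deep-region SNR
   falls;
5. log compression to 8 bits over a configurable displayed dynamic range.

Frame elevational positions follow a freehand profile: uniform steps
perturbed by a fractional jitter and renormalized to the requested
coverage.  The ground truth (sphere centres/radii, frame positions) is
returned so recovery against the known phantom can be tested end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InputError
from .separation import SphereMeasurement
from .volume import CineVolume

_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


@dataclass
class PhantomSpec:
    """Physical phantom description.

    Defaults describe a block of tissue-mimicking material (attenuation
    0.5 dB/cm/MHz) containing 2 mm spheres of -40 dB relative backscatter
    at ~48 spheres/mL, i.e. a 20% volume fraction.
    """

    sphere_diameter_mm: float = 2.0
    volume_fraction: float = 0.20
    density_per_ml: float = 48.0
    contrast_db: float = -40.0
    attenuation_db_cm_mhz: float = 0.5
    frequency_mhz: float = 15.0
    phantom_size_cm: tuple[float, float, float] = (10.0, 5.0, 7.0)  # depth, width, length

    def validate(self) -> "PhantomSpec":
        if self.contrast_db >= 0:
            raise ConfigurationError("spheres must be hypoechoic (contrast_db < 0)")
        if self.sphere_diameter_mm <= 0 or any(s <= 0 for s in self.phantom_size_cm):
            raise ConfigurationError("phantom dimensions must be positive")
        if not 0 <= self.volume_fraction < 1:
            raise ConfigurationError("volume fraction must be in [0, 1)")
        return self

    @property
    def sphere_volume_ml(self) -> float:
        return (math.pi / 6.0) * self.sphere_diameter_mm**3 / 1000.0


@dataclass
class ScanProfile:
    """Freehand sweep description.

    ``speed_jitter`` is the fractional SD of the per-step elevational
    spacing (0 = perfectly uniform mechanical translation); positions are
    renormalized so the sweep always spans ``coverage_cm`` exactly.
    """

    n_frames: int = 62
    duration_s: float = 4.13
    coverage_cm: float = 6.0
    speed_jitter: float = 0.0
    slice_thickness_mm: float = 1.0
    seed: int = 0

    def validate(self) -> "ScanProfile":
        if self.n_frames < 3:
            raise InputError("need at least 3 frames")
        if self.coverage_cm <= 0:
            raise InputError("coverage must be positive")
        if self.speed_jitter < 0:
            raise ConfigurationError("speed_jitter must be >= 0")
        return self


@dataclass
class ImageGeometry:
    """Rendering geometry and image-chain constants."""

    axial_spacing_mm: float = 0.14
    lateral_spacing_mm: float = 0.14
    depth_cm: float | None = None  # default: phantom depth
    width_cm: float | None = None  # default: phantom width
    psf_axial_sigma_px: float = 0.5
    psf_lateral_sigma_px: float = 1.0
    noise_sd: float = 1e-4  # electronic noise, units of surface background amplitude
    dynamic_range_db: float = 63.0
    tgc: bool = False  # exact inverse-attenuation gain curve


@dataclass
class PhantomTruth:
    """Ground truth of one simulated phantom/acquisition.

    Centres are (depth, lateral, elevational) in mm within the phantom;
    ``frame_positions_mm`` is filled at render time.
    """

    centers_mm: np.ndarray
    radii_mm: np.ndarray
    phantom_size_mm: tuple[float, float, float]
    contrast_db: float
    achieved_fraction: float
    seed: int
    frame_positions_mm: np.ndarray | None = None
    background_amplitude: float = 1.0

    def to_json(self, path: str | Path) -> None:
        d = {
            "centers_mm": np.asarray(self.centers_mm).tolist(),
            "radii_mm": np.asarray(self.radii_mm).tolist(),
            "phantom_size_mm": list(self.phantom_size_mm),
            "contrast_db": self.contrast_db,
            "achieved_fraction": self.achieved_fraction,
            "seed": self.seed,
            "frame_positions_mm": (
                None if self.frame_positions_mm is None
                else np.asarray(self.frame_positions_mm).tolist()
            ),
            "background_amplitude": self.background_amplitude,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            centers_mm=np.asarray(d["centers_mm"], dtype=float).reshape(-1, 3),
            radii_mm=np.asarray(d["radii_mm"], dtype=float),
            phantom_size_mm=tuple(d["phantom_size_mm"]),
            contrast_db=d["contrast_db"],
            achieved_fraction=d["achieved_fraction"],
            seed=d["seed"],
            frame_positions_mm=(
                None if d["frame_positions_mm"] is None
                else np.asarray(d["frame_positions_mm"], dtype=float)
            ),
            background_amplitude=d.get("background_amplitude", 1.0),
        )


def place_spheres(
    spec: PhantomSpec,
    seed: int = 0,
    min_separation_mm: float | None = None,
    max_attempts_per_sphere: int = 200,
) -> PhantomTruth:
    """Dart-throw sphere centres uniformly into the phantom block.

    By default the minimum centre separation equals the sphere diameter:
    the phantom contains *solid* spheres, which can touch (and then appear
    connected in the image — the case the watershed stage must handle) but
    cannot interpenetrate.  Pass ``min_separation_mm=0`` to allow overlap.
    Placement stops when the target volume fraction is reached (number of
    spheres = fraction * volume / sphere volume).
    """
    spec.validate()
    if min_separation_mm is None:
        min_separation_mm = spec.sphere_diameter_mm
    if spec.volume_fraction > 0.35 and min_separation_mm > 0:
        raise ConfigurationError(
            "volume fraction > 0.35 with a separation constraint is not packable"
        )
    size_mm = tuple(10.0 * s for s in spec.phantom_size_cm)
    vol_ml = size_mm[0] * size_mm[1] * size_mm[2] / 1000.0
    n = int(round(spec.volume_fraction * vol_ml / spec.sphere_volume_ml))
    rng = np.random.default_rng(seed)

    if min_separation_mm <= 0:
        centers = rng.uniform(0, 1, size=(n, 3)) * np.asarray(size_mm)
    else:
        centers_list: list[np.ndarray] = []
        attempts = 0
        while len(centers_list) < n:
            if attempts > max_attempts_per_sphere * max(n, 1):
                raise ConfigurationError("sphere packing failed: too many rejections")
            c = rng.uniform(0, 1, size=3) * np.asarray(size_mm)
            attempts += 1
            if centers_list:
                tree = cKDTree(np.array(centers_list))
                if tree.query(c, k=1)[0] < min_separation_mm:
                    continue
            centers_list.append(c)
        centers = np.array(centers_list) if centers_list else np.empty((0, 3))

    radii = np.full(n, spec.sphere_diameter_mm / 2.0)
    achieved = n * spec.sphere_volume_ml / vol_ml if vol_ml > 0 else 0.0
    return PhantomTruth(
        centers_mm=centers.reshape(-1, 3),
        radii_mm=radii,
        phantom_size_mm=size_mm,
        contrast_db=spec.contrast_db,
        achieved_fraction=achieved,
        seed=seed,
    )


def frame_positions(profile: ScanProfile, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing elevational positions (mm) spanning the coverage."""
    n = profile.n_frames
    steps = np.ones(n - 1)
    if profile.speed_jitter > 0:
        steps += profile.speed_jitter * rng.standard_normal(n - 1)
        steps = np.clip(steps, 0.05, None)
    pos = np.concatenate([[0.0], np.cumsum(steps)])
    return pos / pos[-1] * profile.coverage_cm * 10.0


def render_acquisition(
    truth: PhantomTruth,
    profile: ScanProfile,
    geometry: ImageGeometry | None = None,
    spec: PhantomSpec | None = None,
) -> tuple[CineVolume, PhantomTruth]:
    """Render a cine loop of B-mode frames of the phantom.

    Returns the 8-bit volume (rows, cols, frames) and the truth with
    ``frame_positions_mm`` filled in.  All randomness (frame jitter,
    speckle, noise) derives from ``profile.seed``.
    """
    profile.validate()
    geo = geometry or ImageGeometry()
    spec = (spec or PhantomSpec()).validate()
    depth_cm = geo.depth_cm if geo.depth_cm is not None else truth.phantom_size_mm[0] / 10.0
    width_cm = geo.width_cm if geo.width_cm is not None else truth.phantom_size_mm[1] / 10.0
    n_rows = int(round(depth_cm * 10.0 / geo.axial_spacing_mm))
    n_cols = int(round(width_cm * 10.0 / geo.lateral_spacing_mm))

    rng = np.random.default_rng(profile.seed)
    z_frames = frame_positions(profile, rng)
    truth.frame_positions_mm = z_frames

    c_amp = 10.0 ** (truth.contrast_db / 20.0)
    t = profile.slice_thickness_mm
    depth_mm = (np.arange(n_rows) + 0.5) * geo.axial_spacing_mm
    lat_mm = (np.arange(n_cols) + 0.5) * geo.lateral_spacing_mm
    att = 10.0 ** (
        -2.0 * spec.attenuation_db_cm_mhz * spec.frequency_mhz * (depth_mm / 10.0) / 20.0
    )

    centers = truth.centers_mm
    radii = truth.radii_mm
    vol = np.empty((n_rows, n_cols, profile.n_frames), dtype=np.float64)
    for f, zf in enumerate(z_frames):
        factor = np.ones((n_rows, n_cols))
        if len(centers):
            near = np.abs(centers[:, 2] - zf) < radii + t / 2.0
            for (cy, cx, cz), r in zip(centers[near], radii[near]):
                r0 = max(0, int((cy - r) / geo.axial_spacing_mm) - 1)
                r1 = min(n_rows, int((cy + r) / geo.axial_spacing_mm) + 2)
                c0 = max(0, int((cx - r) / geo.lateral_spacing_mm) - 1)
                c1 = min(n_cols, int((cx + r) / geo.lateral_spacing_mm) + 2)
                if r0 >= r1 or c0 >= c1:
                    continue
                rho2 = (depth_mm[r0:r1, None] - cy) ** 2 + (lat_mm[None, c0:c1] - cx) ** 2
                h = np.sqrt(np.clip(r**2 - rho2, 0.0, None))
                # slice-thickness overlap with the sphere's elevational chord
                overlap = np.minimum(cz + h, zf + t / 2.0) - np.maximum(cz - h, zf - t / 2.0)
                w = np.clip(overlap, 0.0, None) / t
                factor[r0:r1, c0:c1] = np.minimum(
                    factor[r0:r1, c0:c1], 1.0 - w * (1.0 - c_amp)
                )
        amp = truth.background_amplitude * factor * att[:, None]
        speckle = rng.rayleigh(scale=1.0, size=(n_rows, n_cols)) / _RAYLEIGH_MEAN
        frame = ndi.gaussian_filter(
            amp * speckle, sigma=(geo.psf_axial_sigma_px, geo.psf_lateral_sigma_px)
        )
        frame = frame + rng.normal(0.0, geo.noise_sd, size=(n_rows, n_cols))
        if geo.tgc:
            frame = frame / att[:, None]
        vol[:, :, f] = np.abs(frame)

    ref = np.percentile(vol, 99.9)
    tiny = np.finfo(float).tiny
    y = 255.0 * (1.0 + (20.0 / geo.dynamic_range_db) * np.log10(np.maximum(vol, tiny) / ref))
    y = np.clip(np.round(y), 0, 255).astype(np.uint8)

    volume = CineVolume(
        voxels=y,
        axial_spacing=geo.axial_spacing_mm,
        lateral_spacing=geo.lateral_spacing_mm,
        depth_offset=0.0,
        frame_rate=profile.n_frames / profile.duration_s,
        acquisition_id=f"sim-seed{profile.seed}",
    )
    return volume, truth


def simulate_scan(
    spec: PhantomSpec | None = None,
    profile: ScanProfile | None = None,
    geometry: ImageGeometry | None = None,
    seed: int = 0,
) -> tuple[CineVolume, PhantomTruth]:
    """Place spheres and render one acquisition (single-seed convenience)."""
    spec = spec or PhantomSpec()
    profile = profile or ScanProfile()
    profile.seed = seed
    truth = place_spheres(spec, seed=seed)
    return render_acquisition(truth, profile, geometry, spec)


def detectable_spheres(
    truth: PhantomTruth,
    analyzed_volume: CineVolume,
) -> np.ndarray:
    """Boolean mask of truth spheres whose full extent lies inside the
    analyzed volume (in depth, lateral and elevational coverage).

    Spheres clipped by the depth trim, the lateral frame edge or the sweep
    boundaries cannot present their true maximum cross-section and are not
    counted against recall.
    """
    if truth.frame_positions_mm is None:
        raise InputError("truth has no frame positions; render first")
    c, r = truth.centers_mm, truth.radii_mm
    d0 = analyzed_volume.depth_offset
    d1 = d0 + analyzed_volume.n_rows * analyzed_volume.axial_spacing
    w = analyzed_volume.n_cols * analyzed_volume.lateral_spacing
    z0, z1 = truth.frame_positions_mm[0], truth.frame_positions_mm[-1]
    return (
        (c[:, 0] - r >= d0) & (c[:, 0] + r <= d1)
        & (c[:, 1] - r >= 0) & (c[:, 1] + r <= w)
        & (c[:, 2] - r >= z0) & (c[:, 2] + r <= z1)
    )


def match_measurements(
    spheres: list[SphereMeasurement],
    truth: PhantomTruth,
    analyzed_volume: CineVolume,
    tolerance_mm: float = 1.5,
) -> dict:
    """Greedy 1:1 match of eligible measurements to ground-truth spheres.

    Measurement positions are converted to phantom coordinates (depth via
    depth_offset, elevation via the true frame positions).  Returns recall
    against the detectable truth spheres and the matched measurements'
    equivalent diameters 2*sqrt(s_i/pi).
    """
    eligible = [s for s in spheres if s.eligible]
    det_mask = detectable_spheres(truth, analyzed_volume)
    n_detectable = int(det_mask.sum())
    if not eligible or len(truth.centers_mm) == 0:
        return {"n_eligible": len(eligible), "n_detectable": n_detectable,
                "n_matched": 0, "recall": 0.0, "equiv_diameters_mm": np.empty(0)}

    pos = np.array([
        [
            analyzed_volume.depth_offset + (s.yi + 0.5) * analyzed_volume.axial_spacing,
            (s.xi + 0.5) * analyzed_volume.lateral_spacing,
            truth.frame_positions_mm[s.zi],
        ]
        for s in eligible
    ])
    tree = cKDTree(truth.centers_mm)
    dist, idx = tree.query(pos, k=1)
    order = np.argsort(dist)
    taken: set[int] = set()
    matched_meas: list[int] = []
    matched_truth: list[int] = []
    for i in order:
        if dist[i] > tolerance_mm or idx[i] in taken:
            continue
        taken.add(int(idx[i]))
        matched_meas.append(int(i))
        matched_truth.append(int(idx[i]))

    matched_det = sum(1 for j in matched_truth if det_mask[j])
    diam = np.array([2.0 * math.sqrt(eligible[i].si_mm2 / math.pi) for i in matched_meas])
    return {
        "n_eligible": len(eligible),
        "n_detectable": n_detectable,
        "n_matched": len(matched_meas),
        "recall": matched_det / n_detectable if n_detectable else float("nan"),
        "equiv_diameters_mm": diam,
    }
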