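"""Depth-adaptive segmentation of hypoechoic sphere voxels.

Within each depth slab the pixel values are modelled as a two-component
mixture: a dominant bright background Gaussian and a darker sphere
component.  Because the spheres occupy ~20% of the volume, the naive
all-voxel mean/SD badly misestimate the background, so the background
Gaussian is recovered from the histogram peak mu_k and the *mirrored*
upper half of the distribution: every value x >= mu_k contributes both x
and 2*mu_k - x, and sigma_k is the population SD of that symmetrized set.
The slab threshold is T_k = mu_k - 2*sigma_k; voxels strictly below it are
sphere candidates (m0).  Three iterations of in-plane binary opening remove
speckle speckles, giving m1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import MorphologyConfig, ThresholdConfig
from .errors import InputError
from .volume import CineVolume


@dataclass
class SlabThreshold:
    """Background model and threshold of one depth slab."""

    index: int
    row_range: tuple[int, int]  # half-open [start, end)
    bin_edges: np.ndarray
    counts: np.ndarray
    mu: float
    sigma: float
    threshold: float


@dataclass
class SegmentationMasks:
    """m0: raw sub-threshold mask; m1: after binary opening (m1 ⊆ m0)."""

    m0: np.ndarray
    m1: np.ndarray


def slab_partition(n_rows: int, n_slabs: int = 10) -> list[tuple[int, int]]:
    """Split ``n_rows`` depth rows into ``n_slabs`` contiguous half-open
    ranges with boundaries at round(k * n_rows / n_slabs)."""
    if n_rows < n_slabs:
        raise InputError(f"cannot split {n_rows} rows into {n_slabs} slabs")
    bounds = [int(np.floor(k * n_rows / n_slabs + 0.5)) for k in range(n_slabs + 1)]
    return [(bounds[k], bounds[k + 1]) for k in range(n_slabs)]


def background_peak(counts: np.ndarray, bin_edges: np.ndarray) -> float:
    """Centre of the highest-count histogram bin (ties -> lowest intensity).

    The peak of the all-voxel histogram estimates the background mean: the
    background dominates and is brighter than the spheres, so the mode is
    unaffected by the sphere fraction even when the overall mean is.
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        raise InputError("empty histogram")
    i = int(np.argmax(counts))  # argmax returns the first (lowest) maximum
    return float(0.5 * (bin_edges[i] + bin_edges[i + 1]))


def mirrored_std(slab_voxels: np.ndarray, mu: float) -> float:
    """Background SD from the upper half-distribution mirrored around mu.

    With S = {x >= mu} and S' = S ∪ {2*mu - x}, the mean of S' is exactly
    mu and its population SD is sqrt(mean((x - mu)^2) over S).
    """
    x = np.asarray(slab_voxels, dtype=np.float64).ravel()
    upper = x[x >= mu]
    if upper.size == 0:
        raise InputError("no voxels at or above the background peak")
    dev = upper - mu
    return float(np.sqrt(np.mean(dev * dev)))


def slab_threshold(mu: float, sigma: float, k_sigma: float = 2.0) -> float:
    """T_k = mu_k - k * sigma_k (default k = 2)."""
    return mu - k_sigma * sigma


def compute_slab_thresholds(
    x1: CineVolume, cfg: ThresholdConfig | None = None
) -> list[SlabThreshold]:
    """Per-slab background models and thresholds over the depth extent of x1."""
    cfg = cfg or ThresholdConfig()
    out = []
    for k, (r0, r1) in enumerate(slab_partition(x1.n_rows, cfg.n_slabs)):
        vox = x1.voxels[r0:r1].ravel()
        lo, hi = float(vox.min()), float(vox.max())
        if hi == lo:  # degenerate constant slab
            counts, edges = np.histogram(vox, bins=cfg.n_bins, range=(lo, lo + 1.0))
            mu, sigma = lo, 0.0
        else:
            counts, edges = np.histogram(vox, bins=cfg.n_bins, range=(lo, hi))
            mu = background_peak(counts, edges)
            if not np.any(vox >= mu):  # peak-bin centre above every voxel
                mu = float(vox[vox < mu].max())
            sigma = mirrored_std(vox, mu)
        out.append(
            SlabThreshold(
                index=k,
                row_range=(r0, r1),
                bin_edges=edges,
                counts=counts,
                mu=mu,
                sigma=sigma,
                threshold=slab_threshold(mu, sigma, cfg.k_sigma),
            )
        )
    return out


def _opening_2d(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Binary opening applied frame by frame with a 4-connected cross.

    The opening is strictly in-plane: elevational frame spacing is unknown
    under freehand scanning and at coarse interframe distances a sphere may
    span only a few frames, which a 3D opening would annihilate.
    """
    if iterations <= 0:
        return mask.copy()
    cross = ndi.generate_binary_structure(2, 1)
    out = np.empty_like(mask)
    for f in range(mask.shape[2]):
        er = ndi.binary_erosion(mask[:, :, f], cross, iterations=iterations)
        out[:, :, f] = ndi.binary_dilation(er, cross, iterations=iterations)
    return out


def segment(
    x1: CineVolume,
    thresholds: list[SlabThreshold],
    morph_cfg: MorphologyConfig | None = None,
) -> SegmentationMasks:
    """Threshold x1 slab by slab (m0) and clean with binary opening (m1)."""
    morph_cfg = morph_cfg or MorphologyConfig()
    rows_covered = sorted((t.row_range for t in thresholds))
    expect = 0
    for r0, r1 in rows_covered:
        if r0 != expect:
            raise InputError("slab thresholds must cover every depth row exactly once")
        expect = r1
    if expect != x1.n_rows:
        raise InputError("slab thresholds must cover every depth row exactly once")

    m0 = np.zeros(x1.voxels.shape, dtype=bool)
    for t in thresholds:
        r0, r1 = t.row_range
        m0[r0:r1] = x1.voxels[r0:r1] < t.threshold
    m1 = _opening_2d(m0, morph_cfg.opening_iterations)
    return SegmentationMasks(m0=m0, m1=m1)
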