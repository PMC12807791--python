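"""Per-sphere LSNR and its aggregation into depth curves and variability.

LSNR_i = (Sf_i - Sb_i) / sigma_b_i, computed on the *original* cropped
volume x0 (preprocessing would alter the very statistics being measured):

* Sf — mean intensity inside the sphere's maximum cross-section mask,
  eroded by 3 pixels in-plane so boundary partial-volume pixels are
  excluded;
* Sb, sigma_b — mean and population SD of a background cylinder of
  diameter 4d centred on the sphere axis, spanning every frame, minus the
  raw threshold mask m0 dilated by one voxel (m0 rather than the opened m1,
  to exclude as many sphere pixels as possible).

LSNR is negative for hypoechoic spheres, and invariant under any affine
intensity map a*x + b (a > 0): gain changes cancel between numerator and
denominator.  Per-slab means over 25 uniform depth slabs with standard
errors sigma/sqrt(N) form the LSNR-vs-depth curve; the relative standard
deviation (RSD) across repeated acquisitions quantifies repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import LSNRConfig
from .errors import InputError
from .separation import SphereMeasurement
from .volume import CineVolume


@dataclass
class LSNRCurve:
    """Per-depth-slab LSNR summary.

    Arrays have one entry per slab; slabs with no spheres carry NaN in
    ``lsnr`` / ``sigma`` / ``epsilon`` and contribute no curve point.
    ``epsilon`` (the standard error sigma/sqrt(N)) is defined for N >= 2.
    """

    edges_cm: np.ndarray  # n_slabs + 1 depth edges
    counts: np.ndarray
    lsnr: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray

    @property
    def midpoints_cm(self) -> np.ndarray:
        return 0.5 * (self.edges_cm[:-1] + self.edges_cm[1:])

    @property
    def n_slabs(self) -> int:
        return len(self.counts)

    def peak(self) -> tuple[float, float] | None:
        """(depth_cm, LSNR) of the most negative slab mean, or None."""
        if not np.any(self.counts > 0):
            return None
        i = int(np.nanargmin(self.lsnr))
        return float(self.midpoints_cm[i]), float(self.lsnr[i])


@dataclass
class VariabilityReport:
    """Across-acquisition RSDs (%) of the LSNR and sphere-count curves."""

    per_depth_rsd_lsnr: np.ndarray
    per_depth_rsd_counts: np.ndarray
    overall_rsd_lsnr: float
    overall_rsd_counts: float
    at_depth_cm: float | None = None
    point_rsd_lsnr: float | None = None
    point_rsd_counts: float | None = None


def sphere_signal(
    x0: CineVolume,
    m2: np.ndarray,
    sphere: SphereMeasurement,
    erosion: int = 3,
) -> float | None:
    """Mean x0 intensity of the sphere's eroded maximum cross-section.

    The 2D mask in frame zi is eroded ``erosion`` iterations with a
    4-connected cross; None (drop) if nothing survives.
    """
    mask = m2[:, :, sphere.zi] == sphere.label
    if erosion > 0:
        mask = ndi.binary_erosion(
            mask, ndi.generate_binary_structure(2, 1), iterations=erosion
        )
    if not mask.any():
        return None
    return float(x0.voxels[:, :, sphere.zi][mask].mean())


def background_stats(
    x0: CineVolume,
    m0: np.ndarray,
    sphere: SphereMeasurement,
    d_mm: float,
    dilation: int = 1,
    cylinder_diameter_factor: float = 4.0,
    min_background_voxels: int = 100,
) -> tuple[float, float] | None:
    """(Sb, sigma_b) over the background cylinder around the sphere.

    The cylinder has diameter ``cylinder_diameter_factor * d`` (default 4d),
    is centred at (xi, yi) and spans all frames: the phantom background is
    uniform at fixed depth, so pooling frames shrinks the estimator
    uncertainty.  Voxels in m0 dilated by ``dilation`` are excluded.
    Returns None (drop) if fewer than ``min_background_voxels`` remain.
    sigma_b is the population SD.
    """
    radius_mm = cylinder_diameter_factor * d_mm / 2.0
    rows = np.arange(x0.n_rows)[:, None]
    cols = np.arange(x0.n_cols)[None, :]
    dist2 = ((rows - sphere.yi) * x0.axial_spacing) ** 2 + (
        (cols - sphere.xi) * x0.lateral_spacing
    ) ** 2
    disk = dist2 <= radius_mm**2

    excl = m0
    if dilation > 0:
        excl = ndi.binary_dilation(
            m0, ndi.generate_binary_structure(3, 1), iterations=dilation
        )
    bg = disk[:, :, None] & ~excl
    n = int(bg.sum())
    if n < min_background_voxels:
        return None
    vals = x0.voxels[bg]
    return float(vals.mean()), float(vals.std())


def lsnr(Sf: float, Sb: float, sigma_b: float) -> float | None:
    """(Sf - Sb) / sigma_b; None (drop) when sigma_b is zero."""
    if sigma_b == 0:
        return None
    return (Sf - Sb) / sigma_b


def attach_lsnr(
    x0: CineVolume,
    m0: np.ndarray,
    m2: np.ndarray,
    spheres: list[SphereMeasurement],
    cfg: LSNRConfig | None = None,
    d_mm: float = 2.0,
) -> list[SphereMeasurement]:
    """Fill Sf/Sb/sigma_b/lsnr for every eligible sphere (in place).

    Spheres whose eroded mask empties, whose background set is too small or
    whose background SD is zero are dropped with a recorded reason and a
    warning; they keep ``eligible`` but carry no LSNR.
    """
    cfg = cfg or LSNRConfig()
    for s in spheres:
        if not s.eligible:
            continue
        Sf = sphere_signal(x0, m2, s, cfg.erosion_px)
        if Sf is None:
            s.dropped_reason = "mask empty after erosion"
            warnings.warn(f"sphere {s.label}: {s.dropped_reason}", stacklevel=2)
            continue
        bgs = background_stats(
            x0, m0, s, d_mm, cfg.dilation_px,
            cfg.cylinder_diameter_factor, cfg.min_background_voxels,
        )
        if bgs is None:
            s.dropped_reason = "background set too small"
            warnings.warn(f"sphere {s.label}: {s.dropped_reason}", stacklevel=2)
            continue
        s.Sf = Sf
        s.Sb, s.sigma_b = bgs
        val = lsnr(Sf, s.Sb, s.sigma_b)
        if val is None:
            s.Sf = s.Sb = s.sigma_b = None
            s.dropped_reason = "zero background SD"
            warnings.warn(f"sphere {s.label}: {s.dropped_reason}", stacklevel=2)
            continue
        s.lsnr = val
    return spheres


def lsnr_curve(
    spheres: list[SphereMeasurement],
    depth_extent_cm: tuple[float, float],
    n_slabs: int = 25,
) -> LSNRCurve:
    """Bin per-sphere LSNRs into uniform depth slabs.

    Binning is half-open [y_k, y_{k+1}); the slab mean is the curve value,
    the sample (n-1) SD gives the standard error epsilon = sigma/sqrt(N).
    """
    lo, hi = depth_extent_cm
    if hi <= lo:
        raise InputError("depth extent must be increasing")
    edges = np.linspace(lo, hi, n_slabs + 1)
    pts = [(s.depth_cm, s.lsnr) for s in spheres if s.lsnr is not None]
    counts = np.zeros(n_slabs, dtype=int)
    mean = np.full(n_slabs, np.nan)
    sigma = np.full(n_slabs, np.nan)
    eps = np.full(n_slabs, np.nan)
    if pts:
        depths = np.array([p[0] for p in pts])
        vals = np.array([p[1] for p in pts])
        idx = np.digitize(depths, edges) - 1  # [y_k, y_{k+1}) half-open
        ok = (idx >= 0) & (idx < n_slabs)
        for k in range(n_slabs):
            v = vals[ok & (idx == k)]
            counts[k] = v.size
            if v.size:
                mean[k] = v.mean()
            if v.size >= 2:
                sigma[k] = v.std(ddof=1)
                eps[k] = sigma[k] / np.sqrt(v.size)
    return LSNRCurve(edges_cm=edges, counts=counts, lsnr=mean, sigma=sigma, epsilon=eps)


def variability(
    curves: list[LSNRCurve], at_depth_cm: float | None = None
) -> VariabilityReport:
    """Across-acquisition RSDs per depth slab and overall.

    Requires >= 2 curves on identical slab grids.  Per-slab RSD is the
    sample SD across curves over the absolute mean (x100%); the overall
    value averages slabs where *every* curve is defined (and, for LSNR,
    the mean is nonzero).  Counts use all slabs with a nonzero mean.
    """
    if len(curves) < 2:
        raise InputError("variability needs at least two acquisitions")
    edges = curves[0].edges_cm
    for c in curves[1:]:
        if c.n_slabs != curves[0].n_slabs or not np.allclose(c.edges_cm, edges):
            raise InputError("curves must share an identical slab grid")

    L = np.vstack([c.lsnr for c in curves])
    N = np.vstack([c.counts for c in curves]).astype(float)
    n_slabs = curves[0].n_slabs

    def rsd(mat: np.ndarray) -> np.ndarray:
        out = np.full(n_slabs, np.nan)
        defined = ~np.any(np.isnan(mat), axis=0)
        m = np.abs(np.nanmean(mat, axis=0))
        sd = np.nanstd(mat, axis=0, ddof=1)
        nz = defined & (m > 0)
        if np.any(defined & ~nz):
            warnings.warn("slab with zero mean excluded from overall RSD", stacklevel=3)
        out[nz] = 100.0 * sd[nz] / m[nz]
        return out

    rsd_l = rsd(L)
    rsd_n = rsd(N)
    report = VariabilityReport(
        per_depth_rsd_lsnr=rsd_l,
        per_depth_rsd_counts=rsd_n,
        overall_rsd_lsnr=float(np.nanmean(rsd_l)) if np.any(~np.isnan(rsd_l)) else float("nan"),
        overall_rsd_counts=float(np.nanmean(rsd_n)) if np.any(~np.isnan(rsd_n)) else float("nan"),
    )
    if at_depth_cm is not None:
        k = int(np.clip(np.digitize(at_depth_cm, edges) - 1, 0, n_slabs - 1))
        report.at_depth_cm = at_depth_cm
        report.point_rsd_lsnr = float(rsd_l[k])
        report.point_rsd_counts = float(rsd_n[k])
    return report
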