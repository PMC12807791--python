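"""Preprocessing of the raw volume x0 into the segmentation volume x1.

Two steps, in fixed order: 3D non-local-means denoising, then B-spline
bias-field (N4) correction.  NLM strength is tied to the global intensity
spread of x0 (sigma0 / 8), so the denoiser adapts to gain and dynamic-range
settings without per-scan tuning.  N4 removes the smooth multiplicative
inhomogeneity left by depth attenuation; the control grid is densest along
depth (8 points vs 4 in-plane/elevational) because that is where ultrasound
images are most inhomogeneous.

x1 is used only to *segment* the spheres; every LSNR statistic is computed
on the untouched x0.
"""

from __future__ import annotations

import numpy as np
from dataclasses import replace

from .config import BiasConfig, NLMConfig
from .errors import NumericError
from .volume import CineVolume


def nlm_denoise(x0: CineVolume, cfg: NLMConfig | None = None) -> CineVolume:
    """3D non-local-means denoising of x0.

    Window and patch sizes are full widths (defaults 9 and 3 pixels,
    isotropic); the strength is sigma0 / ``cfg.strength_divisor`` where
    sigma0 is the standard deviation of the entire volume.  Deterministic;
    output intensities stay within the input range.
    """
    from skimage.restoration import denoise_nl_means

    cfg = cfg or NLMConfig()
    cfg.validate()
    v = x0.voxels.astype(np.float32)
    sigma0 = float(np.std(v))
    if sigma0 == 0.0:  # constant volume is a fixed point
        return replace(x0, voxels=v.copy())
    h = sigma0 / cfg.strength_divisor
    out = denoise_nl_means(
        v,
        patch_size=cfg.patch_size,
        patch_distance=(cfg.search_window - 1) // 2,
        h=h,
        fast_mode=True,
        preserve_range=True,
    )
    np.clip(out, float(v.min()), float(v.max()), out=out)
    return replace(x0, voxels=out.astype(np.float32))


def estimate_bias_field(x: CineVolume, cfg: BiasConfig | None = None) -> np.ndarray:
    """Estimate the smooth multiplicative bias field of ``x`` with N4.

    The field is fitted on the log intensities over a B-spline control grid
    of ``cfg.control_points`` (depth, lateral, elevational) points, on a
    volume shrunk by ``cfg.shrink_factor`` for speed, and resampled to full
    resolution.  Returns a strictly positive array shaped like the volume.
    """
    import SimpleITK as sitk

    cfg = cfg or BiasConfig()
    cfg.validate()
    v = x.voxels.astype(np.float64)
    if np.min(v) <= 0:
        raise NumericError("bias correction requires a strictly positive volume")

    img = sitk.GetImageFromArray(v)  # sitk axes (x,y,z) = (elev, lateral, depth)
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    cp_depth, cp_lat, cp_elev = cfg.control_points
    n4.SetNumberOfControlPoints([cp_elev, cp_lat, cp_depth])
    n4.SetMaximumNumberOfIterations([cfg.max_iterations])
    n4.SetConvergenceThreshold(cfg.convergence_threshold)

    if cfg.shrink_factor > 1:
        f = cfg.shrink_factor
        shrink = [min(f, s) for s in img.GetSize()]
        n4.Execute(sitk.Shrink(img, shrink))
    else:
        n4.Execute(img)
    log_field = sitk.GetArrayFromImage(n4.GetLogBiasFieldAsImage(img))
    return np.exp(log_field)


def bias_correct(x: CineVolume, cfg: BiasConfig | None = None) -> CineVolume:
    """Divide out the estimated bias field, producing x1.

    Zero voxels are shifted by epsilon = 1e-3 x mean before the log-domain
    fit (the multiplicative model needs positivity); the output is rescaled
    so its global mean matches the input's.  Output is strictly positive.
    """
    v = x.voxels.astype(np.float64)
    mean_in = float(np.mean(v))
    if mean_in <= 0:
        raise NumericError("cannot bias-correct a non-positive volume")
    eps = 1e-3 * mean_in
    v = np.where(v <= 0, eps, v)
    if np.std(v) < 1e-9 * mean_in:  # constant volume: bias field is constant
        return replace(x, voxels=v.astype(np.float32))

    field = estimate_bias_field(replace(x, voxels=v), cfg)
    out = v / field
    out *= mean_in / float(np.mean(out))
    return replace(x, voxels=out.astype(np.float32))


def preprocess(x0: CineVolume, nlm_cfg: NLMConfig | None = None,
               bias_cfg: BiasConfig | None = None) -> CineVolume:
    """Full preprocessing chain: NLM denoising then bias correction."""
    return bias_correct(nlm_denoise(x0, nlm_cfg), bias_cfg)
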