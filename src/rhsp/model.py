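"""Model/results objects tying the whole analysis pipeline together.

``LSNRModel`` wraps one cine acquisition; ``fit()`` runs the full chain

    extract_fov -> NLM -> N4 -> slab thresholds -> segment -> watershed
    -> max cross-sections -> area filter -> per-sphere LSNR -> depth curve

and returns an ``LSNRResults`` carrying the per-sphere estimates, the
LSNR-vs-depth curve with standard errors, diagnostics (dropped spheres,
slab thresholds) and a ``summary()`` table.  The analysis path contains no
randomness: refitting the same volume reproduces every number exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics, preprocess, separation, threshold
from .config import AnalysisConfig
from .errors import InputError
from .metrics import LSNRCurve, VariabilityReport
from .separation import SphereMeasurement
from .threshold import SegmentationMasks, SlabThreshold
from .volume import CineVolume, extract_fov, read_cine


class LSNRModel:
    """Sphere-phantom LSNR analysis of a single cine acquisition.

    Parameters
    ----------
    volume : CineVolume
        The raw stacked cine loop (not yet FOV-cropped).
    config : AnalysisConfig, optional
        Pipeline settings; defaults follow the standard 2 mm-sphere
        phantom protocol.
    """

    def __init__(self, volume: CineVolume, config: AnalysisConfig | None = None):
        self.volume = volume
        self.config = (config or AnalysisConfig()).validate()

    @classmethod
    def from_path(cls, path, config: AnalysisConfig | None = None) -> "LSNRModel":
        """Build a model from a DICOM file/series, frame directory or
        NRRD/NIfTI volume on disk."""
        config = (config or AnalysisConfig()).validate()
        p = Path(path)
        if p.suffix in {".nrrd", ".nii"} or str(p).endswith(".nii.gz"):
            from .volume import load_volume

            vol = load_volume(p, acquisition_id=p.name)
        else:
            vol = read_cine(p, pixel_spacing=config.pixel_spacing_mm, acquisition_id=p.name)
        return cls(vol, config)

    def fit(self, keep_volumes: bool = True) -> "LSNRResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        x0 = extract_fov(
            self.volume,
            min_offset=cfg.fov.min_offset,
            trim_rows=cfg.fov.trim_rows,
            overlay_value=cfg.fov.overlay_value,
        )
        x1 = preprocess.preprocess(x0, cfg.nlm, cfg.bias)
        thresholds = threshold.compute_slab_thresholds(x1, cfg.threshold)
        masks = threshold.segment(x1, thresholds, cfg.morphology)
        m2 = separation.split_connected(masks.m1, cfg.sphere.min_seed_distance)
        spheres = separation.measure_spheres(m2, x0, cfg.sphere)
        metrics.attach_lsnr(x0, masks.m0, m2, spheres, cfg.lsnr, cfg.sphere.diameter_mm)
        curve = metrics.lsnr_curve(spheres, x0.depth_extent_cm, cfg.lsnr.n_curve_slabs)
        return LSNRResults(
            model=self,
            x0=x0 if keep_volumes else None,
            x1=x1 if keep_volumes else None,
            thresholds=thresholds,
            masks=masks if keep_volumes else None,
            label_map=m2 if keep_volumes else None,
            spheres=spheres,
            curve=curve,
        )


@dataclass
class LSNRResults:
    """Fitted results of one acquisition.

    ``spheres`` holds every watershed label with its measurements and
    eligibility; ``curve`` the per-slab LSNR means, standard errors and
    sphere counts.
    """

    model: LSNRModel
    thresholds: list[SlabThreshold]
    spheres: list[SphereMeasurement]
    curve: LSNRCurve
    x0: CineVolume | None = None
    x1: CineVolume | None = None
    masks: SegmentationMasks | None = None
    label_map: np.ndarray | None = None

    @property
    def eligible_spheres(self) -> list[SphereMeasurement]:
        return [s for s in self.spheres if s.eligible]

    @property
    def n_eligible(self) -> int:
        return len(self.eligible_spheres)

    @property
    def sphere_table(self) -> pd.DataFrame:
        rows = [
            {
                "label": s.label,
                "zi": s.zi,
                "xi_px": s.xi,
                "yi_px": s.yi,
                "depth_cm": s.depth_cm,
                "si_px": s.si_px,
                "si_mm2": s.si_mm2,
                "touches_edge": s.touches_edge,
                "eligible": s.eligible,
                "Sf": s.Sf,
                "Sb": s.Sb,
                "sigma_b": s.sigma_b,
                "lsnr": s.lsnr,
                "dropped_reason": s.dropped_reason,
            }
            for s in self.spheres
        ]
        return pd.DataFrame(rows)

    @property
    def curve_table(self) -> pd.DataFrame:
        c = self.curve
        df = pd.DataFrame(
            {
                "depth_cm": c.midpoints_cm,
                "lsnr": c.lsnr,
                "sigma": c.sigma,
                "epsilon": c.epsilon,
                "n_spheres": c.counts,
            }
        )
        return df[df.n_spheres > 0].reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable report: counts, peak LSNR, per-slab curve."""
        peak = self.curve.peak()
        lines = [
            "LSNR depth-curve analysis",
            "=" * 60,
            f"acquisition:      {self.model.volume.acquisition_id or '<unnamed>'}",
            f"analyzed volume:  {self.x0.voxels.shape if self.x0 is not None else 'n/a'}"
            f"  (rows x cols x frames)",
            f"sphere diameter:  {self.model.config.sphere.diameter_mm:g} mm",
            f"labels found:     {len(self.spheres)}",
            f"eligible spheres: {self.n_eligible}",
            f"with LSNR:        {sum(s.lsnr is not None for s in self.spheres)}",
        ]
        if peak is not None:
            lines.append(f"peak LSNR:        {peak[1]:.2f} at {peak[0]:.2f} cm depth")
        lines += ["-" * 60, self.curve_table.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        peak = self.curve.peak()
        return {
            "acquisition_id": self.model.volume.acquisition_id,
            "n_labels": len(self.spheres),
            "n_eligible": self.n_eligible,
            "n_with_lsnr": int(sum(s.lsnr is not None for s in self.spheres)),
            "peak_lsnr": None if peak is None else peak[1],
            "peak_depth_cm": None if peak is None else peak[0],
            "curve_edges_cm": [float(e) for e in self.curve.edges_cm],
            "config": self.model.config.to_dict(),
        }

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write per-sphere CSV, curve CSV and JSON summary to ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "spheres": out / "spheres.csv",
            "curve": out / "curve.csv",
            "summary": out / "summary.json",
        }
        self.sphere_table.to_csv(paths["spheres"], index=False)
        self.curve_table.to_csv(paths["curve"], index=False)
        paths["summary"].write_text(json.dumps(self.to_summary_dict(), indent=2))
        return paths

    def plot_lsnr(self, ax=None):
        """LSNR vs depth with epsilon error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.curve_table
        ax.errorbar(t.depth_cm, t.lsnr, yerr=t.epsilon, fmt="o-", capsize=3)
        ax.set_xlabel("depth (cm)")
        ax.set_ylabel("LSNR")
        ax.invert_yaxis()
        return ax

    def plot_counts(self, ax=None):
        """Sphere count vs depth."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.curve_table
        ax.bar(t.depth_cm, t.n_spheres, width=np.diff(self.curve.edges_cm).mean() * 0.9)
        ax.set_xlabel("depth (cm)")
        ax.set_ylabel("# spheres")
        return ax


def compare_results(
    results: Sequence[LSNRResults], at_depth_cm: float | None = 2.2
) -> VariabilityReport:
    """Repeatability across acquisitions: RSD of LSNR and sphere counts.

    All acquisitions must share the same depth setting so the slab grids
    align; no depth registration is attempted.
    """
    if len(results) < 2:
        raise InputError("need at least two acquisitions to compare")
    return metrics.variability([r.curve for r in results], at_depth_cm)
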