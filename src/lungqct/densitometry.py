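"""Per-ROI HU densitometry: mean/SD/CoV, low-attenuation areas, and
difference tables against a reference protocol.

Conventions, fixed so oracle tests are unambiguous:

* SD is the sample standard deviation (n-1 denominator).
* CoV = SD / |mean| — the absolute mean makes CoV positive for air-like
  ROIs whose mean is near -1000 HU.
* LAA uses a strict "less than" comparison at each threshold (-950 HU for
  the emphysema surrogate LAA950, -856 HU for the gas-trapping surrogate
  LAA856), reported as a percentage of masked voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import VoxelVolume
from .segmentation import ROIMask

__all__ = ["ROIStats", "LAAResult", "roi_stats", "laa", "diff_vs_reference",
           "format_abs_summary", "write_metrics_csv", "read_metrics_csv"]


@dataclass(frozen=True)
class ROIStats:
    """HU statistics of one region of interest.

    ``n_voxels`` may be None for pre-tabulated rows ingested from CSV, where
    the original voxel count was not published.
    """

    label: str
    n_voxels: int | None
    mean_hu: float
    sd_hu: float
    cov: float

    def __post_init__(self):
        if self.n_voxels is not None and self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")

    @classmethod
    def from_mean_sd(cls, label: str, mean_hu: float, sd_hu: float,
                     n_voxels: int | None = None) -> "ROIStats":
        cov = sd_hu / abs(mean_hu) if mean_hu != 0 else math.nan
        return cls(label, n_voxels, mean_hu, sd_hu, cov)


@dataclass(frozen=True)
class LAAResult:
    """Low-attenuation-area percentages for one ROI."""

    label: str
    laa950: float
    laa856: float

    def __post_init__(self):
        for v in (self.laa950, self.laa856):
            if not (0.0 <= v <= 100.0):
                raise ValueError("LAA percentages must lie in [0, 100]")


def roi_stats(vol: VoxelVolume, mask: ROIMask) -> ROIStats:
    """Mean, sample SD and CoV of the masked voxels."""
    vals = vol.voxels[mask.mask]
    if vals.size < 2:
        raise ValueError(f"mask {mask.label!r} has fewer than 2 voxels")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return ROIStats.from_mean_sd(mask.label, mean, sd, n_voxels=int(vals.size))


def laa(vol: VoxelVolume, mask: ROIMask,
        thresholds: tuple[float, float] = (-950.0, -856.0)) -> LAAResult:
    """Percentage of masked voxels strictly below each threshold."""
    vals = vol.voxels[mask.mask]
    if vals.size == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    t950, t856 = thresholds
    return LAAResult(
        mask.label,
        laa950=100.0 * float(np.count_nonzero(vals < t950)) / vals.size,
        laa856=100.0 * float(np.count_nonzero(vals < t856)) / vals.size,
    )


def diff_vs_reference(
    stats: list[ROIStats], ref: list[ROIStats]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-label HU differences of ``stats`` against a reference protocol.

    Returns the per-label table (signed and absolute mean differences, SD
    differences) plus a summary of the absolute mean differences across
    matched labels: mean, sample SD, min, max — the "mean ± SD (range)"
    style used for cross-protocol accuracy reporting.
    """
    ref_by = {s.label: s for s in ref}
    rows = []
    for s in stats:
        if s.label not in ref_by:
            continue
        r = ref_by[s.label]
        rows.append({
            "label": s.label,
            "mean_hu": s.mean_hu,
            "ref_mean_hu": r.mean_hu,
            "delta_mean_hu": s.mean_hu - r.mean_hu,
            "abs_delta_mean_hu": abs(s.mean_hu - r.mean_hu),
            "delta_sd_hu": s.sd_hu - r.sd_hu,
        })
    if not rows:
        raise ValueError("no labels in common with the reference")
    table = pd.DataFrame(rows)
    a = table["abs_delta_mean_hu"].to_numpy()
    summary = {
        "mean": float(a.mean()),
        "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "min": float(a.min()),
        "max": float(a.max()),
    }
    return table, summary


def format_abs_summary(summary: dict[str, float], unit: str = "HU") -> str:
    """Render a difference summary as ``mean ± SD unit (range lo–hi unit)``."""
    return (f"{summary['mean']:.1f} ± {summary['sd']:.1f} {unit} "
            f"(range {summary['min']:.1f}–{summary['max']:.1f} {unit})")


_CSV_COLUMNS = ["label", "n", "mean", "sd", "cov", "laa950", "laa856"]


def write_metrics_csv(path, stats: list[ROIStats],
                      laa_results: list[LAAResult] | None = None) -> None:
    """Per-protocol metrics table (one row per insert)."""
    laa_by = {r.label: r for r in (laa_results or [])}
    rows = []
    for s in stats:
        r = laa_by.get(s.label)
        rows.append({
            "label": s.label, "n": s.n_voxels, "mean": s.mean_hu,
            "sd": s.sd_hu, "cov": s.cov,
            "laa950": r.laa950 if r else math.nan,
            "laa856": r.laa856 if r else math.nan,
        })
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_metrics_csv(path) -> tuple[list[ROIStats], list[LAAResult]]:
    """Ingest a pre-tabulated per-protocol metrics table."""
    df = pd.read_csv(path)
    stats, laas = [], []
    for _, row in df.iterrows():
        n = None if pd.isna(row.get("n")) else int(row["n"])
        stats.append(ROIStats.from_mean_sd(str(row["label"]), float(row["mean"]),
                                           float(row["sd"]), n_voxels=n))
        if not pd.isna(row.get("laa950")):
            laas.append(LAAResult(str(row["label"]), float(row["laa950"]),
                                  float(row["laa856"])))
    return stats, laas
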