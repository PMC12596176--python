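"""Effective-dose arithmetic, dose-reduction summaries, and the
protocol-selection rule used to harmonize low-dose quantitative lung CT
protocols across scanners.

Effective dose uses the chest conversion

    E [mSv] = CTDIvol [mGy] x scan length [cm] x k

with a 30 cm scan length and chest k-factor 0.027 mSv/(mGy cm) by default.
Full precision is carried everywhere; display rounding (half away from
zero, 2 decimals for mSv, integers for %) is applied only when a report is
rendered.

Selection rule
--------------
Candidates for one scanner are ranked against the reference-standard
protocol on the primary inserts (air and the two water vials), whose ground
truth HU is known:

1. score each candidate by its total absolute mean-HU difference from the
   reference over the primary labels, and by an MTF score (mean of the
   in-plane and z 50%/20% cutoffs);
2. if a single candidate minimizes the HU difference outright (no other
   candidate within ``hu_tie_tol``) *and* also maximizes the MTF score
   (within ``mtf_tie_tol``), it is selected;
3. otherwise — HU scores tie, or the HU- and MTF-preferred candidates
   disagree — the HU-acceptable candidate with the lowest summed HU SD over
   the primary labels is selected, minimizing image noise.

Every comparison is recorded in an audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .densitometry import LAAResult, ROIStats, diff_vs_reference
from .volume_io import ProtocolMeta

__all__ = [
    "DoseParams",
    "ProtocolRecord",
    "ComparisonReport",
    "effective_dose",
    "percent_reduction",
    "summarize_reductions",
    "select_protocol",
    "build_report",
    "round_display",
    "PRIMARY_LABELS",
]

PRIMARY_LABELS = ("air", "water_vial_1", "water_vial_2")


@dataclass(frozen=True)
class DoseParams:
    """Scan length (cm) and chest k-factor (mSv per mGy cm)."""

    scan_length: float = 30.0
    k_factor: float = 0.027

    def __post_init__(self):
        if self.scan_length <= 0 or self.k_factor <= 0:
            raise ValueError("scan_length and k_factor must be positive")


def round_display(value: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` (report-time display only)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def effective_dose(ctdi_vol: float, params: DoseParams = DoseParams()) -> float:
    """Effective dose (mSv) = CTDIvol x scan length x k-factor, full precision."""
    if ctdi_vol < 0:
        raise ValueError("ctdi_vol must be >= 0")
    return ctdi_vol * params.scan_length * params.k_factor


def percent_reduction(reference_ctdi: float, low_ctdi: float) -> float:
    """Percent CTDIvol reduction of a low-dose protocol vs a reference."""
    if reference_ctdi <= 0:
        raise ValueError("reference_ctdi must be positive")
    return 100.0 * (reference_ctdi - low_ctdi) / reference_ctdi


def summarize_reductions(reductions: list[float]) -> dict[str, float]:
    """Mean, sample SD, min and max of a set of percent reductions."""
    if len(reductions) < 2:
        raise ValueError("need at least 2 reductions to summarize")
    a = np.asarray(reductions, dtype=float)
    return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)),
            "min": float(a.min()), "max": float(a.max())}


@dataclass
class ProtocolRecord:
    """One scanner/reconstruction/CTDIvol candidate with its metric set."""

    meta: ProtocolMeta
    roi_stats: list[ROIStats]
    laa: list[LAAResult] = field(default_factory=list)
    mtf_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    dose_params: DoseParams = DoseParams()

    @property
    def name(self) -> str:
        return (f"{self.meta.scanner_label} {self.meta.recon_label} "
                f"{self.meta.ctdi_vol:g} mGy").strip()

    @property
    def effective_dose(self) -> float:
        return effective_dose(self.meta.ctdi_vol, self.dose_params)

    def stats_by_label(self) -> dict[str, ROIStats]:
        return {s.label: s for s in self.roi_stats}

    def mtf_score(self) -> float:
        vals = [self.mtf_summary[ax][lvl]
                for ax in ("in_plane", "z") if ax in self.mtf_summary
                for lvl in ("f50", "f20") if lvl in self.mtf_summary[ax]]
        if not vals:
            raise ValueError(f"candidate {self.name!r} has no MTF summary")
        return float(np.mean(vals))


def select_protocol(
    candidates: list[ProtocolRecord],
    reference: ProtocolRecord,
    hu_tie_tol: float = 5.0,
    mtf_tie_tol: float = 0.1,
    primary_labels: tuple[str, ...] = PRIMARY_LABELS,
) -> tuple[str, list[dict]]:
    """Apply the harmonization selection rule; returns (name, audit trail)."""
    if not candidates:
        raise ValueError("no candidates")
    ref_by = reference.stats_by_label()
    for lbl in primary_labels:
        if lbl not in ref_by:
            raise ValueError(f"reference is missing primary label {lbl!r}")
    audit: list[dict] = []
    scored = []
    for c in candidates:
        by = c.stats_by_label()
        for lbl in primary_labels:
            if lbl not in by:
                raise ValueError(f"candidate {c.name!r} is missing primary label {lbl!r}")
        d_hu = sum(abs(by[lbl].mean_hu - ref_by[lbl].mean_hu) for lbl in primary_labels)
        sd_sum = sum(by[lbl].sd_hu for lbl in primary_labels)
        mtf = c.mtf_score()
        scored.append((c, d_hu, mtf, sd_sum))
        audit.append({"stage": "score", "candidate": c.name,
                      "delta_hu_total": d_hu, "mtf_score": mtf,
                      "sd_sum": sd_sum})
    best_dhu = min(s[1] for s in scored)
    hu_set = [s for s in scored if s[1] <= best_dhu + hu_tie_tol]
    best_mtf = max(s[2] for s in scored)
    mtf_set = {s[0].name for s in scored if s[2] >= best_mtf - mtf_tie_tol}
    if len(hu_set) == 1 and hu_set[0][0].name in mtf_set:
        winner = hu_set[0][0]
        audit.append({"stage": "unique", "selected": winner.name,
                      "reason": "uniquely minimizes HU difference and "
                                "maximizes MTF"})
        return winner.name, audit
    # tie-break: lowest summed HU SD among the HU-acceptable candidates
    winner = min(hu_set, key=lambda s: (s[3], s[0].name))[0]
    audit.append({
        "stage": "sd_tiebreak",
        "tied": [s[0].name for s in hu_set],
        "selected": winner.name,
        "reason": "HU scores tied or HU/MTF preferences disagreed; "
                  "lowest summed HU SD over primary labels selected",
    })
    return winner.name, audit


@dataclass
class ComparisonReport:
    """Full cross-protocol comparison: deltas, selection, dose summary."""

    reference: ProtocolRecord
    candidates: list[ProtocolRecord]
    selected: str
    audit: list[dict]
    deltas: dict[str, pd.DataFrame]
    delta_summaries: dict[str, dict[str, float]]
    dose_summary: dict

    def to_json(self, path: str | Path) -> None:
        doc = {
            "reference": self.reference.name,
            "candidates": [c.name for c in self.candidates],
            "selected": self.selected,
            "audit": self.audit,
            "delta_summaries": self.delta_summaries,
            "dose_summary": self.dose_summary,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    def dose_table(self) -> pd.DataFrame:
        rows = []
        for rec in [self.reference] + self.candidates:
            rows.append({
                "protocol": rec.name,
                "ctdi_vol_mgy": rec.meta.ctdi_vol,
                "effective_dose_msv": round_display(rec.effective_dose, 2),
            })
        return pd.DataFrame(rows)


def build_report(
    reference: ProtocolRecord,
    candidates: list[ProtocolRecord],
    params: DoseParams = DoseParams(),
    baseline_ctdi: float | None = None,
    hu_tie_tol: float = 5.0,
    mtf_tie_tol: float = 0.1,
) -> ComparisonReport:
    """Assemble the comparison report for one scanner's candidates.

    ``baseline_ctdi`` is the dose the percent reductions are computed
    against (a standard-dose protocol); it defaults to the reference
    record's CTDIvol.
    """
    if baseline_ctdi is None:
        baseline_ctdi = reference.meta.ctdi_vol
    selected, audit = select_protocol(candidates or [reference], reference,
                                      hu_tie_tol=hu_tie_tol,
                                      mtf_tie_tol=mtf_tie_tol)
    deltas, summaries = {}, {}
    for c in candidates or [reference]:
        table, summary = diff_vs_reference(c.roi_stats, reference.roi_stats)
        deltas[c.name] = table
        summaries[c.name] = summary
    reductions = {
        c.name: percent_reduction(baseline_ctdi, c.meta.ctdi_vol)
        for c in (candidates or [reference])
    }
    vals = list(reductions.values())
    dose_summary = {
        "per_protocol_pct": {k: round_display(v, 0) for k, v in reductions.items()},
        **(summarize_reductions(vals) if len(vals) >= 2
           else {"mean": vals[0], "sd": 0.0, "min": vals[0], "max": vals[0]}),
        "baseline_ctdi_mgy": baseline_ctdi,
    }
    return ComparisonReport(
        reference=reference,
        candidates=candidates or [reference],
        selected=selected,
        audit=audit,
        deltas=deltas,
        delta_summaries=summaries,
        dose_summary=dose_summary,
    )
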