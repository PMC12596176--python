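"""Published protocol tables bundled as package data.

These are the printed per-protocol inputs for the worked examples: the
final CTDIvol / effective-dose table across all ten scanners, and the full
metric comparison for one representative scanner (a SOMATOM Drive evaluated
at two CTDIvol targets x two iterative-reconstruction strengths) against
the reference-standard low-dose protocol (SOMATOM Force, ADMIRE 5,
2.22 mGy).  Values are transcribed exactly as printed; voxel counts per ROI
were not published, so ``ROIStats.n_voxels`` is None throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from .densitometry import LAAResult, ROIStats
from .dose_harmonization import ProtocolRecord
from .volume_io import ProtocolMeta

__all__ = ["DoseRow", "DOSE_TABLE", "STANDARD_DOSE_CTDI",
           "force_reference_record", "drive_candidate_records"]


@dataclass(frozen=True)
class DoseRow:
    """One protocol row of the final-dose table."""

    protocol: str
    tier: str  # "standard" | "low"
    ctdi_vol: float  # mGy
    printed_effective_dose: float  # mSv, as printed


#: Final harmonized protocols: measured CTDIvol and the printed effective dose.
DOSE_TABLE: list[DoseRow] = [
    DoseRow("Siemens SOMATOM Force Qr40, ADMIRE off", "standard", 7.32, 5.93),
    DoseRow("Siemens SOMATOM Definition AS+ B35, SAFIRE off", "standard", 7.44, 6.02),
    DoseRow("Siemens SOMATOM Force Qr40, ADMIRE 5", "low", 2.22, 1.80),
    DoseRow("Siemens SOMATOM Definition AS+ Q30, SAFIRE 5", "low", 3.52, 2.85),
    DoseRow("Siemens SOMATOM Definition Flash Q30, SAFIRE 5", "low", 3.50, 2.84),
    DoseRow("Siemens SOMATOM Definition Edge Q30, ADMIRE 5", "low", 3.54, 2.87),
    DoseRow("Siemens SOMATOM Drive Q30, ADMIRE 5", "low", 3.43, 2.78),
    DoseRow("GE Discovery CT750 HD Standard, ASiR-V 100%", "low", 4.23, 3.43),
    DoseRow("GE Revolution Apex Standard, ASiR-V 100%", "low", 3.23, 2.62),
    DoseRow("GE Revolution CT Standard, ASiR-V 100%", "low", 3.24, 2.62),
    DoseRow("Philips Brilliance iCT B (Standard), iDose 6", "low", 3.50, 2.85),
    DoseRow("Canon Aquilion Precision AiCE body standard", "low", 3.05, 2.47),
]

#: Standard-dose CTDIvol (mGy) on the reference scanner, the baseline that
#: the headline percent reductions are computed against.
STANDARD_DOSE_CTDI = 7.32


def _stats(rows: dict[str, tuple[float, float]]) -> list[ROIStats]:
    return [ROIStats.from_mean_sd(lbl, mean, sd) for lbl, (mean, sd) in rows.items()]


def force_reference_record() -> ProtocolRecord:
    """Reference-standard low-dose protocol with its printed metric set."""
    return ProtocolRecord(
        meta=ProtocolMeta(scanner_label="Siemens SOMATOM Force",
                          recon_label="ADMIRE 5", ctdi_vol=2.22),
        roi_stats=_stats({
            "air": (-1002.3, 15.4),
            "water_vial_1": (3.8, 26.2),
            "water_vial_2": (3.4, 24.6),
            "lung_sample_A": (-655.6, 131.5),
            "phantom_lung_foam": (-629.2, 33.3),
            "nist4": (-934.0, 18.8),
            "nist8": (-883.1, 17.4),
            "nist12": (-821.4, 21.1),
            "nist14": (-778.1, 21.1),
            "nist20": (-683.0, 19.7),
        }),
        laa=[LAAResult("lung_sample_A", 2.7, 5.3)],
        mtf_summary={"in_plane": {"f50": 3.63, "f20": 5.48},
                     "z": {"f50": 3.47, "f20": 5.70}},
    )


def drive_candidate_records() -> list[ProtocolRecord]:
    """The four Drive CTDIvol x iterative-reconstruction candidates."""

    def rec(recon, ctdi, rows, mtf, laa950, laa856):
        return ProtocolRecord(
            meta=ProtocolMeta(scanner_label="Siemens SOMATOM Drive",
                              recon_label=recon, ctdi_vol=ctdi),
            roi_stats=_stats(rows),
            laa=[LAAResult("lung_sample_A", laa950, laa856)],
            mtf_summary=mtf,
        )

    return [
        rec("ADMIRE 3", 2.40, {
            "air": (-984.9, 23.4),
            "water_vial_1": (-3.2, 37.2),
            "water_vial_2": (-7.3, 35.7),
            "lung_sample_A": (-636.4, 131.5),
            "phantom_lung_foam": (-614.4, 40.6),
            "nist4": (-902.2, 34.5),
            "nist8": (-857.7, 33.5),
            "nist12": (-758.4, 32.4),
            "nist14": (-800.0, 33.0),
            "nist20": (-662.3, 35.5),
        }, {"in_plane": {"f50": 3.67, "f20": 5.35},
            "z": {"f50": 3.35, "f20": 5.35}}, 1.4, 4.9),
        rec("ADMIRE 5", 2.40, {
            "air": (-987.7, 17.0),
            "water_vial_1": (-3.4, 26.2),
            "water_vial_2": (-7.2, 25.0),
            "lung_sample_A": (-636.5, 128.4),
            "phantom_lung_foam": (-613.6, 32.7),
            "nist4": (-901.6, 23.8),
            "nist8": (-857.5, 22.3),
            "nist12": (-758.6, 21.2),
            "nist14": (-800.0, 21.9),
            "nist20": (-662.4, 23.9),
        }, {"in_plane": {"f50": 3.87, "f20": 5.60},
            "z": {"f50": 3.35, "f20": 5.46}}, 1.3, 5.0),
        rec("ADMIRE 3", 3.43, {
            "air": (-987.6, 21.7),
            "water_vial_1": (-0.9, 32.7),
            "water_vial_2": (-1.6, 30.0),
            "lung_sample_A": (-638.1, 131.2),
            "phantom_lung_foam": (-614.1, 38.0),
            "nist4": (-901.6, 27.0),
            "nist8": (-861.1, 24.6),
            "nist12": (-758.9, 24.2),
            "nist14": (-804.1, 26.1),
            "nist20": (-664.5, 29.7),
        }, {"in_plane": {"f50": 3.61, "f20": 5.36},
            "z": {"f50": 3.44, "f20": 5.55}}, 1.5, 5.1),
        rec("ADMIRE 5", 3.43, {
            "air": (-989.7, 15.8),
            "water_vial_1": (-1.2, 22.4),
            "water_vial_2": (-1.8, 20.5),
            "lung_sample_A": (-638.3, 128.5),
            "phantom_lung_foam": (-613.3, 31.4),
            "nist4": (-900.9, 18.2),
            "nist8": (-860.9, 16.2),
            "nist12": (-759.1, 15.8),
            "nist14": (-804.0, 17.2),
            "nist20": (-664.5, 19.8),
        }, {"in_plane": {"f50": 3.82, "f20": 5.59},
            "z": {"f50": 3.46, "f20": 5.67}}, 1.3, 5.2),
    ]
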