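"""Mismatch volume/ratio computation and the treatment-decision rules.

The perfusion-diffusion mismatch is the part of the hypoperfused (TTP)
lesion not contained in the DWI core.  Imaging eligibility for thrombolysis
uses the classic rule: mismatch volume > 10 mL AND mismatch ratio > 1.2
(strict inequalities).  Two ratio conventions coexist in the stroke
literature and both are implemented:

``pwi_over_dwi``
    TTP-lesion volume / DWI-core volume — the convention of the trials the
    1.2 threshold comes from (default).
``mismatch_over_core``
    mismatch volume / DWI-core volume.

The contraindication screen follows the AHA-style list (blood pressure, INR,
anticoagulants, hemorrhage, treatment window); it is reported *separately*
from imaging eligibility, never fused into a single verdict, because the two
are weighed hierarchically in clinical practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .image_io import GeometryError, PatientRecord, mask_volume_mL
from .lesion_segmentation import LesionMask
from .preprocess import Laterality

RATIO_CONVENTIONS = ("pwi_over_dwi", "mismatch_over_core")


@dataclass
class MismatchResult:
    dwi_volume_mL: float
    ttp_volume_mL: float
    mismatch_volume_mL: float
    mismatch_ratio: float  # may be math.inf (empty core, nonzero numerator) or NaN (0/0)
    ratio_convention: str
    side: Optional[str] = None

    def to_dict(self) -> dict:
        ratio = self.mismatch_ratio
        if math.isinf(ratio):
            ratio_out = "inf"
        elif isinstance(ratio, float) and math.isnan(ratio):
            ratio_out = None
        else:
            ratio_out = float(ratio)
        return {
            "dwi_volume_mL": float(self.dwi_volume_mL),
            "ttp_volume_mL": float(self.ttp_volume_mL),
            "mismatch_volume_mL": float(self.mismatch_volume_mL),
            "mismatch_ratio": ratio_out,
            "ratio_convention": self.ratio_convention,
            "side": self.side,
        }


@dataclass
class EligibilityDecision:
    eligible: bool
    volume_threshold_mL: float
    ratio_threshold: float
    contraindications: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "eligible": self.eligible,
            "volume_threshold_mL": self.volume_threshold_mL,
            "ratio_threshold": self.ratio_threshold,
            "contraindications": list(self.contraindications),
        }


def mismatch_ratio(
    dwi_volume_mL: float, ttp_volume_mL: float, mismatch_volume_mL: float, convention: str
) -> float:
    """Ratio under the chosen convention; empty core with a nonzero numerator
    yields +inf, 0/0 yields NaN (neither passes a strict threshold)."""
    if convention not in RATIO_CONVENTIONS:
        raise ValueError(f"unknown ratio convention {convention!r}; use one of {RATIO_CONVENTIONS}")
    num = ttp_volume_mL if convention == "pwi_over_dwi" else mismatch_volume_mL
    if dwi_volume_mL > 0:
        return num / dwi_volume_mL
    return math.inf if num > 0 else math.nan


def compute_mismatch(
    ttp_lesion: LesionMask,
    dwi_lesion: LesionMask,
    convention: str = "pwi_over_dwi",
    side: Optional[Laterality | str] = None,
) -> MismatchResult:
    """Mismatch mask = TTP lesion AND NOT DWI core; volumes and ratio.

    Volume conservation holds exactly:
    volume(mismatch) + volume(TTP intersect DWI) = volume(TTP lesion).
    """
    ttp_lesion.mask.check_same_grid(dwi_lesion.mask, "TTP and DWI lesion masks")
    mm_binary = ttp_lesion.mask.data & ~dwi_lesion.mask.data
    mm_vol = float(np.count_nonzero(mm_binary)) * ttp_lesion.mask.voxel_volume_mL
    ratio = mismatch_ratio(dwi_lesion.volume_mL, ttp_lesion.volume_mL, mm_vol, convention)
    if isinstance(side, Laterality):
        side = side.side
    return MismatchResult(
        dwi_volume_mL=dwi_lesion.volume_mL,
        ttp_volume_mL=ttp_lesion.volume_mL,
        mismatch_volume_mL=mm_vol,
        mismatch_ratio=ratio,
        ratio_convention=convention,
        side=side,
    )


def mismatch_mask(ttp_lesion: LesionMask, dwi_lesion: LesionMask) -> LesionMask:
    """The mismatch region itself as a mask (TTP lesion minus DWI core)."""
    ttp_lesion.mask.check_same_grid(dwi_lesion.mask, "TTP and DWI lesion masks")
    binary = ttp_lesion.mask.data & ~dwi_lesion.mask.data
    return LesionMask.from_binary(binary, ttp_lesion.mask, "TTP")


def imaging_eligibility(
    m: MismatchResult,
    volume_threshold_mL: float = 10.0,
    ratio_threshold: float = 1.2,
) -> EligibilityDecision:
    """Imaging-only eligibility: mismatch volume AND ratio must strictly
    exceed their thresholds (a value exactly at a threshold fails)."""
    eligible = (
        m.mismatch_volume_mL > volume_threshold_mL and m.mismatch_ratio > ratio_threshold
    )
    return EligibilityDecision(
        eligible=bool(eligible),
        volume_threshold_mL=volume_threshold_mL,
        ratio_threshold=ratio_threshold,
    )


# (flag name, record field, predicate on a known value)
_SCREEN = (
    ("hypertension_systolic", "sbp", lambda v: v > 185),
    ("hypertension_diastolic", "dbp", lambda v: v > 110),
    ("intracranial_hemorrhage", "hemorrhage", lambda v: bool(v)),
    ("anticoagulant_use", "anticoagulant", lambda v: bool(v)),
    ("inr_elevated", "inr", lambda v: v > 1.7),
)


def check_contraindications(p: PatientRecord, window_h: float = 4.5) -> list[str]:
    """Screen a patient record against the contraindication list.

    Criteria (strict inequalities): systolic BP > 185 mmHg, diastolic BP >
    110 mmHg, intracranial hemorrhage, anticoagulant use, INR > 1.7, symptom
    onset to treatment > ``window_h`` hours.  An unknown field yields an
    ``unassessable:<field>`` flag — never a silent pass.
    """
    flags: list[str] = []
    for name, attr, pred in _SCREEN:
        v = getattr(p, attr)
        if v is None:
            flags.append(f"unassessable:{attr}")
        elif pred(v):
            flags.append(name)
    ott = p.onset_to_treatment_h
    if ott is None:
        flags.append("unassessable:onset_to_treatment_h")
    elif ott > window_h:
        flags.append("beyond_window")
    return flags


def contraindication_count(flags: list[str]) -> int:
    """Number of definite contraindications (unassessable flags excluded)."""
    return sum(1 for f in flags if not f.startswith("unassessable:"))
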