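"""End-to-end case assessment: maps -> brain mask -> laterality ->
segmentation -> mismatch -> eligibility and contraindication screen.

This is the orchestration the ``assess`` command runs; it is also the entry
point used for phantom-recovery validation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional

from . import __version__
from .config import RunConfig
from .image_io import DSCSeries, PatientRecord, VolumeImage
from .lesion_segmentation import LesionMask, segment_dwi_lesion, segment_ttp_lesion
from .mismatch_decision import (
    EligibilityDecision,
    MismatchResult,
    check_contraindications,
    compute_mismatch,
    imaging_eligibility,
    mismatch_mask,
)
from .param_maps import compute_adc, compute_ttp, signal_to_concentration
from .preprocess import BrainMask, Laterality, compute_brain_mask, detect_laterality

log = logging.getLogger(__name__)


@dataclass
class CaseAssessment:
    brain: BrainMask
    laterality: Laterality
    adc: VolumeImage
    ttp: VolumeImage
    dwi_lesion: LesionMask
    ttp_lesion: LesionMask
    mismatch_lesion: LesionMask
    mismatch: MismatchResult
    eligibility: EligibilityDecision
    contraindications: Optional[list[str]]
    stage_seconds: dict

    def report(self, config: RunConfig) -> dict:
        """Audit-ready JSON report: volumes, decision, thresholds, config hash."""
        return {
            "software": {"name": "strokemismatch", "version": __version__},
            "config": config.to_dict(),
            "config_hash": config.hash,
            "laterality": {
                "side": self.laterality.side,
                "asymmetry_score": self.laterality.asymmetry_score,
            },
            "mismatch": self.mismatch.to_dict(),
            "eligibility": self.eligibility.to_dict(),
            "contraindications": self.contraindications,
            "stage_seconds": self.stage_seconds,
        }


def assess_case(
    b0: VolumeImage,
    b1000: VolumeImage,
    dsc: DSCSeries,
    config: Optional[RunConfig] = None,
    record: Optional[PatientRecord] = None,
    side: Optional[str] = None,
) -> CaseAssessment:
    """Run the full automated mismatch pipeline on one co-registered case.

    ``side`` overrides automatic laterality detection (required when the
    case is too symmetric for the detector).  When ``record`` is None the
    contraindication section of the result is None (unassessable as a
    whole); imaging eligibility is still computed.
    """
    config = config or RunConfig()
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 4)
                log.info("stage %-12s %6.2f s", name, timings[name])

        return _T()

    with _stage("maps"):
        adc = compute_adc(b0, b1000, b=config.b_value)
        conc = signal_to_concentration(dsc)
        ttp = compute_ttp(conc, dsc.tr, template=b0)
    with _stage("brain_mask"):
        brain = compute_brain_mask(b0, closing_radius=config.closing_radius)
    with _stage("laterality"):
        if side is not None:
            laterality = Laterality(side=side, asymmetry_score=float("nan"))
        else:
            laterality = detect_laterality(
                adc, ttp, brain, min_score=config.min_laterality_score
            )
    params = config.segmentation_params()
    with _stage("segmentation"):
        dwi_lesion = segment_dwi_lesion(b1000, adc, brain, laterality, params)
        ttp_lesion = segment_ttp_lesion(ttp, brain, laterality, params)
    with _stage("decision"):
        mm = compute_mismatch(
            ttp_lesion, dwi_lesion, convention=config.ratio_convention, side=laterality
        )
        mm_mask = mismatch_mask(ttp_lesion, dwi_lesion)
        decision = imaging_eligibility(
            mm,
            volume_threshold_mL=config.volume_threshold_mL,
            ratio_threshold=config.ratio_threshold,
        )
        contra = (
            None if record is None else check_contraindications(record, config.window_h)
        )
    return CaseAssessment(
        brain=brain,
        laterality=laterality,
        adc=adc,
        ttp=ttp,
        dwi_lesion=dwi_lesion,
        ttp_lesion=ttp_lesion,
        mismatch_lesion=mm_mask,
        mismatch=mm,
        eligibility=decision,
        contraindications=contra,
        stage_seconds=timings,
    )
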