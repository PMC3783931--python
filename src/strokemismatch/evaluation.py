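"""Validation statistics: confusion matrices, classification metrics,
volumetric agreement, mismatch salvage and group comparisons.

These operations compare the automated eligibility decision against actual
treatment (or against human raters), summarise volumetric agreement by
Spearman correlation and Bland-Altman limits, and compare decision and
outcome variables between the confusion-matrix groups with a rank-sum test.
Undefined quantities (zero denominators, constant inputs, empty groups) are
explicit ``None`` markers, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import GeometryError
from .lesion_segmentation import LesionMask

CELLS = ("tp", "tn", "fp", "fn")


@dataclass
class ConfusionMatrix:
    """2x2 agreement table between a predicted and a reference decision.

    tp: both say treat; tn: both say supportive; fp: predicted treat but
    reference supportive; fn: predicted supportive but reference treat.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    reference_label: str = "actual treatment"

    def __post_init__(self) -> None:
        for cell in CELLS:
            if getattr(self, cell) < 0:
                raise ValueError(f"confusion counts must be >= 0, got {cell}={getattr(self, cell)}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in CELLS} | {
            "total": self.total,
            "reference_label": self.reference_label,
        }


@dataclass
class Metrics:
    """Sensitivity/specificity/PPV/NPV as percentages; None where undefined."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def rounded(self) -> dict:
        """Integer-percent rendering (reporting style for papers)."""
        return {
            k: (None if v is None else int(round(v)))
            for k, v in self.__dict__.items()
        }

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def build_confusion(
    predicted: Sequence[bool],
    actual: Sequence[bool],
    reference_label: str = "actual treatment",
) -> ConfusionMatrix:
    """Count agreement cells from aligned per-patient decision flags."""
    if len(predicted) != len(actual):
        raise ValueError(
            f"predicted ({len(predicted)}) and actual ({len(actual)}) lengths differ"
        )
    if len(predicted) == 0:
        raise ValueError("cannot build a confusion matrix from empty decision lists")
    for name, flags in (("predicted", predicted), ("actual", actual)):
        for f in flags:
            if f is None or not isinstance(f, (bool, np.bool_)):
                raise ValueError(f"{name} flags must be booleans with no unknowns, got {f!r}")
    p = np.asarray(predicted, dtype=bool)
    a = np.asarray(actual, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & a)),
        tn=int(np.sum(~p & ~a)),
        fp=int(np.sum(p & ~a)),
        fn=int(np.sum(~p & a)),
        reference_label=reference_label,
    )


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def classification_metrics(cm: ConfusionMatrix) -> Metrics:
    """sens = TP/(TP+FN); spec = TN/(TN+FP); PPV = TP/(TP+FP); NPV = TN/(TN+FN)."""
    return Metrics(
        sensitivity=_pct(cm.tp, cm.tp + cm.fn),
        specificity=_pct(cm.tn, cm.tn + cm.fp),
        ppv=_pct(cm.tp, cm.tp + cm.fp),
        npv=_pct(cm.tn, cm.tn + cm.fn),
    )


@dataclass
class AgreementSummary:
    """Spearman correlation plus Bland-Altman agreement for paired volumes."""

    spearman_rho: Optional[float]
    mean_difference_mL: float
    sd_difference_mL: float
    limits_of_agreement_mL: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "mean_difference_mL": self.mean_difference_mL,
            "sd_difference_mL": self.sd_difference_mL,
            "limits_of_agreement_mL": list(self.limits_of_agreement_mL),
            "n": self.n,
        }


def volumetric_agreement(vols_a: Sequence[float], vols_b: Sequence[float]) -> AgreementSummary:
    """Spearman rank correlation (average ranks on ties) and Bland-Altman
    statistics on the differences a - b; limits are mean +/- 2 SD.

    rho is None when either vector is constant (ranks undefined).
    """
    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("volume lists must be 1D and equal length")
    if a.size < 3:
        raise ValueError("agreement statistics need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        rho = None
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementSummary(
        spearman_rho=rho,
        mean_difference_mL=mean,
        sd_difference_mL=sd,
        limits_of_agreement_mL=(mean - 2 * sd, mean + 2 * sd),
        n=int(a.size),
    )


@dataclass
class SalvageResult:
    salvage_mL: float
    acute_mismatch_mL: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def mismatch_salvage(acute_mismatch: LesionMask, followup_infarct: LesionMask) -> SalvageResult:
    """Salvaged tissue: the part of the acute mismatch that is NOT infarcted
    on follow-up imaging.  salvage + volume(mismatch AND infarct) equals the
    acute mismatch volume exactly."""
    acute_mismatch.mask.check_same_grid(followup_infarct.mask, "mismatch and follow-up masks")
    saved = acute_mismatch.mask.data & ~followup_infarct.mask.data
    vol = float(np.count_nonzero(saved)) * acute_mismatch.mask.voxel_volume_mL
    return SalvageResult(salvage_mL=vol, acute_mismatch_mL=acute_mismatch.volume_mL)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney two-sided test for a difference in medians.

    Exact enumeration when both groups have <= 20 observations and there are
    no ties; normal approximation with continuity correction otherwise.
    Returns (U statistic for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if max(x.size, y.size) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


#: variables summarised per confusion-matrix group
GROUP_VARIABLES = ("mismatch_mL", "salvage_mL", "nihss_acute", "delta_nihss")


def _quartiles(values: np.ndarray) -> dict:
    """median and 25th/75th percentiles (linear interpolation), or None markers."""
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {"median": None, "q25": None, "q75": None, "n": 0}
    q25, med, q75 = np.percentile(values, [25, 50, 75], method="linear")
    return {"median": float(med), "q25": float(q25), "q75": float(q75), "n": int(values.size)}


def group_summary(cohort: pd.DataFrame) -> dict:
    """Median and IQR of decision/outcome variables per confusion-matrix cell.

    ``cohort`` needs a ``cell`` column in {tp, tn, fp, fn} plus (any of)
    ``mismatch_mL``, ``salvage_mL``, ``nihss_acute``, ``nihss_24h``.
    delta_nihss = nihss_acute - nihss_24h (positive = improvement).
    """
    if "cell" not in cohort.columns:
        raise ValueError("cohort frame needs a 'cell' column")
    df = cohort.copy()
    if "nihss_acute" in df.columns and "nihss_24h" in df.columns:
        df["delta_nihss"] = df["nihss_acute"] - df["nihss_24h"]
    out: dict = {}
    for cell in CELLS:
        grp = df[df["cell"] == cell]
        summ = {}
        for var in GROUP_VARIABLES:
            if var in df.columns:
                summ[var] = _quartiles(grp[var].to_numpy(dtype=float))
        out[cell] = summ
    return out
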