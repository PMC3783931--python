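"""Synthetic acute-stroke MRI phantom and cohort generator with known truth.

The imaging phantom emulates a two-hemisphere brain (ellipsoid) carrying an
ischemic core (reduced ADC, DWI hyperintensity) nested inside a larger
hypoperfused region (delayed gamma-variate bolus arrival in the DSC series).
All ground-truth masks and volumes are returned alongside the noisy images,
so the full pipeline can be validated against construction.

The cohort generator produces per-patient clinical records and mismatch
results consistent with each cell of the decision confusion matrix
(tp/tn/fp/fn), for exercising the evaluation layer at cohort scale.

Everything is driven by a single integer seed; the same seed reproduces the
outputs bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .image_io import DSCSeries, PatientRecord, VolumeImage, mask_volume_mL
from .lesion_segmentation import LesionMask
from .mismatch_decision import (
    MismatchResult,
    check_contraindications,
    contraindication_count,
    imaging_eligibility,
    mismatch_ratio,
)

#: lesion ellipsoids are oblate: through-plane semi-axis is this fraction of in-plane
_LESION_FLATTENING = 0.6
#: brain semi-axes as a fraction of the field of view per axis
_BRAIN_FRACTION = (0.42, 0.42, 0.40)
#: gamma-variate bolus shape (dimensionless) and time constant (s)
_GAMMA_ALPHA = 3.0
_GAMMA_BETA = 1.5
#: peak fractional signal drop of the bolus in normally perfused tissue
_PEAK_DROP = 0.4
_BASELINE_SIGNAL = 1000.0


@dataclass
class PhantomConfig:
    """Acquisition and lesion parameters of the stroke phantom.

    Defaults mirror a typical acute perfusion protocol: TR 1.5 s, TE 30 ms,
    128-ish in-plane matrix downsampled to 64 with 5 mm slices, b=0/1000
    diffusion pair, normal ADC 0.9e-3 mm^2/s vs core 0.5e-3 mm^2/s, DWI
    hyperintensity factor 1.6, 5% Gaussian signal noise.
    """

    shape: tuple[int, int, int] = (64, 64, 20)
    spacing: tuple[float, float, float] = (3.0, 3.0, 5.0)
    side: str = "right"  # "left" | "right" | "none"
    core_volume_mL: float = 20.0
    hypo_volume_mL: float = 100.0
    ttp_delay_s: float = 6.0
    adc_normal: float = 0.9e-3
    adc_core: float = 0.5e-3
    dwi_hyper_factor: float = 1.6
    noise_sd: float = 0.05  # relative to baseline signal
    b_value: float = 1000.0
    tr: float = 1.5
    te: float = 0.03
    n_timepoints: int = 40
    n_baseline: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "none"):
            raise ValueError(f"side must be left/right/none, got {self.side!r}")
        if self.side != "none":
            if self.core_volume_mL < 0 or self.hypo_volume_mL < 0:
                raise ValueError("lesion volumes must be non-negative")
            if self.core_volume_mL > self.hypo_volume_mL > 0:
                raise ValueError(
                    "core volume must not exceed the hypoperfused volume in nested mode"
                )


@dataclass
class PhantomTruth:
    """Ground-truth masks and volumes, taken before noise is added."""

    brain: VolumeImage
    core: VolumeImage
    hypoperfusion: VolumeImage
    core_volume_mL: float
    hypo_volume_mL: float
    side: str


@dataclass
class StrokePhantom:
    b0: VolumeImage
    b1000: VolumeImage
    dsc: DSCSeries
    truth: PhantomTruth
    record: PatientRecord
    config: PhantomConfig


def _grid_coords(shape, spacing) -> list[np.ndarray]:
    """Physical mm coordinates per axis, centred on the grid (midline at 0)."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def _lesion_mask_exact(
    volume_mL: float,
    center: tuple[float, float, float],
    coords: list[np.ndarray],
    allowed: np.ndarray,
    voxel_volume_mL: float,
) -> np.ndarray:
    """Near-ellipsoidal mask of exactly round(volume/voxel) voxels.

    Voxels inside ``allowed`` are ranked by anisotropic distance from the
    lesion centre (in-plane isotropic, flattened through-plane) and the
    closest ones are taken, so the constructed volume matches the request to
    within half a voxel.
    """
    n_target = int(round(volume_mL / voxel_volume_mL))
    if n_target == 0:
        return np.zeros_like(allowed, dtype=bool)
    n_avail = int(np.count_nonzero(allowed))
    if n_target > n_avail:
        raise ValueError(
            f"requested lesion volume {volume_mL:.1f} mL exceeds the available "
            f"hemisphere volume {n_avail * voxel_volume_mL:.1f} mL"
        )
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    d2 = (
        (xx - center[0]) ** 2
        + (yy - center[1]) ** 2
        + ((zz - center[2]) / _LESION_FLATTENING) ** 2
    )
    d2 = np.where(allowed, d2, np.inf)
    flat_order = np.argsort(d2, axis=None, kind="stable")[:n_target]
    mask = np.zeros(d2.size, dtype=bool)
    mask[flat_order] = True
    return mask.reshape(d2.shape)


def _gamma_bolus(t: np.ndarray, arrival: float) -> np.ndarray:
    """Normalised gamma-variate concentration curve, peak value 1.

    g(t) = (tau/(alpha*beta))^alpha * exp(alpha - tau/beta) with
    tau = t - arrival, zero before arrival; the peak sits at
    arrival + alpha*beta seconds.
    """
    tau = np.asarray(t, dtype=float) - arrival
    scaled = np.clip(tau / (_GAMMA_ALPHA * _GAMMA_BETA), 0.0, None)
    return np.where(
        tau > 0,
        scaled**_GAMMA_ALPHA * np.exp(_GAMMA_ALPHA - np.clip(tau, 0.0, None) / _GAMMA_BETA),
        0.0,
    )


def generate_stroke_phantom(cfg: PhantomConfig | None = None) -> StrokePhantom:
    """Build the full synthetic case: DWI pair, DSC series, truth, record.

    The brain is an ellipsoid centred on the grid; the hypoperfused region
    (and its nested core) sit at mid-hemisphere on the requested side.  The
    b=1000 signal follows baseline * exp(-b * ADC) with a T2-style
    hyperintensity factor applied to both diffusion images inside the core
    (so the measured ADC still equals the constructed one).  Each DSC voxel
    curve is a gamma-variate bolus whose arrival is delayed by
    ``ttp_delay_s`` inside the hypoperfused region.  Gaussian noise at
    ``noise_sd`` (relative to baseline) is added to every image; truth masks
    are taken before noise.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    coords = _grid_coords(cfg.shape, cfg.spacing)
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    fov = [n * s for n, s in zip(cfg.shape, cfg.spacing)]
    semi = [f * frac for f, frac in zip(fov, _BRAIN_FRACTION)]
    brain = (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0

    voxel_mL = float(np.prod(cfg.spacing)) / 1000.0
    # lr_axis=0; increasing index moves toward patient-right (left_positive=False)
    if cfg.side == "none":
        hypo = np.zeros_like(brain)
        core = np.zeros_like(brain)
    else:
        sign = 1.0 if cfg.side == "right" else -1.0
        center = (sign * 0.5 * semi[0], 0.0, 0.0)
        hemi = brain & ((xx > 0) if cfg.side == "right" else (xx < 0))
        hypo = _lesion_mask_exact(cfg.hypo_volume_mL, center, coords, hemi, voxel_mL)
        core = _lesion_mask_exact(
            min(cfg.core_volume_mL, cfg.hypo_volume_mL), center, coords, hemi, voxel_mL
        )
        core &= hypo  # nested by construction (same centre, fewer voxels)

    def vol(mask_arr: np.ndarray) -> VolumeImage:
        return VolumeImage(
            mask_arr, cfg.spacing, lr_axis=0, left_positive=False, is_mask=True
        )

    adc = np.where(core, cfg.adc_core, cfg.adc_normal)
    b0_clean = np.where(brain, _BASELINE_SIGNAL, 0.0)
    t2_factor = np.where(core, cfg.dwi_hyper_factor, 1.0)
    b0_clean = b0_clean * t2_factor
    b1000_clean = b0_clean * np.exp(-cfg.b_value * adc)

    # only two distinct arrival times exist, so two template curves suffice
    t = np.arange(cfg.n_timepoints) * cfg.tr
    t0 = cfg.n_baseline * cfg.tr
    conc_peak = -math.log(1.0 - _PEAK_DROP) / cfg.te
    curve_normal = _BASELINE_SIGNAL * np.exp(-cfg.te * conc_peak * _gamma_bolus(t, t0))
    curve_delayed = _BASELINE_SIGNAL * np.exp(
        -cfg.te * conc_peak * _gamma_bolus(t, t0 + cfg.ttp_delay_s)
    )
    dsc_clean = np.zeros(cfg.shape + (cfg.n_timepoints,))
    dsc_clean[brain & ~hypo] = curve_normal
    dsc_clean[hypo] = curve_delayed

    sd = cfg.noise_sd * _BASELINE_SIGNAL
    b0 = b0_clean + rng.normal(0.0, sd, b0_clean.shape)
    b1000 = b1000_clean + rng.normal(0.0, sd, b1000_clean.shape)
    dsc_data = dsc_clean + rng.normal(0.0, sd, dsc_clean.shape)

    truth = PhantomTruth(
        brain=vol(brain),
        core=vol(core),
        hypoperfusion=vol(hypo),
        core_volume_mL=float(np.count_nonzero(core)) * voxel_mL,
        hypo_volume_mL=float(np.count_nonzero(hypo)) * voxel_mL,
        side=cfg.side,
    )
    record = PatientRecord(
        id=f"phantom-{cfg.seed}",
        treated=True,
        sbp=150.0,
        dbp=85.0,
        inr=1.0,
        anticoagulant=False,
        hemorrhage=False,
        onset_to_treatment_h=2.5,
        nihss_acute=11,
        nihss_24h=6,
    )
    mk_vol = lambda d: VolumeImage(d, cfg.spacing, lr_axis=0, left_positive=False)
    return StrokePhantom(
        b0=mk_vol(b0),
        b1000=mk_vol(b1000),
        dsc=DSCSeries(
            dsc_data,
            cfg.spacing,
            tr=cfg.tr,
            te=cfg.te,
            n_baseline=cfg.n_baseline,
            lr_axis=0,
            left_positive=False,
        ),
        truth=truth,
        record=record,
        config=cfg,
    )


def rater_masks_from_truth(
    truth_mask: VolumeImage, n_raters: int = 4, flip_fraction: float = 0.05, seed: int = 0
) -> list[LesionMask]:
    """Simulated expert rater masks: the truth mask with a fraction of
    boundary-agnostic random voxel flips per rater (synthetic stand-ins for
    human outlines)."""
    rng = np.random.default_rng(seed)
    out = []
    base = truth_mask.data.astype(bool)
    for _ in range(n_raters):
        flips = rng.random(base.shape) < flip_fraction
        out.append(LesionMask.from_binary(base ^ flips, truth_mask, "TTP"))
    return out


# cohort generation ----------------------------------------------------------

#: contraindication prevalence per confusion cell (fraction of patients)
DEFAULT_CONTRA_PREVALENCE = {"tp": 0.24, "tn": 0.83, "fp": 0.73, "fn": 0.23}

#: log-normal medians (mL) / spreads for eligible-cell mismatch volumes
_ELIGIBLE_MM = {"tp": (96.0, 0.81), "fp": (73.4, 1.00)}
#: exponential scale (mL) and point-mass-at-zero weight for ineligible cells
_INELIGIBLE_MM = {"tn": (12.0, 0.55), "fn": (2.5, 0.55)}
#: acute NIHSS log-normal medians / spreads per cell
_NIHSS = {"tp": (11.0, 0.5), "tn": (6.0, 0.6), "fp": (8.0, 0.6), "fn": (5.0, 0.5)}
#: 24 h NIHSS improvement (mean, sd) per cell; positive = improvement
_DELTA_NIHSS = {"tp": (5.0, 2.6), "tn": (3.0, 1.5), "fp": (2.0, 1.9), "fn": (1.0, 1.5)}
#: Beta(a, b) salvage fraction of the mismatch per cell
_SALVAGE_BETA = {"tp": (8.0, 2.0), "fp": (8.0, 2.0), "tn": (2.0, 2.0), "fn": (2.0, 2.0)}


@dataclass
class CohortPatient:
    cell: str
    record: PatientRecord
    mismatch: MismatchResult
    salvage_mL: float
    predicted_eligible: bool


def _draw_mismatch_volumes(cell: str, rng: np.random.Generator) -> tuple[float, float, float]:
    """(dwi, ttp, mismatch) volumes in mL consistent with the cell's
    eligibility: tp/fp pass both imaging criteria, tn/fn fail at least one."""
    if cell in _ELIGIBLE_MM:
        median, sigma = _ELIGIBLE_MM[cell]
        mm = 0.0
        while mm <= 10.0:
            mm = float(rng.lognormal(math.log(median), sigma))
        dwi = float(rng.lognormal(math.log(20.0), 0.8))
        # keep the PWI/DWI ratio strictly above 1.2: (dwi+mm)/dwi > 1.2 iff dwi < 5*mm
        dwi = min(dwi, 4.9 * mm)
    else:
        scale, p_zero = _INELIGIBLE_MM[cell]
        mm = 0.0 if rng.random() < p_zero else float(rng.exponential(scale))
        dwi = float(rng.lognormal(math.log(15.0), 0.9))
        if mm > 10.0:
            # volume criterion passes, so the ratio criterion must fail
            dwi = max(dwi, 6.0 * mm)
    return dwi, dwi + mm, mm


def _draw_record(cell: str, idx: int, rng: np.random.Generator,
                 contra_prevalence: dict[str, float]) -> PatientRecord:
    nihss_med, nihss_sig = _NIHSS[cell]
    nihss = int(np.clip(round(rng.lognormal(math.log(nihss_med), nihss_sig)), 0, 42))
    d_mean, d_sd = _DELTA_NIHSS[cell]
    delta = round(rng.normal(d_mean, d_sd))
    nihss_24 = int(np.clip(nihss - delta, 0, 42))

    sbp = float(rng.uniform(120, 180))
    dbp = float(rng.uniform(70, 105))
    inr = float(rng.uniform(0.9, 1.2))
    anticoagulant = False
    onset = float(rng.uniform(1.0, 4.0))
    if rng.random() < contra_prevalence[cell]:
        kind = rng.integers(3)
        if kind == 0:
            onset = float(rng.uniform(5.0, 8.0))
        elif kind == 1:
            sbp = float(rng.uniform(190, 220))
        else:
            anticoagulant = True
            inr = float(rng.uniform(2.0, 3.5))
    return PatientRecord(
        id=f"{cell}-{idx:03d}",
        treated=cell in ("tp", "fn"),
        sbp=sbp,
        dbp=dbp,
        inr=inr,
        anticoagulant=anticoagulant,
        hemorrhage=False,
        onset_to_treatment_h=onset,
        nihss_acute=nihss,
        nihss_24h=nihss_24,
    )


def generate_cohort(
    n: int = 228,
    group_sizes: tuple[int, int, int, int] = (112, 12, 30, 74),
    seed: int = 0,
    contra_prevalence: Optional[dict[str, float]] = None,
) -> list[CohortPatient]:
    """Synthetic patient cohort with prescribed confusion-cell sizes.

    ``group_sizes`` is (tp, tn, fp, fn).  Mismatch volumes, NIHSS scores,
    salvage and contraindication prevalence are drawn per cell around
    realistic group statistics; eligible cells always satisfy mismatch
    volume > 10 mL and ratio > 1.2 and ineligible cells always fail at least
    one criterion, so re-applying the imaging rule recovers the cells
    exactly.
    """
    if sum(group_sizes) != n:
        raise ValueError(f"group sizes {group_sizes} do not sum to n={n}")
    prev = dict(DEFAULT_CONTRA_PREVALENCE)
    if contra_prevalence:
        prev.update(contra_prevalence)
    rng = np.random.default_rng(seed)
    cohort: list[CohortPatient] = []
    for cell, size in zip(("tp", "tn", "fp", "fn"), group_sizes):
        for i in range(size):
            dwi, ttp, mm = _draw_mismatch_volumes(cell, rng)
            ratio = mismatch_ratio(dwi, ttp, mm, "pwi_over_dwi")
            result = MismatchResult(
                dwi_volume_mL=dwi,
                ttp_volume_mL=ttp,
                mismatch_volume_mL=mm,
                mismatch_ratio=ratio,
                ratio_convention="pwi_over_dwi",
            )
            a, b = _SALVAGE_BETA[cell]
            salvage = float(rng.beta(a, b)) * mm
            record = _draw_record(cell, i, rng, prev)
            cohort.append(
                CohortPatient(
                    cell=cell,
                    record=record,
                    mismatch=result,
                    salvage_mL=salvage,
                    predicted_eligible=imaging_eligibility(result).eligible,
                )
            )
    return cohort


def cohort_to_dataframe(cohort: Sequence[CohortPatient]) -> pd.DataFrame:
    """Flat per-patient table (the cohort CSV schema used by the CLI)."""
    rows = []
    for p in cohort:
        flags = check_contraindications(p.record)
        rows.append(
            {
                "id": p.record.id,
                "cell": p.cell,
                "treated": p.record.treated,
                "predicted_eligible": p.predicted_eligible,
                "dwi_mL": p.mismatch.dwi_volume_mL,
                "ttp_mL": p.mismatch.ttp_volume_mL,
                "mismatch_mL": p.mismatch.mismatch_volume_mL,
                "mismatch_ratio": p.mismatch.mismatch_ratio,
                "salvage_mL": p.salvage_mL,
                "nihss_acute": p.record.nihss_acute,
                "nihss_24h": p.record.nihss_24h,
                "contraindication_count": contraindication_count(flags),
            }
        )
    return pd.DataFrame(rows)
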