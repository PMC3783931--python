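"""Parameter-map computation: ADC from the DWI pair, TTP from the DSC series.

ADC comes from the standard two-point monoexponential fit between the b=0 and
b=1000 s/mm^2 acquisitions.  TTP is the time of the contrast-concentration
peak ("tissue curve" peak, equivalently the signal minimum), measured in
seconds from the start of the bolus series on the TR grid.  No deconvolution
is performed: TTP is the only perfusion statistic downstream segmentation
consumes.
"""

from __future__ import annotations

import numpy as np

from .image_io import DSCSeries, GeometryError, VolumeImage


def compute_adc(b0: VolumeImage, b1000: VolumeImage, b: float = 1000.0) -> VolumeImage:
    """Apparent diffusion coefficient map in mm^2/s.

    ADC = ln(S_b0 / S_b) / b per voxel.  Voxels where either signal is
    non-positive (background, noise dropouts) are NaN, never +/-inf.

    Parameters
    ----------
    b0, b1000:
        Diffusion acquisitions at b=0 and at the high b-value, co-registered.
    b:
        The high b-value in s/mm^2 (default 1000).
    """
    b0.check_same_grid(b1000, "DWI b0 and b1000")
    if b <= 0:
        raise ValueError(f"b-value must be positive, got {b}")
    s0 = np.asarray(b0.data, dtype=float)
    s1 = np.asarray(b1000.data, dtype=float)
    valid = (s0 > 0) & (s1 > 0)
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0[valid] / s1[valid]) / b
    return b0.with_data(adc, is_mask=False)


def signal_to_concentration(dsc: DSCSeries) -> np.ndarray:
    """Contrast-concentration time series from DSC signal (units 1/s).

    C(t) = -ln(S(t)/S0)/TE with S0 the per-voxel mean over the first
    ``n_baseline`` time points.  Samples where S(t) <= 0 or S0 <= 0 are NaN.
    """
    s = np.asarray(dsc.data, dtype=float)
    s0 = s[..., : dsc.n_baseline].mean(axis=-1, keepdims=True)
    conc = np.full(s.shape, np.nan)
    valid = (s > 0) & (s0 > 0)
    ratio = np.divide(s, s0, out=np.ones_like(s), where=valid)
    conc[valid] = (-np.log(ratio) / dsc.te)[valid]
    return conc


def compute_ttp(conc: np.ndarray, tr: float, template: VolumeImage | None = None,
                smooth_window: int = 0) -> VolumeImage:
    """Time-to-peak map (s from series start) from a 4D concentration series.

    Per voxel, TTP = argmax_t C(t) * TR.  Plateau ties break to the earliest
    sample (shortest delay, the conservative choice).  Voxels whose curve is
    all-NaN are NaN.  ``smooth_window`` > 1 applies a centred moving average
    along time before the argmax (off by default).
    """
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 4 or conc.shape[-1] < 2:
        raise GeometryError("concentration series must be 4D with >= 2 time points")
    if tr <= 0:
        raise ValueError(f"TR must be positive, got {tr}")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        finite = np.isfinite(conc)
        filled = np.where(finite, conc, 0.0)
        num = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, filled)
        den = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, finite.astype(float)
        )
        conc = np.where(den > 0, num / np.maximum(den, 1e-30), np.nan)
    all_nan = np.all(~np.isfinite(conc), axis=-1)
    safe = np.where(np.isfinite(conc), conc, -np.inf)
    idx = np.argmax(safe, axis=-1)  # first occurrence wins: earliest-peak tie rule
    ttp = idx.astype(float) * tr
    ttp[all_nan] = np.nan
    if template is not None:
        return template.with_data(ttp, is_mask=False)
    return VolumeImage(ttp, (1.0, 1.0, 1.0))
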