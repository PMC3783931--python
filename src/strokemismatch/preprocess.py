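"""Whole-brain masking and lesion-laterality detection.

The brain mask excludes non-brain structures (background, eyes, detached
artefacts) by Otsu thresholding of the b=0 diffusion image followed by
morphological closing, largest-connected-component selection and hole
filling.

Laterality is decided by comparing the two hemispheres on the ADC and TTP
maps: the affected hemisphere shows delayed TTP and reduced ADC.  The two
asymmetries are fused after robust (median/IQR) normalisation; when the
combined score is below a minimum the result is explicitly *undetermined*
and downstream segmentation refuses to run without an explicit side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .image_io import GeometryError, VolumeImage


class LateralityError(RuntimeError):
    """Raised when lesion laterality cannot be determined automatically."""


@dataclass
class BrainMask:
    mask: VolumeImage
    n_voxels: int

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * self.mask.voxel_volume_mL


@dataclass
class Laterality:
    """Detected lesion side; ``side`` is None when undetermined."""

    side: Optional[str]  # "left" | "right" | None
    asymmetry_score: float

    @property
    def determined(self) -> bool:
        return self.side is not None


def compute_brain_mask(
    b0: VolumeImage,
    closing_radius: int = 2,
    threshold: Optional[float] = None,
) -> BrainMask:
    """Whole-brain mask from the b=0 diffusion image.

    Otsu threshold (overridable) -> binary; 3D morphological closing with a
    ball of ``closing_radius`` voxels; keep the largest connected component;
    fill interior holes.
    """
    data = np.asarray(b0.data, dtype=float)
    finite = data[np.isfinite(data)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ValueError("cannot compute a brain mask from a constant volume")
    thr = float(threshold_otsu(finite)) if threshold is None else float(threshold)
    binary = np.nan_to_num(data, nan=-np.inf) > thr
    if closing_radius > 0:
        binary = ndimage.binary_closing(binary, structure=ball(closing_radius))
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("brain mask is empty after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    binary = labels == largest
    binary = ndimage.binary_fill_holes(binary)
    mask = b0.with_data(binary, is_mask=True)
    return BrainMask(mask=mask, n_voxels=int(np.count_nonzero(binary)))


def lr_bounding_interval(brain: BrainMask) -> tuple[int, int]:
    """(lo, hi) inclusive index bounds of the brain mask along the LR axis."""
    axis = brain.mask.lr_axis
    proj = np.any(brain.mask.data, axis=tuple(a for a in range(3) if a != axis))
    idx = np.nonzero(proj)[0]
    return int(idx[0]), int(idx[-1])


def hemisphere_masks(brain: BrainMask) -> dict[str, np.ndarray]:
    """Boolean hemisphere partitions of the brain mask, keyed 'left'/'right'.

    The midline is the geometric mid-plane of the brain bounding box along
    the left-right axis; voxels exactly on an integer midline index belong to
    neither hemisphere.
    """
    vol = brain.mask
    lo, hi = lr_bounding_interval(brain)
    mid = (lo + hi) / 2.0
    idx = np.arange(vol.shape[vol.lr_axis])
    shape = [1, 1, 1]
    shape[vol.lr_axis] = -1
    idx = idx.reshape(shape)
    high = (idx > mid) & vol.data
    low = (idx < mid) & vol.data
    if vol.left_positive:
        return {"left": high, "right": low}
    return {"left": low, "right": high}


def _iqr(values: np.ndarray) -> float:
    lo, hi = np.nanpercentile(values, [25, 75])
    return float(hi - lo)


def detect_laterality(
    adc: VolumeImage,
    ttp: VolumeImage,
    brain: BrainMask,
    min_score: float = 0.1,
    tail_quantile: float = 0.98,
) -> Laterality:
    """Detect which hemisphere carries the lesion from ADC and TTP asymmetry.

    A focal lesion occupies a minority of its hemisphere, so central
    statistics barely move; the detector therefore compares the *tails* of
    the hemisphere distributions.  For each hemisphere h, with the other
    hemisphere o and q = ``tail_quantile``:

        a_TTP(h) = Q_q(TTP_h) - Q_q(TTP_o)           (delay is positive)
        a_ADC(h) = Q_{1-q}(ADC_o) - Q_{1-q}(ADC_h)   (ADC drop is positive)

    score(h) = a_TTP/s_TTP + a_ADC/s_ADC, with s_* the across-brain
    interquartile range of each map (robust scale).  The side maximising the
    score wins; a maximum below ``min_score`` yields an undetermined result
    (side=None) rather than a guess.
    """
    adc.check_same_grid(brain.mask, "ADC and brain mask")
    ttp.check_same_grid(brain.mask, "TTP and brain mask")
    hemis = hemisphere_masks(brain)
    brain_vox = brain.mask.data

    s_ttp = max(_iqr(np.where(brain_vox, ttp.data, np.nan)), 1e-12)
    s_adc = max(_iqr(np.where(brain_vox, adc.data, np.nan)), 1e-12)

    q_hi = 100.0 * tail_quantile
    q_lo = 100.0 * (1.0 - tail_quantile)
    tails = {}
    for side, hemi in hemis.items():
        ttp_h = np.where(hemi, ttp.data, np.nan)
        adc_h = np.where(hemi, adc.data, np.nan)
        tails[side] = (
            float(np.nanpercentile(ttp_h, q_hi)),
            float(np.nanpercentile(adc_h, q_lo)),
        )
    scores = {}
    for side in ("left", "right"):
        other = "right" if side == "left" else "left"
        a_ttp = tails[side][0] - tails[other][0]
        a_adc = tails[other][1] - tails[side][1]
        scores[side] = a_ttp / s_ttp + a_adc / s_adc
    best = max(scores, key=lambda s: scores[s])
    if scores[best] < min_score:
        return Laterality(side=None, asymmetry_score=float(scores[best]))
    return Laterality(side=best, asymmetry_score=float(scores[best]))
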