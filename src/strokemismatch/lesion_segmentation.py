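"""Lesion delineation against a mirrored contralateral reference.

The ischemic core is outlined on the high-b-value DWI image (hyperintense
relative to the mirrored contralateral neighbourhood AND low ADC, guarding
against T2 shine-through); the hypoperfused lesion is outlined on the TTP
map (delay above the contralateral reference).  Both use the same reference
construction and the same morphological cleanup, applied in a fixed order:
threshold -> opening -> minimum-cluster removal -> hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .image_io import GeometryError, VolumeImage, mask_volume_mL
from .preprocess import BrainMask, Laterality, LateralityError, hemisphere_masks, lr_bounding_interval


@dataclass
class SegmentationParams:
    """Thresholds and morphology knobs for lesion delineation.

    k:
        DWI hyperintensity threshold in contralateral SDs above the mirrored
        reference mean.
    adc_max:
        Upper ADC bound (mm^2/s) for core inclusion; the conventional acute
        infarct cutoff 620e-6 is the default.
    tau_s:
        Minimum TTP delay (s) over the contralateral reference for
        hypoperfusion.
    neighborhood:
        Edge length (voxels) of the cubic contralateral neighbourhood used
        for reference statistics.
    min_cluster_mL:
        Connected components smaller than this are removed.
    opening_radius:
        Ball radius (voxels) of the binary opening; 0 disables it.
    allow_midline_crossing:
        If False (default) lesion masks are clipped to the affected
        hemisphere.
    """

    k: float = 2.0
    adc_max: float = 620e-6
    tau_s: float = 4.0
    neighborhood: int = 5
    min_cluster_mL: float = 0.2
    opening_radius: int = 1
    allow_midline_crossing: bool = False

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "adc_max": self.adc_max,
            "tau_s": self.tau_s,
            "neighborhood": self.neighborhood,
            "min_cluster_mL": self.min_cluster_mL,
            "opening_radius": self.opening_radius,
            "allow_midline_crossing": self.allow_midline_crossing,
        }


@dataclass
class LesionMask:
    mask: VolumeImage
    volume_mL: float
    modality: str  # "DWI" | "TTP"

    @classmethod
    def from_binary(cls, binary: np.ndarray, template: VolumeImage, modality: str) -> "LesionMask":
        vol = template.with_data(binary.astype(bool), is_mask=True)
        return cls(mask=vol, volume_mL=mask_volume_mL(vol), modality=modality)


def _require_side(side: Laterality) -> str:
    if not side.determined:
        raise LateralityError(
            "lesion laterality is undetermined; pass an explicit side to segment"
        )
    return side.side


def mirror_reference(
    map_vol: VolumeImage,
    brain: BrainMask,
    side: Laterality,
    neighborhood: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel contralateral reference statistics (mean, SD).

    Each voxel in the affected hemisphere is paired with its mirror across
    the brain bounding-box mid-plane along the left-right axis; the reference
    mean and SD are computed over a cubic ``neighborhood`` around the
    mirrored position, restricted to the brain mask.  Voxels whose mirrored
    centre falls outside the brain (or the grid) get NaN reference values.

    Returns two arrays on the map grid; both are NaN outside the affected
    hemisphere.
    """
    map_vol.check_same_grid(brain.mask, "map and brain mask")
    affected = _require_side(side)
    data = np.asarray(map_vol.data, dtype=float)
    valid = brain.mask.data & np.isfinite(data)

    # neighbourhood mean/SD over brain voxels only, via box sums of weights
    size = int(neighborhood)
    w = valid.astype(float)
    x = np.where(valid, data, 0.0)
    cnt = ndimage.uniform_filter(w, size=size, mode="constant")
    m1 = ndimage.uniform_filter(x, size=size, mode="constant")
    m2 = ndimage.uniform_filter(x * x, size=size, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, m1 / cnt, np.nan)
        var = np.where(cnt > 0, m2 / cnt - mean**2, np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))

    # mirror about the bounding-box mid-plane: index j = lo + hi - i
    axis = map_vol.lr_axis
    lo, hi = lr_bounding_interval(brain)
    n = data.shape[axis]
    i = np.arange(n)
    j = lo + hi - i
    inside = (j >= 0) & (j < n)
    j_clipped = np.clip(j, 0, n - 1)

    def _sample(arr: np.ndarray) -> np.ndarray:
        out = np.take(arr, j_clipped, axis=axis)
        bad_shape = [1, 1, 1]
        bad_shape[axis] = n
        out = np.where(inside.reshape(bad_shape), out, np.nan)
        return out

    ref_mean = _sample(mean)
    ref_sd = _sample(sd)
    mirror_in_brain = _sample(brain.mask.data.astype(float)) > 0
    ref_mean = np.where(mirror_in_brain, ref_mean, np.nan)
    ref_sd = np.where(mirror_in_brain, ref_sd, np.nan)

    hemi = hemisphere_masks(brain)[affected]
    ref_mean = np.where(hemi, ref_mean, np.nan)
    ref_sd = np.where(hemi, ref_sd, np.nan)
    return ref_mean, ref_sd


def _opening_structure(spacing: tuple[float, float, float], radius_voxels: int) -> np.ndarray:
    """Spacing-aware structuring element: a ball of physical radius
    ``radius_voxels * min(spacing)`` mm, so thick-slice data is not opened
    more aggressively through-plane than in-plane."""
    r_mm = radius_voxels * min(spacing)
    offsets = [np.arange(-radius_voxels, radius_voxels + 1) * s for s in spacing]
    xx, yy, zz = np.meshgrid(*offsets, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= r_mm**2 + 1e-9


def _cleanup(binary: np.ndarray, template: VolumeImage, params: SegmentationParams) -> np.ndarray:
    """threshold -> opening -> min-cluster removal -> hole filling."""
    out = binary
    if params.opening_radius > 0:
        out = ndimage.binary_opening(
            out, structure=_opening_structure(template.spacing, params.opening_radius)
        )
    labels, n = ndimage.label(out)
    if n:
        min_vox = params.min_cluster_mL / template.voxel_volume_mL
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = 1 + np.nonzero(sizes >= min_vox)[0]
        out = np.isin(labels, keep)
    out = ndimage.binary_fill_holes(out)
    return out


def segment_dwi_lesion(
    b1000: VolumeImage,
    adc: VolumeImage,
    brain: BrainMask,
    side: Laterality,
    params: SegmentationParams | None = None,
) -> LesionMask:
    """Outline the DWI ischemic core in the affected hemisphere.

    A voxel is core iff its b=1000 signal exceeds the mirrored contralateral
    reference mean by ``k`` reference SDs AND its ADC is below ``adc_max``
    (dual criterion: hyperintensity alone can be T2 shine-through).
    """
    params = params or SegmentationParams()
    b1000.check_same_grid(adc, "b1000 and ADC")
    affected = _require_side(side)
    ref_mean, ref_sd = mirror_reference(b1000, brain, side, params.neighborhood)
    with np.errstate(invalid="ignore"):
        crit = (b1000.data > ref_mean + params.k * ref_sd) & (adc.data < params.adc_max)
    crit &= brain.mask.data
    if not params.allow_midline_crossing:
        crit &= hemisphere_masks(brain)[affected]
    binary = _cleanup(crit, b1000, params)
    binary &= brain.mask.data
    return LesionMask.from_binary(binary, b1000, "DWI")


def segment_ttp_lesion(
    ttp: VolumeImage,
    brain: BrainMask,
    side: Laterality,
    params: SegmentationParams | None = None,
) -> LesionMask:
    """Outline the hypoperfused lesion: TTP delay over the contralateral
    reference greater than ``tau_s`` seconds, then the shared cleanup."""
    params = params or SegmentationParams()
    affected = _require_side(side)
    ref_mean, _ = mirror_reference(ttp, brain, side, params.neighborhood)
    with np.errstate(invalid="ignore"):
        crit = (ttp.data - ref_mean) > params.tau_s
    crit &= brain.mask.data
    if not params.allow_midline_crossing:
        crit &= hemisphere_masks(brain)[affected]
    binary = _cleanup(crit, ttp, params)
    binary &= brain.mask.data
    return LesionMask.from_binary(binary, ttp, "TTP")
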