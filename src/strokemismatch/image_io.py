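"""NIfTI image and clinical-record I/O with geometry validation.

All images in a case are required to live on the same voxel grid (the acute
perfusion grid); this module checks geometry instead of registering.  The
in-memory carrier for every 3D map (DWI signal, ADC, TTP, binary masks) is
:class:`VolumeImage`; raw 4D bolus-tracking data is a :class:`DSCSeries`.

Left/right is resolved from the NIfTI orientation codes.  When a file has a
degenerate affine with no identifiable left-right axis the caller must pass
``lr_axis`` explicitly -- the loader never guesses patient orientation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


class GeometryError(ValueError):
    """Raised when image dimensionality, spacing or grid compatibility is invalid."""


class ClinicalDataError(ValueError):
    """Raised when a clinical-record file violates the documented schema."""


@dataclass
class VolumeImage:
    """A 3D scalar volume with voxel spacing and a left-right axis convention.

    Parameters
    ----------
    data:
        3D array.  Signal in arbitrary units, ADC in mm^2/s, TTP in s, or a
        binary mask in {0, 1}.
    spacing:
        Voxel size (dx, dy, dz) in mm; all components must be positive.
    lr_axis:
        Index of the array axis that maps to the patient's left-right
        direction.
    left_positive:
        True if increasing index along ``lr_axis`` moves toward patient-left.
    is_mask:
        If True, ``data`` must contain only values {0, 1}.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    lr_axis: int = 0
    left_positive: bool = False
    is_mask: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(
                f"VolumeImage requires a 3D array, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not math.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise GeometryError(f"spacing must be three positive numbers, got {self.spacing}")
        if not 0 <= self.lr_axis <= 2:
            raise GeometryError(f"lr_axis must be 0, 1 or 2, got {self.lr_axis}")
        if self.is_mask:
            vals = np.unique(self.data[np.isfinite(self.data)])
            if not np.all(np.isin(vals, (0, 1))):
                raise GeometryError("mask volume contains values outside {0, 1}")
            self.data = self.data.astype(bool)

    @property
    def voxel_volume_mL(self) -> float:
        """Volume of one voxel in millilitres (dx*dy*dz / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def check_same_grid(self, other: "VolumeImage", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GeometryError(
                f"{what} are not on the same grid: "
                f"{self.shape}@{self.spacing} vs {other.shape}@{other.spacing}"
            )

    def with_data(self, data: np.ndarray, is_mask: Optional[bool] = None) -> "VolumeImage":
        """New VolumeImage on this grid carrying ``data``."""
        return replace(
            self, data=data, is_mask=self.is_mask if is_mask is None else is_mask
        )

    def flipped_lr(self) -> "VolumeImage":
        """The volume mirrored along the left-right axis (patient-side swap)."""
        return replace(
            self,
            data=np.flip(self.data, axis=self.lr_axis).copy(),
            left_positive=not self.left_positive,
        )


def mask_volume_mL(mask: VolumeImage) -> float:
    """Volume in mL of a binary mask: voxel count times voxel volume."""
    if not mask.is_mask:
        raise GeometryError("mask_volume_mL expects a mask-typed volume")
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mL


@dataclass
class DSCSeries:
    """Raw 4D dynamic susceptibility contrast time series.

    ``data`` has time on the last axis.  TR and TE are in seconds;
    ``n_baseline`` counts the pre-bolus time points used to estimate the
    per-voxel baseline signal.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    tr: float
    te: float
    n_baseline: int
    lr_axis: int = 0
    left_positive: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise GeometryError(
                f"DSCSeries requires a 4D array, got {self.data.ndim} dimensions"
            )
        if self.tr <= 0 or self.te <= 0:
            raise GeometryError(f"TR and TE must be positive, got TR={self.tr}, TE={self.te}")
        n_t = self.data.shape[-1]
        if not 1 <= self.n_baseline < n_t:
            raise GeometryError(
                f"n_baseline must be in [1, {n_t - 1}] for {n_t} time points, "
                f"got {self.n_baseline}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def spatial_template(self) -> VolumeImage:
        """A VolumeImage on this series' spatial grid (zeros), for geometry checks."""
        return VolumeImage(
            np.zeros(self.data.shape[:3]),
            self.spacing,
            lr_axis=self.lr_axis,
            left_positive=self.left_positive,
        )


# scale bounds for clinical scores
_NIHSS_RANGE = (0, 42)
_MRS_RANGE = (0, 6)


@dataclass
class PatientRecord:
    """Clinical variables for contraindication screening and group statistics.

    ``None`` means "unknown": unknown fields are propagated explicitly and a
    screening rule that cannot be assessed reports an ``unassessable:<field>``
    flag rather than silently passing.
    """

    id: str
    treated: bool
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    inr: Optional[float] = None
    anticoagulant: Optional[bool] = None
    hemorrhage: Optional[bool] = None
    onset_to_treatment_h: Optional[float] = None
    nihss_acute: Optional[int] = None
    nihss_24h: Optional[int] = None
    nihss_3m: Optional[int] = None
    mrs_3m: Optional[int] = None

    def __post_init__(self) -> None:
        for name, rng in (
            ("nihss_acute", _NIHSS_RANGE),
            ("nihss_24h", _NIHSS_RANGE),
            ("nihss_3m", _NIHSS_RANGE),
            ("mrs_3m", _MRS_RANGE),
        ):
            v = getattr(self, name)
            if v is not None and not rng[0] <= v <= rng[1]:
                raise ClinicalDataError(f"{name}={v} outside scale range {rng}")
        for name in ("sbp", "dbp", "inr"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ClinicalDataError(f"{name}={v} must be positive")
        if self.onset_to_treatment_h is not None and self.onset_to_treatment_h < 0:
            raise ClinicalDataError("onset_to_treatment_h must be non-negative")


def _affine_from_volume(vol: VolumeImage) -> np.ndarray:
    """Diagonal affine encoding spacing and the left-right axis direction.

    The LR array axis is mapped to world x; patient-left at increasing index
    gives a negative x direction (radiological-style), so that NIfTI
    orientation codes round-trip through :func:`read_volume`.
    """
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    other_axes = [a for a in range(3) if a != vol.lr_axis]
    sign = -1.0 if vol.left_positive else 1.0
    aff[0, vol.lr_axis] = sign * vol.spacing[vol.lr_axis]
    aff[1, other_axes[0]] = vol.spacing[other_axes[0]]
    aff[2, other_axes[1]] = vol.spacing[other_axes[1]]
    return aff


def _resolve_lr_axis(affine: np.ndarray) -> tuple[Optional[int], bool]:
    """(lr_axis, left_positive) from NIfTI orientation, or (None, ...) if absent."""
    try:
        codes = nib.orientations.aff2axcodes(affine)
    except Exception:  # degenerate affine
        return None, False
    for axis, code in enumerate(codes):
        if code in ("L", "R"):
            return axis, code == "L"
    return None, False


def write_volume(vol: VolumeImage, path: PathLike) -> None:
    """Write a VolumeImage as NIfTI-1; masks are stored as uint8."""
    data = vol.data.astype(np.uint8) if vol.is_mask else np.asarray(vol.data, dtype=np.float64)
    img = nib.Nifti1Image(data, _affine_from_volume(vol))
    nib.save(img, str(path))


def read_volume(
    path: PathLike,
    lr_axis: Optional[int] = None,
    is_mask: bool = False,
) -> VolumeImage:
    """Read a 3D NIfTI-1 volume.

    Spacing is taken from the header; the left-right axis is resolved from the
    header orientation unless ``lr_axis`` is given.  A 4D file is rejected --
    use :func:`read_dsc` for time series.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise GeometryError(
            f"{path} has {img.ndim} dimensions; expected a 3D volume "
            "(use read_dsc for 4D time series)"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise GeometryError(f"{path} has non-positive voxel spacing {spacing}")
    hdr_axis, left_positive = _resolve_lr_axis(img.affine)
    if lr_axis is None:
        if hdr_axis is None:
            raise GeometryError(
                f"{path}: orientation header does not identify a left-right axis; "
                "pass lr_axis explicitly"
            )
        lr_axis = hdr_axis
    data = np.asarray(img.get_fdata())
    return VolumeImage(
        data, spacing, lr_axis=lr_axis, left_positive=left_positive, is_mask=is_mask
    )


def write_dsc(series: DSCSeries, path: PathLike) -> None:
    """Write a DSCSeries as 4D NIfTI-1 with TR recorded in the time zoom."""
    template = series.spatial_template()
    aff = _affine_from_volume(template)
    img = nib.Nifti1Image(np.asarray(series.data, dtype=np.float64), aff)
    img.header.set_zooms(series.spacing + (series.tr,))
    nib.save(img, str(path))


def read_dsc(
    path: PathLike,
    tr: float,
    te: float,
    n_baseline: int,
    lr_axis: Optional[int] = None,
) -> DSCSeries:
    """Read a 4D DSC NIfTI-1 series.

    TR and TE are taken from the arguments, overriding the header: NIfTI
    timing metadata is unreliable across scanners.  A mismatch with the
    header's time step is logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise GeometryError(f"{path} has {img.ndim} dimensions; expected a 4D series")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if len(zooms) > 3 and zooms[3] > 0 and not math.isclose(zooms[3], tr, rel_tol=1e-3):
        log.warning(
            "%s: header time step %.4g s differs from TR argument %.4g s; using the argument",
            path, zooms[3], tr,
        )
    hdr_axis, left_positive = _resolve_lr_axis(img.affine)
    if lr_axis is None:
        if hdr_axis is None:
            raise GeometryError(
                f"{path}: orientation header does not identify a left-right axis; "
                "pass lr_axis explicitly"
            )
        lr_axis = hdr_axis
    return DSCSeries(
        np.asarray(img.get_fdata()),
        spacing,
        tr=tr,
        te=te,
        n_baseline=n_baseline,
        lr_axis=lr_axis,
        left_positive=left_positive,
    )


# clinical-record schema ------------------------------------------------------

_MANDATORY_FIELDS = ("id", "treated", "sbp", "dbp")
_BOOL_FIELDS = ("treated", "anticoagulant", "hemorrhage")
_FLOAT_FIELDS = ("sbp", "dbp", "inr", "onset_to_treatment_h")
_INT_FIELDS = ("nihss_acute", "nihss_24h", "nihss_3m", "mrs_3m")
_ALL_FIELDS = ("id",) + _BOOL_FIELDS[:1] + _FLOAT_FIELDS + _BOOL_FIELDS[1:] + _INT_FIELDS

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f"}


def _parse_bool(value, field_name: str) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s == "":
        return None
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ClinicalDataError(f"cannot interpret {field_name}={value!r} as a flag")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _record_from_mapping(row: dict, index: int) -> PatientRecord:
    for f in _MANDATORY_FIELDS:
        if f not in row or _is_missing(row[f]):
            raise ClinicalDataError(
                f"record {index}: mandatory field '{f}' is missing or blank"
            )
    kwargs = {"id": str(row["id"])}
    for f in _BOOL_FIELDS:
        kwargs[f] = _parse_bool(row.get(f), f)
    for f in _FLOAT_FIELDS:
        v = row.get(f)
        kwargs[f] = None if _is_missing(v) else float(v)
    for f in _INT_FIELDS:
        v = row.get(f)
        kwargs[f] = None if _is_missing(v) else int(round(float(v)))
    return PatientRecord(**kwargs)


def read_clinical(path: PathLike) -> list[PatientRecord]:
    """Read patient records from CSV or JSON.

    Both encodings use the same field names (``id, treated, sbp, dbp, inr,
    anticoagulant, hemorrhage, onset_to_treatment_h, nihss_acute, nihss_24h,
    nihss_3m, mrs_3m``).  Missing optional fields become ``None`` (unknown);
    a missing mandatory field (id, treated, sbp, dbp) is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such clinical file: {path}")
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise ClinicalDataError("JSON clinical file must contain a list of records")
    else:
        df = pd.read_csv(path, dtype={"id": str})
        rows = df.to_dict(orient="records")
    return [_record_from_mapping(row, i) for i, row in enumerate(rows)]


def write_clinical(records: Sequence[PatientRecord], path: PathLike) -> None:
    """Write patient records to CSV or JSON, matching the read_clinical schema."""
    path = Path(path)
    rows = []
    for r in records:
        row = {f: getattr(r, f) for f in _ALL_FIELDS}
        rows.append(row)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows, columns=list(_ALL_FIELDS)).to_csv(path, index=False)
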