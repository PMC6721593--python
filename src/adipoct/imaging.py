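"""Volumetric image containers and NIfTI I/O with physical units.

CT volumes carry Hounsfield units (HU), PET volumes carry standardized
uptake values (SUV) or raw activity concentration (Bq/mL).  All geometry is
expressed in world millimetres with 0-based voxel indices addressed at the
voxel *center*: the world coordinate of voxel ``i`` along an axis is
``origin + i * spacing``.  Axis 0 is the left-right axis, so the sagittal
midline is a plane of constant axis-0 coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, UnitError, ValidationError

VALID_UNITS = ("HU", "SUV", "Bq/mL")


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = tuple(float(v) for v in np.atleast_1d(value))
    if len(arr) != 3:
        raise ValidationError(f"{name} must have exactly 3 components, got {len(arr)}")
    return arr  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3-D scalar grid with spacing, origin and a declared physical unit."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "HU"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3-D, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValidationError("values grid is empty")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing_mm must be strictly positive, got {self.spacing_mm}")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable per-axis world-coordinate arrays (open meshgrid)."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def same_geometry(self, other: "ImageVolume | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass
class BinaryMask:
    """A boolean grid sharing an :class:`ImageVolume`'s geometry."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got ndim={self.values.ndim}")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing_mm must be strictly positive")

    @classmethod
    def like(cls, vol: ImageVolume, values: np.ndarray) -> "BinaryMask":
        values = np.asarray(values)
        if values.shape != vol.shape:
            raise ValidationError(
                f"mask shape {values.shape} does not match volume shape {vol.shape}"
            )
        return cls(values=values, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.spacing_mm[axis]


# ---------------------------------------------------------------------------
# NIfTI I/O.  The unit travels in a JSON sidecar keyed by the image filename
# because NIfTI-1 has no standard slot for HU-vs-SUV semantics.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_name(name + ".json")


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz) with a unit sidecar."""
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"unit": vol.unit}))
    return path


def read_volume(path: str | Path, unit: str | None = None) -> ImageVolume:
    """Read a NIfTI-1 volume; the unit comes from the sidecar unless given."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises a zoo of types for bad headers
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D image, got ndim={data.ndim} in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if unit is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            unit = json.loads(sidecar.read_text()).get("unit")
        if unit is None:
            raise UnitError(
                f"no unit sidecar found for {path}; pass unit= explicitly"
            )
    return ImageVolume(values=data, spacing_mm=spacing, origin_mm=origin, unit=unit)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    vol = ImageVolume(
        values=mask.values.astype(np.uint8),
        spacing_mm=mask.spacing_mm,
        origin_mm=mask.origin_mm,
        unit="HU",  # placeholder unit; masks are dimensionless
    )
    return write_volume(vol, path)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path, unit="HU")
    return BinaryMask(values=vol.values > 0.5, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


def to_suv(activity: ImageVolume, body_weight_kg: float, injected_dose_mbq: float) -> ImageVolume:
    """Convert an activity-concentration map (Bq/mL) to body-weight SUV.

    SUV = activity[Bq/mL] * weight[kg] * 1000 / (dose[MBq] * 1e6); decay
    correction is assumed to have been applied upstream by the scanner.
    """
    if activity.unit != "Bq/mL":
        raise UnitError(f"expected unit 'Bq/mL', got {activity.unit!r}")
    if body_weight_kg <= 0:
        raise ValidationError("body_weight_kg must be positive")
    if injected_dose_mbq <= 0:
        raise ValidationError("injected_dose_MBq must be positive")
    suv = activity.values * body_weight_kg * 1000.0 / (injected_dose_mbq * 1e6)
    return ImageVolume(
        values=suv, spacing_mm=activity.spacing_mm, origin_mm=activity.origin_mm, unit="SUV"
    )
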