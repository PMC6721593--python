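"""Image measurements: tumor-anchored and mirrored VOIs, adipose masking,
the four adipose-attenuation parameters, SUVmax and metabolic tumor volume.

The measurement model follows the clinical protocol the package emulates:
a spheroid volume-of-interest (VOI) covering the tumor plus a 10 mm shell
of surrounding tissue, a mirror VOI of identical size reflected across the
sagittal midline onto the contralateral breast, and a fat window of
[-200, -50] HU (inclusive at both ends) selecting adipose voxels inside
each VOI.  TAT HU / CAT HU are the mean attenuations of those selections;
HU difference = TAT - CAT and HU difference % = (CAT - TAT) / CAT * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InsufficientAdiposeError, UnitError, ValidationError
from .imaging import BinaryMask, ImageVolume

FAT_WINDOW_HU = (-200.0, -50.0)


@dataclass(frozen=True)
class SpheroidVOI:
    """Axis-aligned ellipsoid in world millimetres.

    A point p is inside iff sum_i ((p_i - c_i) / a_i)^2 <= 1.
    """

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))
        object.__setattr__(self, "semi_axes_mm", tuple(float(v) for v in self.semi_axes_mm))
        if len(self.center_mm) != 3 or len(self.semi_axes_mm) != 3:
            raise ValidationError("center_mm and semi_axes_mm must have 3 components")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError(f"semi-axes must be positive, got {self.semi_axes_mm}")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """Membership test for an (n, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        q = ((pts - np.asarray(self.center_mm)) / np.asarray(self.semi_axes_mm)) ** 2
        return q.sum(axis=1) <= 1.0 + 1e-12

    def membership(self, vol: ImageVolume | BinaryMask) -> np.ndarray:
        """Boolean grid of voxels whose *centers* fall inside the spheroid."""
        q = np.zeros(vol.shape, dtype=float)
        for axis in range(3):
            coords = vol.axis_coords(axis)
            term = ((coords - self.center_mm[axis]) / self.semi_axes_mm[axis]) ** 2
            shape = [1, 1, 1]
            shape[axis] = -1
            q = q + term.reshape(shape)
        return q <= 1.0 + 1e-12


@dataclass(frozen=True)
class AdiposeParams:
    """The four adipose-attenuation readouts of one case."""

    tat_hu: float
    cat_hu: float
    hu_difference: float
    hu_difference_pct: float


@dataclass(frozen=True)
class MeasurementRecord:
    adipose: AdiposeParams
    suv_max: float
    mtv_cm3: float
    n_fat_voxels_tumor_side: int
    n_fat_voxels_contralateral: int

    def to_dict(self) -> dict:
        return {
            "tat_hu": self.adipose.tat_hu,
            "cat_hu": self.adipose.cat_hu,
            "hu_difference": self.adipose.hu_difference,
            "hu_difference_pct": self.adipose.hu_difference_pct,
            "suv_max": self.suv_max,
            "mtv_cm3": self.mtv_cm3,
            "n_fat_voxels_tumor_side": self.n_fat_voxels_tumor_side,
            "n_fat_voxels_contralateral": self.n_fat_voxels_contralateral,
        }


def tumor_voi(tumor_mask: BinaryMask, margin_mm: float = 10.0) -> SpheroidVOI:
    """Smallest-inflation spheroid covering the tumor plus a margin shell.

    The mask is dilated by a ball of radius ``margin_mm`` (in world mm, so
    anisotropic grids dilate correctly), the VOI is centered on the dilated
    bounding box, semi-axes start at the half-extents and are scaled by the
    minimal common factor s >= 1 so that every dilated voxel center satisfies
    the ellipsoid membership inequality.  Containment is therefore exact.
    """
    if margin_mm < 0:
        raise ValidationError("margin_mm must be nonnegative")
    if tumor_mask.count == 0:
        raise ValidationError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(
        ~tumor_mask.values, sampling=tumor_mask.spacing_mm
    )
    dilated = dist <= margin_mm
    idx = np.argwhere(dilated)
    pts = np.asarray(tumor_mask.origin_mm) + idx * np.asarray(tumor_mask.spacing_mm)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    # Degenerate axes (single-slice masks) are floored at half a voxel.
    half = np.maximum(half, np.asarray(tumor_mask.spacing_mm) / 2.0)
    q = (((pts - center) / half) ** 2).sum(axis=1)
    s = max(1.0, float(np.sqrt(q.max())))
    return SpheroidVOI(center_mm=tuple(center), semi_axes_mm=tuple(s * half))


def mirror_voi(voi: SpheroidVOI, midline_x_mm: float) -> SpheroidVOI:
    """Reflect a VOI across the sagittal midplane; size is preserved."""
    cx, cy, cz = voi.center_mm
    return SpheroidVOI(
        center_mm=(2.0 * midline_x_mm - cx, cy, cz), semi_axes_mm=voi.semi_axes_mm
    )


def adipose_mask(
    ct: ImageVolume,
    voi: SpheroidVOI,
    hu_lo: float = FAT_WINDOW_HU[0],
    hu_hi: float = FAT_WINDOW_HU[1],
) -> BinaryMask:
    """Select VOI voxels in the fat window (endpoints inclusive)."""
    if ct.unit != "HU":
        raise UnitError(f"adipose_mask needs a CT in HU, got unit {ct.unit!r}")
    inside = voi.membership(ct)
    if not inside.any():
        raise GeometryError("VOI does not intersect the image grid")
    selected = inside & (ct.values >= hu_lo) & (ct.values <= hu_hi)
    return BinaryMask.like(ct, selected)


def mean_attenuation(
    ct: ImageVolume,
    mask: BinaryMask,
    min_voxels: int = 10,
    side: str | None = None,
) -> float:
    """Mean HU over masked voxels; errors out below ``min_voxels``.

    The voxel floor operationalizes the clinical exclusion of cases with
    insufficient breast adipose tissue for a stable measurement.
    """
    if ct.unit != "HU":
        raise UnitError(f"mean_attenuation needs a CT in HU, got unit {ct.unit!r}")
    n = mask.count
    if n < min_voxels:
        raise InsufficientAdiposeError(
            f"only {n} adipose voxels (< {min_voxels}) in the "
            f"{side or 'requested'} VOI",
            side=side,
        )
    return float(ct.values[mask.values].mean())


def adipose_parameters(tat_hu: float, cat_hu: float) -> AdiposeParams:
    """Apply the two difference formulas to the per-side mean attenuations.

    HU difference = TAT - CAT; HU difference % = (CAT - TAT) / CAT * 100.
    Because fat attenuation is negative, the percent difference carries the
    same sign as the plain difference.
    """
    if cat_hu == 0:
        raise ValidationError("cat_hu = 0 is not a fat attenuation; cannot divide")
    for name, value in (("tat_hu", tat_hu), ("cat_hu", cat_hu)):
        if not (FAT_WINDOW_HU[0] <= value <= FAT_WINDOW_HU[1]):
            raise ValidationError(
                f"{name} = {value} HU lies outside the fat window {FAT_WINDOW_HU}"
            )
    diff = tat_hu - cat_hu
    pct = (cat_hu - tat_hu) / cat_hu * 100.0
    return AdiposeParams(
        tat_hu=float(tat_hu),
        cat_hu=float(cat_hu),
        hu_difference=float(diff),
        hu_difference_pct=float(pct),
    )


def suv_max(pet: ImageVolume, voi: SpheroidVOI) -> float:
    """Maximum SUV over voxels inside the VOI."""
    if pet.unit != "SUV":
        raise UnitError(f"suv_max needs a PET in SUV, got unit {pet.unit!r}")
    inside = voi.membership(pet)
    if not inside.any():
        raise GeometryError("VOI does not intersect the PET grid")
    return float(pet.values[inside].max())


def metabolic_tumor_volume(
    pet: ImageVolume, voi: SpheroidVOI, suv_threshold: float = 2.50
) -> float:
    """Volume (cm^3) of VOI voxels with SUV at or above the threshold.

    Returns 0.0 when no voxel qualifies, as for tumors whose peak uptake
    stays below the threshold.
    """
    if pet.unit != "SUV":
        raise UnitError(f"metabolic_tumor_volume needs a PET in SUV, got {pet.unit!r}")
    inside = voi.membership(pet)
    if not inside.any():
        raise GeometryError("VOI does not intersect the PET grid")
    n = int((inside & (pet.values >= suv_threshold)).sum())
    return n * pet.voxel_volume_mm3 / 1000.0


def measure_case(
    ct: ImageVolume,
    pet: ImageVolume,
    tumor_mask: BinaryMask,
    midline_x_mm: float,
    margin_mm: float = 10.0,
    hu_lo: float = FAT_WINDOW_HU[0],
    hu_hi: float = FAT_WINDOW_HU[1],
    suv_threshold: float = 2.50,
    min_fat_voxels: int = 10,
) -> MeasurementRecord:
    """Run the full per-case measurement chain on aligned CT/PET/mask."""
    if not ct.same_geometry(pet):
        raise ValidationError("CT and PET grids are not aligned")
    if not ct.same_geometry(tumor_mask):  # type: ignore[arg-type]
        raise ValidationError("CT and tumor mask grids are not aligned")
    voi = tumor_voi(tumor_mask, margin_mm=margin_mm)
    cvoi = mirror_voi(voi, midline_x_mm)
    fat_t = adipose_mask(ct, voi, hu_lo, hu_hi)
    fat_c = adipose_mask(ct, cvoi, hu_lo, hu_hi)
    tat = mean_attenuation(ct, fat_t, min_voxels=min_fat_voxels, side="tumor")
    cat = mean_attenuation(ct, fat_c, min_voxels=min_fat_voxels, side="contralateral")
    adipose = adipose_parameters(tat, cat)
    return MeasurementRecord(
        adipose=adipose,
        suv_max=suv_max(pet, voi),
        mtv_cm3=metabolic_tumor_volume(pet, voi, suv_threshold=suv_threshold),
        n_fat_voxels_tumor_side=fat_t.count,
        n_fat_voxels_contralateral=fat_c.count,
    )
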