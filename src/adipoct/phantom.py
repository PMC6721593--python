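"""Synthetic PET/CT phantoms and survival-cohort simulation.

The phantom is deliberately schematic: two ellipsoidal breasts mirrored
about the sagittal midplane, filled with adipose tissue near -100 HU, a
fibroglandular ellipsoid inside each, and a spherical tumor in one breast.
Fat within a configurable reach of the tumor surface receives a uniform
additive HU shift, emulating the elevated attenuation of cancer-associated
peritumoral adipose tissue.  The PET channel places a uniform uptake peak
at the tumor over a low background.  Ground truth (programmed fat means,
tumor volume, peak SUV) travels with each case so the measurement chain
can be validated end to end.

The cohort simulator draws covariates from configurable marginal
frequencies, gives each patient a contralateral fat attenuation (CAT HU)
and a peritumoral shift whose location depends on T stage and hormone
receptor status, and generates recurrence times from an exponential
proportional-hazards model with administrative censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import GeometryError, ValidationError
from .imaging import BinaryMask, ImageVolume

# ---------------------------------------------------------------------------
# Phantom images
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of one synthetic breast PET/CT case.

    ``fat_hu_sd`` is fat-tissue texture (default 0 so a noise-free phantom
    reproduces programmed means exactly); ``noise_sd_hu``/``noise_sd_suv``
    are additive scanner noise over the whole grid.
    """

    grid_shape: tuple[int, int, int] = (100, 64, 24)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 5.0)  # clinical 5 mm slices
    breast_offset_mm: float = 26.0  # midline to breast center, per side
    breast_semi_axes_mm: tuple[float, float, float] = (22.0, 26.0, 45.0)
    gland_semi_axes_mm: tuple[float, float, float] = (8.0, 10.0, 16.0)
    gland_offset_mm: tuple[float, float, float] = (0.0, 12.0, 0.0)
    fat_hu_mean: float = -100.0
    fat_hu_sd: float = 0.0
    gland_hu_mean: float = 30.0
    tumor_center_mm: tuple[float, float, float] | None = None  # default: breast center
    tumor_radius_mm: float = 6.0
    tumor_hu_mean: float = 40.0
    peritumoral_delta_hu: float = 10.0
    peritumoral_reach_mm: float = 13.0
    tumor_suv_peak: float = 8.44
    background_suv: float = 0.5
    air_hu: float = -1000.0
    noise_sd_hu: float = 0.0
    noise_sd_suv: float = 0.0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if any(n < 2 for n in self.grid_shape):
            raise ValidationError("grid_shape must be at least 2 voxels per axis")
        if not (-200.0 <= self.fat_hu_mean <= -50.0):
            raise ValidationError(
                f"fat_hu_mean {self.fat_hu_mean} outside the fat window [-200, -50]"
            )
        if self.peritumoral_reach_mm < 10.0:
            raise ValidationError(
                "peritumoral_reach_mm must be >= 10 so the measurement shell "
                "samples shifted fat"
            )
        if self.tumor_radius_mm <= 0:
            raise ValidationError("tumor_radius_mm must be positive")
        if min(self.fat_hu_sd, self.noise_sd_hu, self.noise_sd_suv) < 0:
            raise ValidationError("noise standard deviations must be nonnegative")


@dataclass(frozen=True)
class PhantomTruth:
    """Programmed ground truth of a phantom case."""

    tat_hu: float  # fat mean inside the peritumoral reach
    cat_hu: float  # fat mean elsewhere (contralateral)
    tumor_volume_mm3: float  # voxelized tumor volume
    suv_peak: float


@dataclass
class PhantomCase:
    ct: ImageVolume
    pet: ImageVolume
    tumor_mask: BinaryMask
    midline_x_mm: float
    truth: PhantomTruth

    def __post_init__(self):
        if self.tumor_mask.count == 0:
            raise ValidationError("tumor mask is empty")
        if not self.ct.same_geometry(self.pet):
            raise ValidationError("CT and PET geometry differ")


def _ellipsoid(vol_like, center, semi_axes) -> np.ndarray:
    q = np.zeros(vol_like.shape, dtype=float)
    for axis in range(3):
        coords = vol_like.axis_coords(axis)
        term = ((coords - center[axis]) / semi_axes[axis]) ** 2
        shape = [1, 1, 1]
        shape[axis] = -1
        q = q + term.reshape(shape)
    return q <= 1.0


def make_breast_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Build one deterministic phantom case from a spec and a seed."""
    spec.validate()
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing_mm
    template = ImageVolume(
        values=np.zeros(spec.grid_shape, dtype=np.float64),
        spacing_mm=spec.spacing_mm,
        origin_mm=(0.0, 0.0, 0.0),
        unit="HU",
    )
    midline_x = (nx - 1) / 2.0 * dx
    yc = (ny - 1) / 2.0 * dy
    zc = (nz - 1) / 2.0 * dz

    right_center = (midline_x + spec.breast_offset_mm, yc, zc)
    left_center = (midline_x - spec.breast_offset_mm, yc, zc)
    breasts = _ellipsoid(template, right_center, spec.breast_semi_axes_mm) | _ellipsoid(
        template, left_center, spec.breast_semi_axes_mm
    )
    glands = np.zeros(spec.grid_shape, dtype=bool)
    for bc in (right_center, left_center):
        gc = tuple(bc[i] + spec.gland_offset_mm[i] for i in range(3))
        glands |= _ellipsoid(template, gc, spec.gland_semi_axes_mm)
    glands &= breasts

    tumor_center = spec.tumor_center_mm or right_center
    r = spec.tumor_radius_mm
    # Tumor must sit fully inside its breast and not cross the midline.
    if abs(tumor_center[0] - midline_x) < r:
        raise GeometryError("tumor crosses the sagittal midline")
    host = right_center if tumor_center[0] >= midline_x else left_center
    if any(a <= r for a in spec.breast_semi_axes_mm) or sum(
        ((tumor_center[i] - host[i]) / (spec.breast_semi_axes_mm[i] - r)) ** 2
        for i in range(3)
    ) > 1.0:
        raise GeometryError("tumor radius exceeds the breast region")
    tumor = _ellipsoid(template, tumor_center, (r, r, r))

    fat = breasts & ~glands & ~tumor

    ct = np.full(spec.grid_shape, spec.air_hu, dtype=np.float64)
    ct[fat] = spec.fat_hu_mean
    ct[glands & ~tumor] = spec.gland_hu_mean
    ct[tumor] = spec.tumor_hu_mean
    # Peritumoral shift: fat within reach (world mm) of the tumor surface.
    dist = ndimage.distance_transform_edt(~tumor, sampling=spec.spacing_mm)
    shifted = fat & (dist <= spec.peritumoral_reach_mm)
    ct[shifted] += spec.peritumoral_delta_hu
    if spec.fat_hu_sd > 0:
        ct[fat] += rng.normal(0.0, spec.fat_hu_sd, size=int(fat.sum()))
    if spec.noise_sd_hu > 0:
        ct += rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)

    pet = np.full(spec.grid_shape, spec.background_suv, dtype=np.float64)
    pet[tumor] = spec.tumor_suv_peak
    if spec.noise_sd_suv > 0:
        pet += rng.normal(0.0, spec.noise_sd_suv, size=spec.grid_shape)
        np.clip(pet, 0.0, None, out=pet)

    voxvol = dx * dy * dz
    truth = PhantomTruth(
        tat_hu=spec.fat_hu_mean + spec.peritumoral_delta_hu,
        cat_hu=spec.fat_hu_mean,
        tumor_volume_mm3=float(tumor.sum()) * voxvol,
        suv_peak=spec.tumor_suv_peak,
    )
    geom = dict(spacing_mm=spec.spacing_mm, origin_mm=(0.0, 0.0, 0.0))
    return PhantomCase(
        ct=ImageVolume(values=ct, unit="HU", **geom),
        pet=ImageVolume(values=pet, unit="SUV", **geom),
        tumor_mask=BinaryMask(values=tumor, **geom),
        midline_x_mm=midline_x,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Statistical structure of a simulated surgical breast-cancer cohort.

    Covariate frequencies default to the study population the package
    emulates (287 patients; T1/T2/T3 = 47.4/44.6/8.0%, N0 = 66.2%,
    ER+ = 74.2%, PR+ = 61.7%, HER2+ = 49.5%, Ki67+ = 61.7%).  CAT HU is
    Normal(-97.54, 7); the tumor-side shift (TAT - CAT) has a location
    that increases with T stage and with ER/PR negativity, reproducing the
    qualitative group structure of the source population.  Recurrence
    times follow an exponential baseline scaled by exp(sum beta * x) with
    uniform administrative censoring on [6.1, 88.9] months; the baseline
    is calibrated so the expected event fraction matches
    ``target_event_fraction`` unless ``baseline_hazard`` is given.
    """

    n_patients: int = 287
    age_mean: float = 52.0
    age_sd: float = 10.0
    bmi_mean: float = 23.8
    bmi_sd: float = 3.0
    postmenopausal_freq: float = 0.624
    t_stage_freq: tuple[float, float, float] = (0.474, 0.446, 0.080)
    n_stage_freq: tuple[float, float, float, float] = (0.662, 0.202, 0.073, 0.063)
    grade_freq: tuple[float, float, float] = (0.234, 0.497, 0.269)
    er_pos_freq: float = 0.742
    pr_pos_freq: float = 0.617
    her2_pos_freq: float = 0.495
    ki67_pos_freq: float = 0.617
    cat_hu_mean: float = -97.54
    cat_hu_sd: float = 7.0
    # TAT-shift location model: base + T-stage effect + receptor effects.
    delta_base: float = 6.7
    delta_t_effects: tuple[float, float, float] = (0.0, 2.8, 4.8)
    delta_er_neg: float = 2.0
    delta_pr_neg: float = 2.0
    delta_sd: float = 5.5
    # BMI negatively shifts CAT HU (heavier patients have lower fat HU).
    bmi_cat_slope: float = -0.6  # HU per kg/m^2 around the BMI mean
    # Primary-tumor PET parameters, weakly coupled to the shift.
    suv_log_mean: float = math.log(4.0)
    suv_log_sd: float = 0.55
    suv_delta_slope: float = 0.04  # on log SUV per HU of shift
    mtv_log_mean: float = math.log(1.8)
    mtv_log_sd: float = 1.0
    # Hazard model: column -> log hazard ratio per unit.  Categorical
    # levels are addressed as "column=level" (e.g. "t_stage=T3").
    hazard_log_hr: dict = field(default_factory=lambda: {"tat_hu": math.log(1.10)})
    baseline_hazard: float | None = None  # events/month; None -> calibrate
    target_event_fraction: float = 0.105
    censor_low_months: float = 6.1
    censor_high_months: float = 88.9

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be at least 2")
        for name, freqs in (
            ("t_stage_freq", self.t_stage_freq),
            ("n_stage_freq", self.n_stage_freq),
            ("grade_freq", self.grade_freq),
        ):
            if any(not 0 <= f <= 1 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-6:
                raise ValidationError(f"{name} must be probabilities summing to 1")
        for name, f in (
            ("er_pos_freq", self.er_pos_freq),
            ("pr_pos_freq", self.pr_pos_freq),
            ("her2_pos_freq", self.her2_pos_freq),
            ("ki67_pos_freq", self.ki67_pos_freq),
            ("postmenopausal_freq", self.postmenopausal_freq),
        ):
            if not 0 <= f <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if not 0 < self.censor_low_months < self.censor_high_months:
            raise ValidationError("censoring window must be positive and ordered")


def _covariate_column(df: pd.DataFrame, key: str) -> np.ndarray:
    """Resolve a hazard-model key to a numeric column (supports 'col=level')."""
    if "=" in key:
        col, level = key.split("=", 1)
        if col not in df.columns:
            raise ValidationError(f"unknown covariate {col!r}")
        return (df[col].astype(str) == level).to_numpy(dtype=float)
    if key not in df.columns:
        raise ValidationError(f"unknown covariate {key!r}")
    return df[key].to_numpy(dtype=float)


def _expected_event_fraction(lam0: float, rel_hazard: np.ndarray, a: float, b: float) -> float:
    """Mean P(event) under Exp(lam0 * rel) event times and U(a, b) censoring.

    For T ~ Exp(lam), C ~ U(a, b):
    P(T <= C) = 1 - E[exp(-lam C)] = 1 - (exp(-lam a) - exp(-lam b)) / (lam (b - a)).
    """
    lam = lam0 * rel_hazard
    with np.errstate(over="ignore"):
        surv = (np.exp(-lam * a) - np.exp(-lam * b)) / (lam * (b - a))
    return float(1.0 - np.mean(surv))


def simulate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Simulate one cohort; identical (spec, seed) gives an identical table."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_patients

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 30, 85).round(0)
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), 16.0, 36.0).round(1)
    menopausal_post = (rng.random(n) < spec.postmenopausal_freq).astype(int)
    t_stage = rng.choice(["T1", "T2", "T3"], size=n, p=spec.t_stage_freq)
    n_stage = rng.choice(["N0", "N1", "N2", "N3"], size=n, p=spec.n_stage_freq)
    grade = rng.choice([1, 2, 3], size=n, p=spec.grade_freq)
    er = (rng.random(n) < spec.er_pos_freq).astype(int)
    pr = (rng.random(n) < spec.pr_pos_freq).astype(int)
    her2 = (rng.random(n) < spec.her2_pos_freq).astype(int)
    ki67 = (rng.random(n) < spec.ki67_pos_freq).astype(int)
    triple_negative = ((er == 0) & (pr == 0) & (her2 == 0)).astype(int)

    cat_hu = (
        rng.normal(spec.cat_hu_mean, spec.cat_hu_sd, n)
        + spec.bmi_cat_slope * (bmi - spec.bmi_mean)
    )
    cat_hu = np.clip(cat_hu, -200.0, -50.0)
    t_idx = np.searchsorted(["T1", "T2", "T3"], t_stage)
    delta_loc = (
        spec.delta_base
        + np.asarray(spec.delta_t_effects)[t_idx]
        + spec.delta_er_neg * (er == 0)
        + spec.delta_pr_neg * (pr == 0)
    )
    delta = rng.normal(delta_loc, spec.delta_sd)
    tat_hu = np.clip(cat_hu + delta, -200.0, -50.0)
    hu_difference = tat_hu - cat_hu
    hu_difference_pct = (cat_hu - tat_hu) / cat_hu * 100.0

    suv_max = np.exp(
        rng.normal(spec.suv_log_mean, spec.suv_log_sd, n)
        + spec.suv_delta_slope * (hu_difference - np.mean(spec.delta_t_effects))
    )
    suv_max = np.clip(suv_max, 0.5, 40.0)
    mtv = np.where(
        suv_max >= 2.50,
        np.exp(rng.normal(spec.mtv_log_mean, spec.mtv_log_sd, n)),
        0.0,
    )

    df = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "age": age,
            "bmi": bmi,
            "menopausal_post": menopausal_post,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "histologic_grade": grade,
            "er": er,
            "pr": pr,
            "her2": her2,
            "ki67": ki67,
            "triple_negative": triple_negative,
            "cat_hu": cat_hu,
            "tat_hu": tat_hu,
            "hu_difference": hu_difference,
            "hu_difference_pct": hu_difference_pct,
            "suv_max": suv_max,
            "mtv_cm3": mtv,
        }
    )

    # Proportional-hazards event times with centered linear predictor.
    lp = np.zeros(n)
    for key, beta in spec.hazard_log_hr.items():
        x = _covariate_column(df, key)
        lp += beta * (x - x.mean())
    rel = np.exp(lp)
    a, b = spec.censor_low_months, spec.censor_high_months
    if spec.baseline_hazard is None:
        lam0 = optimize.brentq(
            lambda l: _expected_event_fraction(l, rel, a, b) - spec.target_event_fraction,
            1e-8,
            10.0,
            xtol=1e-12,
        )
    else:
        lam0 = spec.baseline_hazard
    event_time = rng.exponential(1.0 / (lam0 * rel))
    censor_time = rng.uniform(a, b, n)
    df["followup_months"] = np.minimum(event_time, censor_time)
    df["recurrence"] = (event_time <= censor_time).astype(int)
    return df


def simulate_reader_pair(
    truth_values, reader_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent noisy reads of each truth value (inter-reader model)."""
    truth = np.asarray(truth_values, dtype=float)
    if truth.size == 0:
        raise ValidationError("truth_values is empty")
    if reader_sd < 0:
        raise ValidationError("reader_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    r1 = truth + rng.normal(0.0, reader_sd, truth.shape)
    r2 = truth + rng.normal(0.0, reader_sd, truth.shape)
    return r1, r2
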