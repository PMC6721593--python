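# Methods

## Measurement model

All geometry is in world millimetres with voxel-center addressing: the
world coordinate of voxel *i* along an axis is `origin + i * spacing`.
Axis 0 is left–right, so the sagittal midline is a plane of constant
axis-0 coordinate; the contralateral VOI is obtained by reflecting the
tumor VOI's center across that plane (`x' = 2·midline − x`), which on an
aligned grid also lands it in the same quadrant of the opposite breast.

**Tumor VOI.** Clinical practice draws the spheroid by hand; this
implementation makes it deterministic. The tumor mask is dilated by a
ball of radius `margin_mm` (default 10 mm, applied in world mm via a
spacing-aware Euclidean distance transform, so anisotropic 1×1×5 mm
grids dilate correctly). The VOI is centered on the dilated bounding
box, semi-axes start at the half-extents (floored at half a voxel for
degenerate axes), and all three are scaled by the minimal common factor
s ≥ 1 such that every dilated voxel center satisfies
Σᵢ((pᵢ−cᵢ)/aᵢ)² ≤ 1. Containment of the dilated tumor is therefore
exact by construction; the price is that on strongly non-spherical
tumors the inflated ellipsoid can reach slightly beyond the dilation.

**Adipose selection and parameters.** Within a VOI, fat is every voxel
whose center lies inside the ellipsoid and whose CT value is in
[−200, −50] HU, *inclusive at both ends* (the clinical definition is
ambiguous at the boundary; inclusivity is chosen and tested there).
Voxel membership is by center point, not partial volume, matching the
default of clinical ROI tools. TAT HU and CAT HU are plain arithmetic
means over the selected voxels; a side falls below `min_voxels`
(default 10) raises an insufficient-adipose error labelled with the
side, mirroring the clinical exclusion of patients without enough
breast fat to measure. The derived parameters are applied exactly as
defined: HU difference = TAT − CAT and
HU difference % = (CAT − TAT)/CAT × 100; because CAT < 0 both carry the
same sign.

**PET measures.** SUVmax is the maximum SUV inside the tumor VOI. MTV is
the volume (cm³) of VOI voxels with SUV ≥ 2.50, threshold inclusive, and
is 0.0 whenever SUVmax < 2.50. `to_suv` converts activity concentration
(Bq/mL) to body-weight SUV (`activity × weight_kg × 1000 / dose_Bq`);
lean-body-mass SUV and decay correction are out of scope (decay
correction is assumed already applied by the scanner).

## Phantom

The phantom is schematic on purpose: two ellipsoidal breasts (semi-axes
22×26×45 mm) mirrored about the midline, fat at `fat_hu_mean`
(default −100 HU), a fibroglandular ellipsoid (+30 HU) inside each,
air at −1000 HU, and a spherical tumor (+40 HU, default radius 6 mm)
at the center of one breast. Fat within `peritumoral_reach_mm` of the
tumor surface is shifted by `peritumoral_delta_hu`. The PET channel is
`background_suv` everywhere except the tumor, which holds
`tumor_suv_peak` uniformly.

Defaults worth noting:

- `spacing_mm = (1, 1, 5)` — clinical 5 mm CT slices; the grid
  (100×64×24 voxels) fully contains both breasts.
- `peritumoral_reach_mm = 13` with a 10 mm VOI margin (and a floor of
  10): the VOI's minimal-inflation ellipsoid can extend marginally past
  the 10 mm dilation on anisotropic grids, so a reach slightly larger
  than the margin guarantees every fat voxel inside the VOI carries the
  programmed shift — noise-free phantoms then reproduce programmed TAT
  and CAT exactly, which the tests assert to 10⁻⁶ HU.
- `fat_hu_sd` (tissue texture, default 0) is separate from
  `noise_sd_hu`/`noise_sd_suv` (additive Gaussian scanner noise over the
  whole grid, default 0). With texture off and noise off the phantom is
  piecewise constant. CT quantum/streak artifacts are not modelled.

Ground truth (programmed TAT/CAT means, voxelized tumor volume, SUV
peak) travels with each case. Geometry is validated: the tumor may not
cross the midline nor poke out of its breast.

## Cohort simulator

Covariates are drawn from marginal frequencies matching the emulated
surgical population (n = 287 default; T1/T2/T3 = 47.4/44.6/8.0%,
N0 = 66.2%, ER+ = 74.2%, PR+ = 61.7%, HER2+ = 49.5%, Ki67+ = 61.7%,
62.4% postmenopausal; age ~ N(52, 10²) clipped to 30–85, BMI ~
N(23.8, 3²)). The triple-negative flag is derived from ER/PR/HER2, so it
is consistent by construction (its marginal rate, ~5%, is lower than the
clinical 11.5% because receptors are drawn independently).

Adipose parameters: CAT HU ~ N(−97.54, 7²) with a −0.6 HU per kg/m²
BMI slope (heavier patients have lower fat attenuation); the tumor-side
shift Δ = TAT − CAT is Normal with sd 5.5 and location
6.7 + {0, 2.8, 4.8} by T stage + 2.0·[ER−] + 2.0·[PR−] — reproducing
the qualitative stage/receptor structure of the clinical group means
without claiming to reconstruct an unreported joint distribution.
SUVmax is lognormal (median 4) with a weak positive link to Δ, and MTV
is lognormal but exactly 0 when SUVmax < 2.50.

**Survival.** Event times are exponential with rate
λ₀·exp(Σβₖ(xₖ − x̄ₖ)); censoring is administrative, uniform on
[6.1, 88.9] months; observed time = min(event, censor). When λ₀ is not
given it is calibrated by root-finding so the cohort's expected event
fraction equals 10.5% (closed form: for T ~ Exp(λ), C ~ U(a,b),
P(T ≤ C) = 1 − (e^{−λa} − e^{−λb})/(λ(b−a))). The default hazard is
driven by TAT HU alone at β = ln 1.10 per HU. Published per-covariate
hazard ratios from a univariate battery are *marginal* estimates;
programming them jointly would double-count shared signal and reproduce
none of them, so the generator drives hazard through the biomarker and
lets stage/receptor associations arise through the Δ-location model.
All randomness flows from one explicit `numpy` seed per call; the
pipeline expands a root seed into per-stage substreams via
`SeedSequence.spawn`.

## Statistics

- **Lin's CCC** with population (1/n) moments; 95% CI by Fisher
  z-transform with Lin's asymptotic variance (the CI method is a package
  choice; degenerate |CCC| = 1 collapses the CI to a point).
- **Paired t**, **Student's t** (two groups, equal-variance),
  **Kruskal–Wallis** with tie correction (≥3 groups) followed by
  **Conover–Iman** pairwise post-hoc when significant (the post-hoc used
  by the MedCalc software family; implemented here as no installed
  package provides it), **Spearman** with average ranks.
- **Cox PH** via lifelines (Efron tie handling, Wald CIs); categorical
  stage/grade expand to treatment-coded dummies (T1/N0/grade-1
  reference, N stage collapsed to N0 vs N1–3). The three adjusted
  models add (1) age+T+N, (2) +ER+PR+Ki67, (3) +SUVmax+MTV to each
  adipose parameter. Tests cross-check coefficients against a
  grid-search partial-likelihood oracle on tie-free fixtures (10⁻³).
- **Kaplan–Meier** product-limit and **log-rank** via lifelines;
  `survival_at(60)` gives 5-year RFS.
- **ROC cutoff**: candidate thresholds at midpoints between consecutive
  distinct scores; maximize Youden J = sensitivity + specificity − 1
  with prediction positive at score ≥ threshold; ties broken toward the
  lower threshold (higher sensitivity). The "optimal cutoff" criterion
  is underdetermined clinically; Youden with midpoint candidates is the
  package's fixed choice.
- **Stratified recurrence table**: T1 vs T2–T3 strata, high/low arms at
  the chosen cutoff, percentages rounded half-up to one decimal,
  Fisher's exact two-sided p per stratum (the clinical table's exact
  test is unnamed; Fisher is used and could differ from a chi-square);
  empty strata are reported as not evaluable ("NE" in markdown output).
- No multiple-testing correction anywhere, mirroring the reporting
  conventions of the analysis the package emulates; p < 0.05.

## Pipeline

`run_study(StudyConfig)` executes simulate → measure → analyze → render.
The imaging stage measures a configurable number of phantom cases
(default 2) and tabulates measured vs programmed truth; the cohort
stage produces the patient table directly (per-patient image synthesis
at n = 287 would add nothing — the imaging chain is validated on the
phantom stage). Outputs are CSV per table, one markdown report and a
JSON summary, all embedding the SHA-256 config hash; identical
config + seed gives byte-identical reports. Real, pre-measured cohort
CSVs can be analyzed with the same battery (`adipoct analyze`),
skipping the imaging stages.

## Problem sizes and verification

The test suite validates hand-computable examples exactly, properties
(monotonicity of MTV in its threshold, mirror involution, containment,
seed determinism) on small grids, and stochastic behavior at cohort
sizes of 200–8000. Hazard-ratio recovery is checked as the mean
univariate Cox HR over 200 cohorts of n = 287 (±0.02 of the programmed
1.10 and 1.12), the problem size at which the Monte-Carlo error of the
mean is ≈0.002 — small against the tolerance while keeping the whole
suite under a minute. `scripts/acceptance.py` re-runs exactly that
recovery from scratch.

## Known limitations

- The phantom's anatomy is geometric; no atlas breasts, no DICOM, no
  scanner physics. Passing tests demonstrate correctness of the
  measurement and analysis chain, not robustness to real-image
  confounds (partial volume at 5 mm slices, motion, contrast spill).
- The cohort's covariate joint distribution is an explicit assumption
  (independent marginals plus the stated Δ-location links), not a
  reconstruction of any real population; cohort-specific clinical
  readouts (specific cutoffs, CCCs, adjusted HRs, 5-year RFS rates)
  are therefore not reproduction targets — only the machinery and the
  programmed-parameter recovery are.
- VOI construction resolves by fiat what clinicians do by hand; the
  minimal-inflation rule is one deterministic answer and a documented
  potential source of deviation from manual measurements.
- CT ↔ PET grids are assumed aligned (the phantom emits aligned grids);
  registration of real data is out of scope.
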