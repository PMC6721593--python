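# adipoct

Quantification of peritumoral breast adipose tissue CT-attenuation on
PET/CT, and its prognostic analysis for recurrence-free survival (RFS) —
exercised entirely on synthetic phantoms and simulated cohorts with known
ground truth.

## The scientific problem

Adipocytes in direct contact with breast cancer cells ("cancer-associated
adipocytes") shrink, lose lipid and fibrose, which *raises* their CT
attenuation. On the non-contrast CT of an FDG PET/CT this is measurable:
draw a spheroid volume-of-interest (VOI) covering the tumor plus a 1-cm
shell of surrounding tissue, mirror a same-sized VOI onto the
contralateral breast, keep only voxels in the adipose window
[−200, −50] HU, and compare mean attenuations:

- **TAT HU** — mean fat attenuation in the tumor-adjacent VOI
- **CAT HU** — mean fat attenuation in the mirrored contralateral VOI
- **HU difference** = TAT − CAT
- **HU difference %** = (CAT − TAT)/CAT × 100 (positive when TAT > CAT,
  since CAT < 0)

Denser tumor-adjacent fat (higher TAT HU, larger differences) marks a
tumor-remodelled microenvironment and predicts worse RFS. The package also
measures the PET tumor markers SUVmax and metabolic tumor volume (MTV,
volume of VOI voxels with SUV ≥ 2.50), and models RFS with Cox
proportional hazards, Kaplan–Meier curves, log-rank tests, ROC/Youden
cutoff selection and a T-stage-stratified recurrence table.

Because no patient images can ship with the code, a first-class phantom
module synthesizes breast PET/CT cases with a programmed peritumoral
fat-attenuation shift, and a cohort simulator generates 287-patient
populations whose covariate frequencies, event fraction (~10.5%) and
per-unit hazard ratios (e.g. 1.10 per HU of TAT HU) match the clinical
population the analysis emulates — so every stage of the pipeline can be
validated against known truth.

## Who it is for

Researchers in quantitative imaging / radiomics who want a tested,
deterministic reference implementation of adipose-attenuation
measurement and its survival analysis, or a calibrated simulation
test-bed for peritumoral-fat biomarker studies.

## Worked example

```python
import adipoct as a

spec = a.PhantomSpec(fat_hu_mean=-108.743, peritumoral_delta_hu=16.28, noise_sd_hu=0.0)
case = a.make_breast_phantom(spec, seed=11)
rec = a.measure_case(case.ct, case.pet, case.tumor_mask, case.midline_x_mm)
```

prints (see `examples/01_phantom_measurement.py`):

```
TAT HU (tumor-adjacent fat mean):     -92.463
CAT HU (contralateral fat mean):     -108.743
HU difference (TAT - CAT):             16.280
HU difference % ((CAT-TAT)/CAT*100):   14.971
SUVmax of the tumor VOI:                 8.44
MTV at SUV >= 2.50 (cm^3):              0.880
```

The noise-free phantom programs contralateral fat at −108.743 HU and a
+16.28 HU peritumoral shift; the full VOI → fat-window → mean chain reads
both back exactly, and the two difference formulas give 16.280 HU and
14.971%. SUVmax equals the programmed uptake peak and MTV equals the
voxelized tumor volume.

`examples/02_cohort_survival.py` simulates a cohort whose hazard is driven
by TAT HU at a programmed hazard ratio of 1.10 per HU and recovers it:

```
patients: 287, recurrences: 32 (11.1%)
univariate Cox, TAT HU (per 1 HU): HR 1.102 (95% CI 1.062-1.143), p = 2.6e-07
Youden-optimal TAT HU cutoff: -89.08 HU (sens 0.91, spec 0.46)
5-year RFS, high-TAT arm (n=166): 80.8%
5-year RFS, low-TAT arm (n=121): 96.8%
log-rank chi2 = 15.6, p = 8e-05
```

Further examples cover inter-reader agreement (Lin's CCC) and the full
config-driven study report (`examples/03`, `examples/04`).

## Command line

A thin CLI wraps the library:

```bash
adipoct simulate --config study.yaml --seed 7 --out sim/      # phantom + cohort
adipoct measure  --ct ct.nii.gz --pet pet.nii.gz --mask m.nii.gz --midline-x 49.5
adipoct analyze  --cohort cohort.csv --out report/            # pre-measured data
adipoct report   --config study.yaml --out report/            # full study
```

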