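"""Simulate a 287-patient cohort and recover the programmed hazard ratio.

The generator drives recurrence through TAT HU with a per-HU hazard ratio
of 1.10, calibrates the exponential baseline to a ~10.5% event fraction,
and censors administratively on [6.1, 88.9] months.  A univariate Cox fit
should estimate a hazard ratio near 1.10.
"""

import math

import adipoct as a

spec = a.CohortSpec(hazard_log_hr={"tat_hu": math.log(1.10)})
cohort = a.simulate_cohort(spec, seed=2019)
print(f"patients: {len(cohort)}, recurrences: {cohort.recurrence.sum()} "
      f"({100 * cohort.recurrence.mean():.1f}%)")

fit = a.cox_regression(cohort, ["tat_hu"])
row = fit.row("tat_hu")
print(f"univariate Cox, TAT HU (per 1 HU): HR {row.hazard_ratio:.3f} "
      f"(95% CI {row.ci_lo:.3f}-{row.ci_hi:.3f}), p = {row.p_value:.2g}")

cut = a.optimal_cutoff(cohort.tat_hu.to_numpy(), cohort.recurrence.to_numpy())
print(f"Youden-optimal TAT HU cutoff: {cut.threshold:.2f} HU "
      f"(sens {cut.sensitivity:.2f}, spec {cut.specificity:.2f})")

high = cohort.tat_hu >= cut.threshold
chi2, p = a.log_rank(cohort.followup_months, cohort.recurrence, high)
for arm, sel in (("high", high), ("low", ~high)):
    km = a.kaplan_meier(cohort.loc[sel, "followup_months"], cohort.loc[sel, "recurrence"])
    print(f"5-year RFS, {arm}-TAT arm (n={km.n}): {100 * km.survival_at(60):.1f}%")
print(f"log-rank chi2 = {chi2:.1f}, p = {p:.2g}")
# Denser tumor-adjacent fat carries a worse recurrence-free prognosis;
# the gap between the arms' 5-year RFS quantifies that stratification.
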