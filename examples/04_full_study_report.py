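"""Run the full config-driven study and render report tables.

Simulates a cohort, validates the imaging chain on phantom cases, runs
the complete statistical battery and writes CSV/markdown/JSON tables to
an output directory.
"""

import adipoct as a

config = a.StudyConfig(seed=20190808, out_dir="scratch/example_report")
report = a.run_study(config)

print(f"config hash: {report.config_hash}")
print(f"patients: {report.summary['n_patients']}, "
      f"events: {report.summary['n_events']} "
      f"({100 * report.summary['event_fraction']:.1f}%)")
print(f"TAT HU cutoff chosen by ROC: {report.summary['tat_hu_cutoff']:.2f} HU")
print("\nstage-stratified recurrence (high vs low TAT HU):")
print(report.tables["stratified_recurrence"].to_string(index=False))
print(f"\ntables written to {config.out_dir}")
# Each table mirrors one stage of the analysis: baseline characteristics,
# adipose-parameter group comparisons, univariate/multivariate Cox fits,
# ROC cutoffs with Kaplan-Meier stratification, and recurrence rates by
# T stage and TAT HU arm.
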