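"""Config-driven orchestration of the full study flow.

``run_study`` simulates (or ingests) a cohort, optionally exercises the
imaging chain on a few phantom cases, runs the statistical battery and
renders report tables: a baseline-characteristics table, adipose-parameter
group comparisons, univariate and multivariate Cox tables, ROC cutoffs
with Kaplan-Meier stratification, and the stage-stratified recurrence
table.  A single root seed is expanded into per-stage substreams so stage
reruns stay consistent, and the config hash is embedded in every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import quantify as qt
from . import stats as st
from .errors import ValidationError

log = logging.getLogger("adipoct")

ADIPOSE_PARAMS = ["tat_hu", "cat_hu", "hu_difference", "hu_difference_pct"]

# Univariate covariate battery (cohort column or derived contrast).
UNIVARIATE_COVARIATES = [
    "age",
    "bmi",
    "menopausal_post",
    "t_stage",
    "n_stage",
    "histologic_grade",
    "er",
    "pr",
    "her2",
    "ki67",
    "triple_negative",
    "suv_max",
    "mtv_cm3",
    "tat_hu",
    "cat_hu",
    "hu_difference",
    "hu_difference_pct",
]


@dataclass
class StudyConfig:
    seed: int = 20190808
    cohort: ph.CohortSpec = field(default_factory=ph.CohortSpec)
    phantom: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    n_imaging_cases: int = 2
    reader_sd_hu: float = 2.0
    fat_window_hu: tuple[float, float] = (-200.0, -50.0)
    suv_threshold: float = 2.50
    voi_margin_mm: float = 10.0
    min_fat_voxels: int = 10
    km_horizon_months: float = 60.0
    out_dir: str | None = None

    def validate(self) -> None:
        lo, hi = self.fat_window_hu
        if not (-1000 < lo < hi < 500):
            raise ValidationError(f"fat window {self.fat_window_hu} is not physical")
        if self.suv_threshold < 0 or self.voi_margin_mm < 0:
            raise ValidationError("thresholds must be nonnegative")
        self.cohort.validate()
        self.phantom.validate()

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        cohort = ph.CohortSpec(**raw.pop("cohort", {}))
        spec = raw.pop("phantom", {})
        for key in ("grid_shape", "spacing_mm", "breast_semi_axes_mm",
                    "gland_semi_axes_mm", "gland_offset_mm", "tumor_center_mm"):
            if key in spec and spec[key] is not None:
                spec[key] = tuple(spec[key])
        phantom_spec = ph.PhantomSpec(**spec)
        if "fat_window_hu" in raw:
            raw["fat_window_hu"] = tuple(raw["fat_window_hu"])
        return cls(cohort=cohort, phantom=phantom_spec, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class StudyReport:
    config_hash: str
    seed: int
    tables: dict[str, pd.DataFrame]
    km_curves: dict[str, pd.DataFrame]
    summary: dict

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "summary": _jsonable(self.summary),
            "tables": {
                name: _jsonable(df.to_dict(orient="records"))
                for name, df in self.tables.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n)]


def _fmt_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.2f} ± {sd:.2f}"


def _baseline_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col, label in [
        ("age", "Age (years)"),
        ("bmi", "Body mass index"),
        ("suv_max", "Maximum SUV of primary tumor"),
        ("mtv_cm3", "MTV of primary tumor (cm3)"),
        ("tat_hu", "TAT HU"),
        ("cat_hu", "CAT HU"),
        ("hu_difference", "HU difference"),
        ("hu_difference_pct", "HU difference %"),
        ("followup_months", "Follow-up (months)"),
    ]:
        s = df[col]
        rows.append(
            {
                "characteristic": label,
                "group": "",
                "n": len(df),
                "pct": float("nan"),
                "median": st.round_half_up(float(s.median()), 2),
                "min": st.round_half_up(float(s.min()), 2),
                "max": st.round_half_up(float(s.max()), 2),
            }
        )
    categoricals = [
        ("menopausal_post", {1: "Postmenopausal", 0: "Premenopausal"}),
        ("t_stage", None),
        ("n_stage", None),
        ("histologic_grade", None),
        ("er", {1: "ER positive", 0: "ER negative"}),
        ("pr", {1: "PR positive", 0: "PR negative"}),
        ("her2", {1: "HER2 positive", 0: "HER2 negative"}),
        ("ki67", {1: "Ki67 positive", 0: "Ki67 negative"}),
        ("triple_negative", {1: "Triple negative", 0: "Not triple negative"}),
        ("recurrence", {1: "Recurrence", 0: "No recurrence"}),
    ]
    for col, mapping in categoricals:
        counts = df[col].value_counts().sort_index()
        for level, count in counts.items():
            label = mapping[level] if mapping else f"{col} {level}"
            rows.append(
                {
                    "characteristic": col,
                    "group": label,
                    "n": int(count),
                    "pct": st.round_half_up(100.0 * count / len(df)),
                    "median": float("nan"),
                    "min": float("nan"),
                    "max": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _group_comparison_table(df: pd.DataFrame) -> pd.DataFrame:
    factors = {
        "t_stage": df["t_stage"],
        "n_stage": np.where(df["n_stage"] == "N0", "N0", "N1-3"),
        "histologic_grade": df["histologic_grade"].astype(str),
        "er": np.where(df["er"] == 1, "positive", "negative"),
        "pr": np.where(df["pr"] == 1, "positive", "negative"),
        "her2": np.where(df["her2"] == 1, "positive", "negative"),
        "ki67": np.where(df["ki67"] == 1, "positive", "negative"),
        "recurrence": np.where(df["recurrence"] == 1, "recur", "no recur"),
    }
    rows = []
    for factor, labels in factors.items():
        labels = np.asarray(labels)
        for param in ADIPOSE_PARAMS:
            try:
                cmp = st.group_compare(df[param].to_numpy(), labels)
            except ValidationError:
                continue  # a level with < 2 members in a tiny cohort
            for _, g in cmp.group_stats.iterrows():
                rows.append(
                    {
                        "factor": factor,
                        "group": g["group"],
                        "parameter": param,
                        "n": int(g["n"]),
                        "mean": float(g["mean"]),
                        "sd": float(g["sd"]),
                        "mean_sd": _fmt_mean_sd(g["mean"], g["sd"]),
                        "test": cmp.test_name,
                        "p_value": cmp.p_value,
                    }
                )
    return pd.DataFrame(rows)


def _univariate_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cov in UNIVARIATE_COVARIATES:
        try:
            fit = st.cox_regression(df, [cov], model_label=f"univariate:{cov}")
        except (ValidationError, st.ConvergenceError) as exc:
            log.warning("univariate Cox skipped for %s: %s", cov, exc)
            continue
        for _, row in fit.table.iterrows():
            rows.append(
                {
                    "variable": row["covariate"],
                    "coefficient": row["coefficient"],
                    "hazard_ratio": row["hazard_ratio"],
                    "ci_lo": row["ci_lo"],
                    "ci_hi": row["ci_hi"],
                    "p_value": row["p_value"],
                }
            )
    return pd.DataFrame(rows)


def _multivariate_table(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for param in ("tat_hu", "hu_difference", "hu_difference_pct"):
        for label, adj in st.MODEL_COVARIATES.items():
            try:
                fit = st.cox_regression(df, [param] + adj, model_label=label)
                row = fit.row(param)
            except (ValidationError, st.ConvergenceError) as exc:
                log.warning("%s Cox skipped for %s: %s", label, param, exc)
                continue
            rows.append(
                {
                    "parameter": param,
                    "model": label,
                    "hazard_ratio": row["hazard_ratio"],
                    "ci_lo": row["ci_lo"],
                    "ci_hi": row["ci_hi"],
                    "p_value": row["p_value"],
                }
            )
    return pd.DataFrame(rows)


def _imaging_table(config: StudyConfig, seeds: list[int]) -> pd.DataFrame:
    rows = []
    for i, seed in enumerate(seeds):
        case = ph.make_breast_phantom(config.phantom, seed=seed)
        rec = qt.measure_case(
            case.ct,
            case.pet,
            case.tumor_mask,
            midline_x_mm=case.midline_x_mm,
            margin_mm=config.voi_margin_mm,
            hu_lo=config.fat_window_hu[0],
            hu_hi=config.fat_window_hu[1],
            suv_threshold=config.suv_threshold,
            min_fat_voxels=config.min_fat_voxels,
        )
        rows.append(
            {
                "case": i,
                "seed": seed,
                "truth_tat_hu": case.truth.tat_hu,
                "measured_tat_hu": rec.adipose.tat_hu,
                "truth_cat_hu": case.truth.cat_hu,
                "measured_cat_hu": rec.adipose.cat_hu,
                "truth_suv_peak": case.truth.suv_peak,
                "measured_suv_max": rec.suv_max,
                "truth_tumor_volume_cm3": case.truth.tumor_volume_mm3 / 1000.0,
                "measured_mtv_cm3": rec.mtv_cm3,
                "n_fat_voxels_tumor_side": rec.n_fat_voxels_tumor_side,
                "n_fat_voxels_contralateral": rec.n_fat_voxels_contralateral,
            }
        )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full simulate -> measure -> analyze -> render flow."""
    config.validate()
    seeds = _stage_seeds(config.seed, 4 + max(config.n_imaging_cases, 0))
    cohort_seed, reader_seed_tat, reader_seed_cat = seeds[0], seeds[1], seeds[2]
    imaging_seeds = seeds[4 : 4 + config.n_imaging_cases]

    log.info("simulating cohort (n=%d)", config.cohort.n_patients)
    df = ph.simulate_cohort(config.cohort, seed=cohort_seed)

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {
        "n_patients": len(df),
        "n_events": int(df["recurrence"].sum()),
        "event_fraction": float(df["recurrence"].mean()),
    }

    if config.n_imaging_cases > 0:
        log.info("measuring %d phantom cases", config.n_imaging_cases)
        tables["imaging_validation"] = _imaging_table(config, imaging_seeds)

    tables["baseline"] = _baseline_table(df)
    tables["group_comparison"] = _group_comparison_table(df)

    # Inter-reader agreement on TAT and CAT.
    agreement_rows = []
    for param, rseed in (("tat_hu", reader_seed_tat), ("cat_hu", reader_seed_cat)):
        r1, r2 = ph.simulate_reader_pair(df[param].to_numpy(), config.reader_sd_hu, rseed)
        ccc = st.concordance_correlation(r1, r2)
        agreement_rows.append(
            {"parameter": param, "ccc": ccc.estimate, "ci_lo": ccc.ci_lo, "ci_hi": ccc.ci_hi}
        )
    tables["reader_agreement"] = pd.DataFrame(agreement_rows)

    t_stat, t_p = st.paired_t_test(df["tat_hu"], df["cat_hu"])
    summary["paired_t_tat_vs_cat"] = {"t": t_stat, "p_value": t_p}

    corr_rows = []
    for a in ("bmi", "suv_max", "mtv_cm3"):
        for b in ADIPOSE_PARAMS:
            rho, p = st.spearman_correlation(df[a], df[b])
            corr_rows.append({"x": a, "y": b, "rho": rho, "p_value": p})
    tables["spearman"] = pd.DataFrame(corr_rows)

    tables["univariate_cox"] = _univariate_table(df)
    tables["multivariate_cox"] = _multivariate_table(df)

    cutoff_rows, km_rows = [], []
    km_curves: dict[str, pd.DataFrame] = {}
    for param in ("tat_hu", "hu_difference", "hu_difference_pct"):
        cut = st.optimal_cutoff(df[param].to_numpy(), df["recurrence"].to_numpy())
        cutoff_rows.append(
            {
                "parameter": param,
                "threshold": cut.threshold,
                "sensitivity": cut.sensitivity,
                "specificity": cut.specificity,
                "youden_j": cut.youden_j,
            }
        )
        high = df[param].to_numpy() >= cut.threshold
        chi2, p = st.log_rank(df["followup_months"], df["recurrence"], high)
        for arm, sel in (("high", high), ("low", ~high)):
            km = st.kaplan_meier(df.loc[sel, "followup_months"], df.loc[sel, "recurrence"])
            km_curves[f"{param}_{arm}"] = pd.DataFrame(
                {"months": km.timeline, "survival": km.survival}
            )
            km_rows.append(
                {
                    "parameter": param,
                    "arm": arm,
                    "n": km.n,
                    "n_events": km.n_events,
                    "rfs_at_horizon": km.survival_at(config.km_horizon_months),
                    "logrank_chi2": chi2,
                    "p_value": p,
                }
            )
    tables["cutoffs"] = pd.DataFrame(cutoff_rows)
    tables["km_stratified"] = pd.DataFrame(km_rows)

    tat_cut = tables["cutoffs"].set_index("parameter").loc["tat_hu", "threshold"]
    tables["stratified_recurrence"] = st.stratified_recurrence_table(
        df, "tat_hu", float(tat_cut)
    )
    summary["tat_hu_cutoff"] = float(tat_cut)

    report = StudyReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        tables=tables,
        km_curves=km_curves,
        summary=summary,
    )
    report.tables["cohort"] = df
    if config.out_dir:
        render_tables(report, config.out_dir)
    return report


def render_tables(report: StudyReport, out_dir: str | Path, formats=("csv", "md")) -> list[Path]:
    """Write report tables as CSV and a combined markdown file, plus JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        for name, df in report.tables.items():
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        for name, df in report.km_curves.items():
            path = out / f"km_{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
    if "md" in formats:
        lines = [
            "# Study report",
            "",
            f"config hash: `{report.config_hash}`  |  seed: {report.seed}",
            "",
        ]
        for name, df in report.tables.items():
            if name == "cohort":
                continue
            lines.append(f"## {name}")
            lines.append("")
            lines.append(_markdown_table(df))
            lines.append("")
        path = out / "report.md"
        path.write_text("\n".join(lines))
        written.append(path)
    path = out / "report.json"
    path.write_text(report.to_json())
    written.append(path)
    return written


def _markdown_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "(empty)"
    show = df.copy()
    for col in show.columns:
        if show[col].dtype.kind == "f":
            show[col] = show[col].map(
                lambda v: "NE" if pd.isna(v) else f"{v:.4g}"
            )
        else:
            show[col] = show[col].map(lambda v: "NE" if pd.isna(v) else str(v))
    header = "| " + " | ".join(show.columns) + " |"
    sep = "| " + " | ".join("---" for _ in show.columns) + " |"
    rows = ["| " + " | ".join(map(str, row)) + " |" for row in show.to_numpy()]
    return "\n".join([header, sep] + rows)
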