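"""Statistical battery for the adipose-attenuation survival analysis.

Agreement (Lin's concordance correlation), paired and group comparisons,
rank correlation, Cox proportional-hazards regression (univariate and the
three adjusted covariate models), Kaplan-Meier curves, log-rank tests,
ROC/Youden cutoff selection and the stage-stratified recurrence table.

Cox, Kaplan-Meier and log-rank computations are delegated to ``lifelines``
(Efron tie handling); classical tests use ``scipy.stats``.  Lin's CCC, the
Conover-Iman post-hoc and the midpoint-threshold Youden scan are
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .errors import ConvergenceError, DegenerateDataError, ValidationError

# Covariate sets of the three adjusted models, by cohort-table column.
MODEL_COVARIATES = {
    "model1": ["age", "t_stage", "n_stage"],
    "model2": ["age", "t_stage", "n_stage", "er", "pr", "ki67"],
    "model3": ["age", "t_stage", "n_stage", "er", "pr", "ki67", "suv_max", "mtv_cm3"],
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (report-table convention, e.g. 34.146 -> 34.1)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Agreement and simple tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CCCResult:
    estimate: float
    ci_lo: float
    ci_hi: float


def concordance_correlation(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2) with population
    (1/n) moments; the CI uses Lin's asymptotic variance of atanh(CCC).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    if sx2 == 0 or sy2 == 0:
        raise DegenerateDataError("zero variance in x or y; CCC undefined")
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)
    r = sxy / math.sqrt(sx2 * sy2)
    if 1.0 - ccc**2 < 1e-12 or abs(r) < 1e-12:
        return CCCResult(estimate=ccc, ci_lo=ccc, ci_hi=ccc)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    var_z = (
        (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
        - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(max(min(ccc, 1 - 1e-15), -1 + 1e-15))
    half = sps.norm.ppf(1 - alpha / 2) * math.sqrt(var_z)
    return CCCResult(
        estimate=ccc, ci_lo=math.tanh(z - half), ci_hi=math.tanh(z + half)
    )


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-sided paired t test; degenerate when all differences are equal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("x and y must be equal-length with n >= 2")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateDataError("all paired differences identical; t undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    test_name: str  # "student_t" or "kruskal_wallis"
    statistic: float
    p_value: float
    group_stats: pd.DataFrame  # group, n, mean, sd
    posthoc: pd.DataFrame | None = None  # pairwise Conover-Iman


def _conover_iman(values: np.ndarray, labels: np.ndarray, h_stat: float) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons after a significant Kruskal-Wallis."""
    ranks = sps.rankdata(values)
    groups = pd.unique(labels)
    big_n = values.size
    k = len(groups)
    s2 = (np.sum(ranks**2) - big_n * (big_n + 1) ** 2 / 4.0) / (big_n - 1)
    scale = s2 * (big_n - 1 - h_stat) / (big_n - k)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            ri, rj = ranks[labels == gi], ranks[labels == gj]
            se = math.sqrt(scale * (1.0 / ri.size + 1.0 / rj.size))
            t = (ri.mean() - rj.mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df=big_n - k)
            rows.append({"group_a": gi, "group_b": gj, "t": t, "p_value": p})
    return pd.DataFrame(rows)


def group_compare(values, groups, alpha: float = 0.05) -> GroupComparison:
    """Student's t for two groups, Kruskal-Wallis (+ Conover-Iman) for more."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValidationError("values and groups must align")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(s.size < 2 for s in samples):
        raise ValidationError("every group needs at least 2 members")
    gstats = pd.DataFrame(
        {
            "group": uniq,
            "n": [s.size for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) for s in samples],
        }
    )
    if len(uniq) == 2:
        res = sps.ttest_ind(samples[0], samples[1], equal_var=True)
        return GroupComparison("student_t", float(res.statistic), float(res.pvalue), gstats)
    res = sps.kruskal(*samples)
    posthoc = None
    if res.pvalue < alpha:
        posthoc = _conover_iman(values, labels, float(res.statistic))
    return GroupComparison(
        "kruskal_wallis", float(res.statistic), float(res.pvalue), gstats, posthoc
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length sequences with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input; rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Survival models
# ---------------------------------------------------------------------------


@dataclass
class SurvivalFit:
    model_label: str
    table: pd.DataFrame  # covariate, coefficient, hazard_ratio, ci_lo, ci_hi, p_value
    n: int
    n_events: int

    def row(self, covariate: str) -> pd.Series:
        hit = self.table[self.table["covariate"] == covariate]
        if hit.empty:
            raise KeyError(covariate)
        return hit.iloc[0]


def _design_matrix(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Expand cohort columns into a numeric Cox design matrix.

    Categorical stage/grade columns become treatment-coded dummies
    (T1/N0/grade-1 reference); everything else is used as-is.
    """
    cols = {}
    for cov in covariates:
        if cov not in df.columns:
            raise ValidationError(f"unknown covariate {cov!r}")
        series = df[cov]
        if cov == "t_stage":
            cols["t_stage_T2"] = (series == "T2").astype(float)
            cols["t_stage_T3"] = (series == "T3").astype(float)
        elif cov == "n_stage":
            cols["n_stage_N1_3"] = (series != "N0").astype(float)
        elif cov == "histologic_grade":
            cols["grade_2"] = (series == 2).astype(float)
            cols["grade_3"] = (series == 3).astype(float)
        else:
            cols[cov] = series.astype(float)
    return pd.DataFrame(cols, index=df.index)


def cox_regression(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "followup_months",
    event_col: str = "recurrence",
    model_label: str = "univariate",
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Wald CIs and p-values)."""
    if df[event_col].sum() < 1:
        raise ValidationError("need at least one event")
    design = _design_matrix(df, covariates)
    for col in design.columns:
        if design[col].nunique() < 2:
            raise ValidationError(f"covariate {col!r} is constant")
    data = design.copy()
    data[duration_col] = df[duration_col].to_numpy(dtype=float)
    data[event_col] = df[event_col].to_numpy(dtype=int)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except (_LLConvergence, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame(
        {
            "covariate": summ.index,
            "coefficient": summ["coef"].to_numpy(),
            "hazard_ratio": summ["exp(coef)"].to_numpy(),
            "ci_lo": summ["exp(coef) lower 95%"].to_numpy(),
            "ci_hi": summ["exp(coef) upper 95%"].to_numpy(),
            "p_value": summ["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return SurvivalFit(
        model_label=model_label,
        table=table,
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


@dataclass
class KaplanMeierCurve:
    timeline: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous product-limit)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def kaplan_meier(durations, events) -> KaplanMeierCurve:
    """Product-limit survival estimate."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size < 1 or durations.size != events.size:
        raise ValidationError("need equal-length nonempty durations and events")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    return KaplanMeierCurve(
        timeline=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n=durations.size,
        n_events=int(events.sum()),
    )


def log_rank(durations, events, group_flag) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    flag = np.asarray(group_flag).astype(bool)
    if flag.all() or (~flag).all():
        raise ValidationError("both groups must be nonempty")
    res = logrank_test(
        durations[flag], durations[~flag], events[flag], events[~flag]
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cutoffs and stratified recurrence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float


def optimal_cutoff(scores, event_labels) -> CutoffResult:
    """Youden-J-optimal threshold over midpoints of consecutive scores.

    Larger scores are taken to indicate events; prediction is positive when
    score >= threshold.  Ties in J are broken toward the lower threshold
    (higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(event_labels).astype(bool)
    if scores.size != labels.size:
        raise ValidationError("scores and labels must align")
    if labels.all() or (~labels).all():
        raise ValidationError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise DegenerateDataError("all scores identical; no candidate threshold")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    pos, neg = scores[labels], scores[~labels]
    best = None
    for thr in candidates:  # ascending, so first max wins the tie-break
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(thr), sens, spec, j)
    return best


def stratified_recurrence_table(
    df: pd.DataFrame,
    score_col: str,
    cutoff: float,
    event_col: str = "recurrence",
    strata: dict[str, list[str]] | None = None,
    stage_col: str = "t_stage",
) -> pd.DataFrame:
    """Recurrence counts by stratum x (score above/below cutoff) with
    Fisher's exact two-sided p per stratum.

    ``strata`` maps stratum names to stage levels; default groups T1 alone
    against T2-T3 combined.  Percentages are rounded half-up to 1 decimal.
    """
    strata = strata or {"T1": ["T1"], "T2-T3": ["T2", "T3"]}
    rows = []
    for name, levels in strata.items():
        sub = df[df[stage_col].isin(levels)]
        high = sub[score_col] >= cutoff
        cells = {}
        for arm, sel in (("high", high), ("low", ~high)):
            part = sub[sel]
            total = len(part)
            events = int(part[event_col].sum())
            cells[arm] = (events, total)
        table22 = [
            [cells["high"][0], cells["high"][1] - cells["high"][0]],
            [cells["low"][0], cells["low"][1] - cells["low"][0]],
        ]
        if cells["high"][1] == 0 or cells["low"][1] == 0:
            p = float("nan")
        else:
            p = float(sps.fisher_exact(table22, alternative="two-sided")[1])
        for arm in ("high", "low"):
            events, total = cells[arm]
            pct = round_half_up(100.0 * events / total) if total else float("nan")
            rows.append(
                {
                    "stratum": name,
                    "arm": arm,
                    "events": events,
                    "total": total,
                    "pct": pct,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
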