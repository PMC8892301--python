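"""Two-group comparison layer: exact and rank tests, routing, and report tables.

The two-sided Fisher exact test is computed from first principles by
probability ordering ("minimum likelihood"): with the margins of the observed
2x2 table fixed, the p-value is the sum of hypergeometric probabilities of
every table no more probable than the observed one. Probabilities are
computed with log-gamma arithmetic, so large tables are stable.

Continuous variables are routed by per-group Shapiro-Wilk normality at
alpha = 0.05: both groups normal -> Welch's unequal-variance t test and
mean (SD) summaries; otherwise Mann-Whitney U and median [IQR] summaries
(quantiles by linear interpolation between order statistics). Categorical
variables always go to Fisher. p-values are unadjusted, one per row, as is
conventional for feasibility tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "fisher_exact_2x2",
    "welch_t_test",
    "mann_whitney_u",
    "spearman_rho",
    "route_test",
    "build_cohort_table",
    "format_p",
]

#: relative tolerance when comparing table probabilities (guards float ties)
_REL_EPS = 1e-7


@dataclass(frozen=True)
class GroupComparison:
    """One table row: a variable, its per-group summaries, and the test result."""

    variable: str
    test: str  # welch_t | mann_whitney | fisher
    group_a_stat: str
    group_b_stat: str
    statistic: float
    p_value: float
    p_formatted: str


@dataclass(frozen=True)
class CorrelationResult:
    x_variable: str
    y_variable: str
    rho: float
    p_value: float
    n: int


def format_p(p: float) -> str:
    """Journal-style p string: "<.001", ">.99", else leading-zero-free decimals.

    Two decimals by default; three when the value is below .01 or when
    2-decimal rounding would be borderline (third digit 4-5, e.g. ".045").
    """
    if not 0.0 <= p <= 1.0 or math.isnan(p):
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    if p < 0.0095 or abs(p - round(p, 2)) >= 0.0045:
        return f"{p:.3f}"[1:]
    return f"{p:.2f}"[1:]


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for the hypergeometric table [[a, r1-a], [c1-a, r2-c1+a]]."""
    n = r1 + r2
    lg = math.lgamma
    return (
        lg(r1 + 1) - lg(a + 1) - lg(r1 - a + 1)
        + lg(r2 + 1) - lg(c1 - a + 1) - lg(r2 - c1 + a + 1)
        - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by probability ordering.

    ``table`` is [[a, b], [c, d]] of non-negative integer counts. Any zero
    margin makes every table with those margins certain, so p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = np.array([_log_hypergeom_pmf(k, r1, r2, c1) for k in support])
    obs = logp[a - lo]
    p = float(np.exp(logp[logp <= obs + _REL_EPS]).sum())
    return min(p, 1.0)


def welch_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test (two-sided)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both samples degenerate with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (midranks), two-sided.

    Exact enumeration when the pooled size is <= 12 with no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y, *, x_variable: str = "x", y_variable: str = "y") -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks, t-approximation p).

    Pairs with a missing value are dropped; a constant vector has no rank
    ordering, so rho is NaN rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(x_variable, y_variable, float("nan"), float("nan"), len(x))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(x_variable, y_variable, float(rho), float(p), len(x))


def _mean_sd(v: np.ndarray) -> str:
    return f"{v.mean():.1f} ({v.std(ddof=1):.1f})"


def _median_iqr(v: np.ndarray) -> str:
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return f"{q50:.1f} ({q25:.1f}-{q75:.1f})"


def _n_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f})"


def route_test(variable: str, values_a, values_b, kind: str = "continuous") -> GroupComparison:
    """Distribution-routed comparison of one variable between two groups.

    ``kind`` is ``continuous`` or ``categorical`` (binary indicator arrays).
    Continuous routing: Shapiro-Wilk per group at alpha = .05, both normal ->
    Welch t, else Mann-Whitney (also the fallback when a group has n < 3).
    """
    if kind == "categorical":
        a = np.asarray(values_a, dtype=bool)
        b = np.asarray(values_b, dtype=bool)
        ka, kb = int(a.sum()), int(b.sum())
        table = [[ka, len(a) - ka], [kb, len(b) - kb]]
        p = fisher_exact_2x2(table)
        return GroupComparison(
            variable, "fisher", _n_pct(ka, len(a)), _n_pct(kb, len(b)),
            float(ka), p, format_p(p),
        )
    if kind != "continuous":
        raise ValueError(f"unknown variable kind {kind!r}")
    a = np.asarray(values_a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(values_b, dtype=float)
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"{variable}: empty group")
    normal = False
    if len(a) >= 3 and len(b) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
        normal = stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
    if normal:
        stat, p = welch_t_test(a, b)
        return GroupComparison(
            variable, "welch_t", _mean_sd(a), _mean_sd(b), stat, p, format_p(p)
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        stat, p = float(len(a) * len(b) / 2), 1.0  # one shared constant value
    else:
        stat, p = mann_whitney_u(a, b)
    return GroupComparison(
        variable, "mann_whitney", _median_iqr(a), _median_iqr(b), stat, p, format_p(p)
    )


#: (label, column, kind) inventory of the baseline-characteristics table
META_INVENTORY = [
    ("Male", "sex", "male"),
    ("Age (years)", "age", "continuous"),
    ("BMI (kg/m2)", "bmi", "continuous"),
    ("Chest circumference (inches)", "chest_circumference_in", "continuous"),
    ("Waist circumference (cm)", "waist_circumference_cm", "continuous"),
    ("FEV1 (% predicted)", "fev1_pct_pred", "continuous"),
    ("Oversized vest", "oversized_vest", "categorical"),
]

#: inventory of the feasibility / vital-signs table
FEASIBILITY_INVENTORY = [
    ("Duration worn (days)", "days_worn", "continuous"),
    ("Longest consecutive days worn", "longest_consecutive_days", "continuous"),
    ("Occasions of missing days", "missing_day_occasions", "continuous"),
    ("Battery depletion during wear", "any_battery_depletion", "categorical"),
    ("Wear time (hours)", "mean_daily_wear_hours", "continuous"),
    ("HR signal quality (%)", "hr_signal_quality", "continuous"),
    ("RR signal quality (%)", "rr_signal_quality", "continuous"),
    ("HR data quality (%)", "hr_data_quality", "continuous"),
    ("RR data quality (%)", "rr_data_quality", "continuous"),
    ("ST data quality (%)", "st_data_quality", "continuous"),
    ("Heart rate (beats/min)", "mean_hr", "continuous"),
    ("Respiratory rate (breaths/min)", "mean_rr", "continuous"),
    ("Skin temperature (C)", "mean_st", "continuous"),
    ("Stationary (hours)", "stationary_hours_per_day", "continuous"),
    ("Physical activity (% of wear time)", "ambulatory_pct", "continuous"),
]

WEEKLY_BINS = (">5", "4-5", "3-4", "2-3", "1-2", "<1")
MRC_GRADES = (2, 3, 4, 5)


def build_cohort_table(
    participants: pd.DataFrame,
    meta: pd.DataFrame,
    *,
    group_a: str = "AECOPD",
    group_b: str = "Stable",
) -> pd.DataFrame:
    """Assemble the full two-group report from participant summaries + metadata.

    One row per variable in the baseline and feasibility inventories; ordinal
    MRC grades and weekly wear categories are compared grade-by-grade /
    bin-by-bin as bin-vs-rest 2x2 Fisher tests.
    """
    df = meta.merge(participants, on="participant_id", how="inner", validate="1:1")
    ga = df[df["group"] == group_a]
    gb = df[df["group"] == group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 participants per group")

    rows: list[GroupComparison] = []
    for label, col, kind in META_INVENTORY:
        if kind == "male":
            rows.append(route_test(label, ga[col] == "male", gb[col] == "male", "categorical"))
        else:
            rows.append(route_test(label, ga[col], gb[col], kind))
    for grade in MRC_GRADES:
        rows.append(
            route_test(
                f"MRC grade {grade}", ga["mrc_grade"] == grade, gb["mrc_grade"] == grade,
                "categorical",
            )
        )
    for bin_label in WEEKLY_BINS:
        rows.append(
            route_test(
                f"Duration worn {bin_label} weeks",
                ga["weekly_category"] == bin_label,
                gb["weekly_category"] == bin_label,
                "categorical",
            )
        )
    for label, col, kind in FEASIBILITY_INVENTORY:
        if kind == "categorical":
            rows.append(route_test(label, ga[col].astype(bool), gb[col].astype(bool), kind))
        else:
            rows.append(route_test(label, ga[col], gb[col], kind))

    out = pd.DataFrame([vars(r) for r in rows])
    out.columns = [
        "variable", "test", f"{group_a.lower()}_summary", f"{group_b.lower()}_summary",
        "statistic", "p_value", "p_formatted",
    ]
    return out
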