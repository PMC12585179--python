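"""Group-level statistics on fitted parameters and discrimination indices.

Thin, convention-fixing wrappers around scipy's nonparametric and t tests:
the Mann–Whitney statistic is reported as min(U, U′) so it is invariant to
the order of the two groups (matching how per-group parameter comparisons
for this paradigm are usually printed), Spearman correlations use average
ranks for ties, and the paired t test reports Cohen's d of the differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "spearman_rho",
    "one_sample_t",
    "paired_t",
    "compare_cohort",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int | None
    method: str
    effect_size: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    return x


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test; statistic = min(U, U′).

    Exact p for small tie-free samples, normal approximation with tie and
    continuity correction otherwise (scipy's 'auto' policy).
    """
    a, b = _clean(a), _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u1 = float(res.statistic)
    u_min = min(u1, a.size * b.size - u1)
    return TestResult(u_min, float(res.pvalue), a.size, b.size, "mann_whitney_u")


def spearman_rho(a, b) -> TestResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    a, b = _clean(a), _clean(b)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant sample")
    res = sps.spearmanr(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), a.size, a.size, "spearman_rho")


def one_sample_t(x, mu0: float) -> TestResult:
    """One-sample two-sided t test of mean(x) against mu0."""
    x = _clean(x)
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(x, mu0)
    d = float((x.mean() - mu0) / x.std(ddof=1))
    return TestResult(float(res.statistic), float(res.pvalue), x.size, None,
                      "one_sample_t", effect_size=d)


def paired_t(a, b) -> TestResult:
    """Paired t test on (a − b) against 0; reports Cohen's d of the differences."""
    a, b = _clean(a), _clean(b)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = a - b
    if np.ptp(diff) == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    res = one_sample_t(diff, 0.0)
    return TestResult(res.statistic, res.p_value, a.size, a.size, "paired_t",
                      effect_size=res.effect_size)


def compare_cohort(
    table: pd.DataFrame,
    group_col: str = "group",
    param_cols: list[str] | None = None,
    di_col: str = "di_test3_test1",
) -> pd.DataFrame:
    """Run the standard battery on a per-animal table with two groups.

    Per parameter: Mann–Whitney U between the two groups, and Spearman ρ of
    the parameter against the discrimination index (pooled over groups);
    per group: one-sample t of the DI against 0.5.  Returns a tidy frame
    (analysis, variable, group_a, group_b, statistic, p, n1, n2); tests
    whose preconditions fail (e.g. a constant DI) are flagged with NaN
    statistics and an 'error' note.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    ga, gb = groups
    if param_cols is None:
        param_cols = [c for c in table.columns if c.startswith("est_")]
    rows = []

    def _row(analysis, variable, group_a, group_b, fn, *args):
        try:
            res = fn(*args)
            rows.append(
                dict(analysis=analysis, variable=variable, group_a=group_a,
                     group_b=group_b, statistic=res.statistic, p=res.p_value,
                     n1=res.n1, n2=res.n2, note="")
            )
        except ValueError as exc:
            rows.append(
                dict(analysis=analysis, variable=variable, group_a=group_a,
                     group_b=group_b, statistic=np.nan, p=np.nan,
                     n1=np.nan, n2=np.nan, note=f"error: {exc}")
            )

    a_mask = table[group_col] == ga
    for col in param_cols:
        _row("mann_whitney_u", col, ga, gb, mann_whitney_u,
             table.loc[a_mask, col], table.loc[~a_mask, col])
        if di_col in table.columns:
            _row("spearman_vs_di", col, ga, gb, spearman_rho,
                 table[col], table[di_col])
    if di_col in table.columns:
        for g in groups:
            _row("di_vs_0.5", di_col, g, None, one_sample_t,
                 table.loc[table[group_col] == g, di_col], 0.5)
    return pd.DataFrame(rows)
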