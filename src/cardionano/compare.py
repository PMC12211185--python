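"""Condition-versus-control statistics: means +/- SEM and Student's t-test.

The comparison frame used throughout: per-group mean and standard error of
the mean (SEM = SD / sqrt(n), sample SD with n-1 denominator), a two-tailed
equal-variance (pooled) two-sample Student's t-test, and significance stars
at p < 0.05 (*), < 0.01 (**), < 0.001 (***). A Welch option is available
but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class SummaryStats:
    mean: float
    sem: float  # NaN when n < 2
    n: int


def summarize(values) -> SummaryStats:
    """Sample mean and SEM (SD with n-1 denominator over sqrt(n))."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    n = values.size
    sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return SummaryStats(float(values.mean()), sem, int(n))


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    stars: str
    flags: list[str] = field(default_factory=list)


def students_t(
    group_a,
    group_b,
    label_a: str = "a",
    label_b: str = "b",
    equal_var: bool = True,
) -> GroupComparison:
    """Two-tailed two-sample t-test (pooled variance by default).

    Degenerate inputs are handled explicitly: identical constant groups give
    t = 0, p = 1; zero pooled variance with unequal means gives the limiting
    p = 0 with a ``zero_variance`` flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    sa, sb = summarize(a), summarize(b)
    df = float(a.size + b.size - 2) if equal_var else np.nan
    flags: list[str] = []
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if sa.mean == sb.mean:
            t, p = 0.0, 1.0
        else:
            t = np.inf if sa.mean > sb.mean else -np.inf
            p = 0.0
            flags.append("zero_variance")
        if not equal_var:
            df = float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        if not equal_var:
            df = float(res.df)
    return GroupComparison(
        label_a, label_b, sa.n, sb.n, sa.mean, sb.mean, sa.sem, sb.sem,
        t, df, p, stars(p), flags,
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
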