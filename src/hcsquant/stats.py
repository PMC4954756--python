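"""Classical statistical tests reported alongside the quantifications.

All tests follow the textbook formulations: pooled-variance (Student)
two-sample t (Welch available via flag), one-way ANOVA, and the two-tailed
variance-ratio F test. Degenerate inputs (zero variance everywhere) are
reported as statistic 0, p = 1 and flagged rather than raising, so batch
pipelines keep running. No multiple-testing correction is applied; raw
p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    test_name: str
    labels: tuple[str, ...]
    statistic: float
    degrees_of_freedom: tuple[float, ...]
    p_value: float
    n: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _clean(x, name="group") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"{name} needs n >= 2, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def t_test_unpaired(
    group_a, group_b, labels=("a", "b"), welch: bool = False
) -> TestResult:
    """Unpaired two-tailed two-sample t-test (pooled variance by default)."""
    a = _clean(group_a, labels[0])
    b = _clean(group_b, labels[1])
    na, nb = a.size, b.size
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(
                "t_unpaired_two_tailed", tuple(labels), 0.0,
                (float(na + nb - 2),), 1.0, (na, nb), degenerate=True,
            )
        return TestResult(
            "t_unpaired_two_tailed", tuple(labels),
            float(np.sign(a.mean() - b.mean()) * np.inf),
            (float(na + nb - 2),), 0.0, (na, nb), degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TestResult(
        "t_unpaired_two_tailed", tuple(labels), float(res.statistic),
        (df,), float(res.pvalue), (na, nb),
    )


def one_way_anova(groups, labels=None) -> TestResult:
    """One-way fixed-effects ANOVA over k groups: F with (k-1, N-k) df."""
    arrays = [_clean(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    labels = tuple(labels) if labels else tuple(str(i) for i in range(len(arrays)))
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df = (float(k - 1), float(n_total - k))
    ns = tuple(a.size for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult("one_way_anova", labels, 0.0, df, 1.0, ns, degenerate=True)
        return TestResult("one_way_anova", labels, float("inf"), df, 0.0, ns, degenerate=True)
    f = (ss_between / df[0]) / (ss_within / df[1])
    p = float(sps.f.sf(f, df[0], df[1]))
    return TestResult("one_way_anova", labels, float(f), df, p, ns)


def f_variance_test(group_a, group_b, labels=("a", "b")) -> TestResult:
    """Two-tailed variance-ratio F test (larger variance in the numerator)."""
    a = _clean(group_a, labels[0])
    b = _clean(group_b, labels[1])
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return TestResult(
            "f_variance", tuple(labels), 1.0,
            (float(a.size - 1), float(b.size - 1)), 1.0,
            (a.size, b.size), degenerate=True,
        )
    if va >= vb:
        f, dfn, dfd = (np.inf if vb == 0 else va / vb), a.size - 1, b.size - 1
        lab = tuple(labels)
    else:
        f, dfn, dfd = vb / va, b.size - 1, a.size - 1
        lab = (labels[1], labels[0])
    p = min(1.0, 2.0 * float(sps.f.sf(f, dfn, dfd)))
    return TestResult(
        "f_variance", lab, float(f), (float(dfn), float(dfd)), p,
        (a.size, b.size), degenerate=not np.isfinite(f),
    )


def confidence_interval_mean(x, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the mean (the error bars of the
    per-treatment percent-activation summaries)."""
    arr = _clean(x)
    sem = arr.std(ddof=1) / np.sqrt(arr.size)
    tcrit = sps.t.ppf(0.5 + level / 2.0, arr.size - 1)
    m = arr.mean()
    return float(m - tcrit * sem), float(m + tcrit * sem)
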