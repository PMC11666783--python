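"""Statistical tests and summaries for the measurement tables.

Categorical class comparisons use the two-sided Fisher exact test
(probability-mass method: the p-value sums all hypergeometric tables whose
probability does not exceed the observed one); absolute-valued measurements
use the unpaired two-tailed pooled-variance t-test; orientation
distributions use the two-tailed Wilcoxon rank-sum test (exact enumeration
with midranks up to 10 per group, normal approximation with continuity and
tie correction beyond).  No multiple-comparison adjustment is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "group_summary",
    "fisher_exact_two_sided",
    "t_test_unpaired_two_tailed",
    "wilcoxon_rank_sum_two_tailed",
    "frequency_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 or int(v) != v for v in vals):
            raise ValueError("counts must be non-negative integers")
        if sum(vals) == 0:
            raise ValueError("empty table")

    def as_array(self):
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def group_summary(values):
    """n, mean, SD, median and quartiles of one measurement group."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return dict(n=int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                median=float(med), q25=float(q25), q75=float(q75))


def fisher_exact_two_sided(table):
    """Two-sided Fisher exact p-value for a 2x2 table (margins fixed)."""
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("a margin of the table is zero")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def t_test_unpaired_two_tailed(x, y):
    """Pooled-variance two-sample t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per group")
    df = len(x) + len(y) - 2
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), df, float(p)


def _midranks(pooled):
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum_two_tailed(x, y, exact_max_n=10):
    """Two-tailed Wilcoxon rank-sum p-value.

    Exact enumeration over all rank assignments (midranks for ties) when
    both groups have at most ``exact_max_n`` observations; otherwise the
    normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    if n <= exact_max_n and m <= exact_max_n:
        dev = abs(w_obs - mu) - 1e-12
        count = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            total += 1
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= dev:
                count += 1
        return count / total
    # normal approximation with tie-corrected variance
    _, t_counts = np.unique(pooled, return_counts=True)
    N = n + m
    tie_term = (t_counts**3 - t_counts).sum() / (N * (N - 1))
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2 * sps.norm.sf(max(z, 0.0))))


def frequency_report(records, event_col, class_col="label", classes=None):
    """Per-class event frequencies plus pairwise two-sided Fisher tests.

    ``records`` is a tidy table with one row per chromosome/kinetochore,
    ``event_col`` a boolean column; returns ``(frequency table, pairwise
    Fisher p-values)``.  No multiple-testing adjustment.
    """
    df = pd.DataFrame(records)
    if classes is None:
        classes = sorted(df[class_col].unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes to compare")
    freq_rows = []
    counts = {}
    for cl in classes:
        sub = df[df[class_col] == cl]
        if len(sub) == 0:
            raise ValueError(f"class {cl!r} has no records")
        k = int(sub[event_col].sum())
        counts[cl] = (k, len(sub))
        freq_rows.append(dict(**{class_col: cl}, events=k, total=len(sub),
                              frequency=k / len(sub)))
    tests = []
    for c1, c2 in itertools.combinations(classes, 2):
        k1, n1 = counts[c1]
        k2, n2 = counts[c2]
        p = fisher_exact_two_sided([[k1, n1 - k1], [k2, n2 - k2]])
        tests.append(dict(class_a=c1, class_b=c2, p_value=p))
    return pd.DataFrame(freq_rows), pd.DataFrame(tests)
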