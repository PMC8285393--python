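"""Nonparametric two-sample machinery for condition-vs-condition comparisons.

Pause scores are compared between conditions with a paired Wilcoxon
signed-rank test (the same transcripts are scored in both conditions);
RRTS distributions with an unpaired Mann–Whitney U test.  Both tests are
implemented here from first principles with two modes:

* **exact** — full enumeration of the null (all 2^n sign vectors, or all
  C(n1+n2, n1) group labelings) for small samples, giving rational
  p-values with no approximation;
* **approx** — the tie-corrected normal approximation with continuity
  correction for larger samples.

The exact mode doubles as an oracle for the approximation at the mode
boundary.  Descriptive helpers (ECDF steps, notched box-plot statistics)
support cumulative-histogram and box-whisker style summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata

#: largest sample size (n for signed-rank, n1+n2 for Mann–Whitney) for
#: which the exact null is enumerated; enumeration is instant up to here
EXACT_CUTOFF = 12

_ALTERNATIVES = ("two-sided", "less", "greater")


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    alternative: str
    n: int
    n2: Optional[int] = None
    direction: int = 0  # sign of the median effect
    mode: str = "approx"
    n_zero_dropped: int = 0


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _two_sided(p_less: float, p_greater: float) -> float:
    return min(1.0, 2.0 * min(p_less, p_greater))


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    alternative: str = "two-sided",
    exact_cutoff: int = EXACT_CUTOFF,
) -> ComparisonResult:
    """Paired Wilcoxon signed-rank test on ``a - b``.

    Zero differences are dropped (Wilcoxon's original convention) and
    counted.  The statistic is W+, the rank sum of positive differences
    over |differences| with average ranks for ties.  ``alternative="less"``
    tests whether ``a`` tends to be smaller than ``b``.
    """
    _check_alternative(alternative)
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("paired samples must be equal-length 1-D and nonempty")
    d = a - b
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("degenerate test: all differences zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    direction = int(np.sign(np.median(d)))

    if n <= exact_cutoff:
        # enumerate all 2^n sign vectors: the null distribution of W+ is
        # the distribution of rank-subset sums
        total = 2**n
        n_le = n_ge = 0
        eps = 1e-9
        for signs in product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if w <= w_plus + eps:
                n_le += 1
            if w >= w_plus - eps:
                n_ge += 1
        p_less, p_greater = n_le / total, n_ge / total
        mode = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        # continuity correction of 0.5 toward the mean
        p_greater = float(norm.sf((w_plus - mu - 0.5) / sigma))
        p_less = float(norm.cdf((w_plus - mu + 0.5) / sigma))
        mode = "approx"

    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = _two_sided(p_less, p_greater)
    return ComparisonResult(
        test_name="wilcoxon_signed_rank",
        statistic=w_plus,
        p_value=p,
        alternative=alternative,
        n=n,
        direction=direction,
        mode=mode,
        n_zero_dropped=n_zero,
    )


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_cutoff: int = EXACT_CUTOFF,
) -> ComparisonResult:
    """Unpaired Mann–Whitney U test.

    The statistic is U1 for sample ``x`` with average-rank tie handling.
    ``alternative="less"`` tests whether ``x`` is stochastically smaller
    than ``y``.  Exact mode enumerates all C(n1+n2, n1) assignments of the
    pooled ranks to group ``x``.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    direction = int(np.sign(np.median(x) - np.median(y)))

    if n1 + n2 <= exact_cutoff:
        base = n1 * (n1 + 1) / 2.0
        eps = 1e-9
        n_le = n_ge = total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = float(ranks[list(idx)].sum()) - base
            total += 1
            if u <= u1 + eps:
                n_le += 1
            if u >= u1 - eps:
                n_ge += 1
        p_less, p_greater = n_le / total, n_ge / total
        mode = "exact"
    else:
        big_n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (big_n * (big_n - 1))
        sigma = math.sqrt(n1 * n2 / 12.0 * ((big_n + 1) - tie_term))
        p_greater = float(norm.sf((u1 - mu - 0.5) / sigma))
        p_less = float(norm.cdf((u1 - mu + 0.5) / sigma))
        mode = "approx"

    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = _two_sided(p_less, p_greater)
    return ComparisonResult(
        test_name="mann_whitney_u",
        statistic=u1,
        p_value=p,
        alternative=alternative,
        n=n1,
        n2=n2,
        direction=direction,
        mode=mode,
    )


def ecdf(values: Sequence[float]) -> list[tuple[float, float]]:
    """Right-continuous ECDF step points: (value, cumulative fraction).

    Duplicated values collapse into a single step of proportional height;
    the final fraction is exactly 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf of empty sample")
    uniq, counts = np.unique(v, return_counts=True)
    fracs = np.cumsum(counts) / v.size
    fracs[-1] = 1.0
    return list(zip(uniq.tolist(), fracs.tolist()))


@dataclass(frozen=True)
class BoxStats:
    """Notched box-plot statistics.

    Quartiles use linear interpolation between order statistics; notches
    are median ± 1.57·IQR/√n (McGill's 95% comparison interval); whiskers
    reach the most extreme data within 1.5·IQR of the quartiles.
    """

    median: float
    q1: float
    q3: float
    iqr: float
    notch_low: float
    notch_high: float
    whisker_low: float
    whisker_high: float
    n: int


NOTCH_CONSTANT = 1.57


def box_stats(values: Sequence[float]) -> BoxStats:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats of empty sample")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    half_notch = NOTCH_CONSTANT * iqr / math.sqrt(v.size)
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    above, below = v[v >= lo_fence], v[v <= hi_fence]
    whisker_low = float(above.min()) if above.size else float(q1)
    whisker_high = float(below.max()) if below.size else float(q3)
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        notch_low=float(med - half_notch),
        notch_high=float(med + half_notch),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        n=int(v.size),
    )
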