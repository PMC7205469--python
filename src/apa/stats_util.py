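"""Shared statistics: size-matched rank-sum comparisons and bootstrap CIs.

Because rank-sum p-values shrink mechanically as n grows, two-group
comparisons first match the control sample size to the test sample by
keeping the controls whose expression fold-change is closest to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class MatchedComparison:
    test_values: list[float]
    control_values: list[float]
    control_ids: list[str]
    statistic: float
    p: float


def match_controls(
    control_fc: Mapping[str, float], n: int
) -> list[str]:
    """The ``n`` control ids with smallest |log2 fold-change|, ties by id.

    When the control pool is not larger than ``n`` the full pool is
    returned unchanged.
    """
    ids = sorted(control_fc)
    if len(ids) <= n:
        return ids
    ranked = sorted(ids, key=lambda g: (abs(math.log2(control_fc[g])), g))
    return sorted(ranked[:n])


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact enumeration null when both groups have at most ``exact_max_n``
    observations and no ties straddle the groups; normal approximation with
    tie correction otherwise.
    """
    use_exact = len(x) <= exact_max_n and len(y) <= exact_max_n
    method = "exact" if use_exact and len(set(x) | set(y)) == len(x) + len(y) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def size_matched_wilcoxon(
    test_values: Mapping[str, float],
    control_values: Mapping[str, float],
    control_fc: Mapping[str, float],
) -> MatchedComparison:
    """Rank-sum test of test vs a size-matched control subset.

    Controls are the |test| genes with fold-change closest to 1 (smallest
    |log2 fc|); if the control pool is already no larger than the test set
    it is used as-is.
    """
    chosen = match_controls(
        {g: control_fc[g] for g in control_values}, len(test_values)
    )
    tv = [test_values[g] for g in sorted(test_values)]
    cv = [control_values[g] for g in chosen]
    statistic, p = rank_sum_test(tv, cv)
    return MatchedComparison(tv, cv, chosen, statistic, p)


def bootstrap_median_ci(
    values: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    min_n: int = 5,
) -> tuple[float, float, float]:
    """Percentile-bootstrap CI of the median; (median, lo, hi).

    With fewer than ``min_n`` observations only the point estimate is
    returned (lo and hi are NaN).
    """
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    if len(x) < min_n:
        return med, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    boots = np.median(x[idx], axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return med, float(lo), float(hi)
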