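"""Extreme-REHH enrichment counts, Fisher tests, and Q-Q diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

DEFAULT_THRESHOLDS = (0.001, 0.005, 0.01, 0.05)


@dataclass
class EnrichmentTable:
    groups: list
    totals: dict               # group -> cores examined in region
    counts: dict               # group -> {threshold: count below threshold}
    thresholds: tuple
    fisher_p: dict             # (threshold, frozenset(pair)) -> two-sided p


def count_extreme(p_by_group: dict, thresholds=DEFAULT_THRESHOLDS,
                  bonferroni: bool = False) -> EnrichmentTable:
    """Tally cores with empirical p below each threshold, per group.

    *p_by_group* maps group -> sequence of empirical p-values (one per
    region core). Pairwise two-sided Fisher tests of extreme vs
    non-extreme counts are included for every group pair and threshold;
    with ``bonferroni`` they are multiplied by the number of group pairs
    (capped at 1). Raw p-values are the default.
    """
    thresholds = tuple(sorted(thresholds))
    groups = list(p_by_group)
    totals = {g: len(p_by_group[g]) for g in groups}
    counts = {g: {t: int(np.count_nonzero(np.asarray(p_by_group[g]) < t))
                  for t in thresholds} for g in groups}
    pairs = list(combinations(groups, 2))
    correction = len(pairs) if bonferroni else 1
    fisher = {}
    for ga, gb in pairs:
        for t in thresholds:
            if totals[ga] == 0 or totals[gb] == 0:
                continue
            p = fisher_excess(counts[ga][t], totals[ga],
                              counts[gb][t], totals[gb])
            fisher[(t, frozenset((ga, gb)))] = min(1.0, p * correction)
    return EnrichmentTable(groups, totals, counts, thresholds, fisher)


def fisher_excess(extreme_a: int, total_a: int, extreme_b: int,
                  total_b: int) -> float:
    """Two-sided Fisher exact p for an excess of extremes in one group.

    Sums hypergeometric outcomes whose probability does not exceed that
    of the observed table (with the customary 1e-7 relative slack for
    floating-point ties, as in scipy.stats.fisher_exact).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("zero total")
    if not (0 <= extreme_a <= total_a and 0 <= extreme_b <= total_b):
        raise ValueError("extreme count outside [0, total]")
    K = extreme_a + extreme_b
    lo = max(0, K - total_b)
    hi = min(K, total_a)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total_a + total_b, total_a, K)
    p_obs = pmf[extreme_a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


@dataclass
class QqSeries:
    observed: np.ndarray  # sorted observed -log10 p, most significant first
    expected: np.ndarray  # -log10((i - 0.5) / n)


def qq_data(p_values) -> QqSeries:
    """Observed vs expected -log10 p for a Q-Q plot."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    obs = -np.log10(np.sort(p))
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return QqSeries(obs, exp)
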