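"""Bootstrap test of differential focal-window differentiation.

For three groups A, B, C the statistic is

    T = (theta_X_AB - theta_X_AC) - (thetabar_bg_AB - thetabar_bg_AC)

where theta_X is the focal-window mean F_ST for a pair and thetabar_bg
averages the per-window mean F_ST over the matched null windows (the
focal window excluded by construction). Under the null that the focal
difference matches the background difference, E(T) = 0.

Significance comes from resampling individuals with replacement,
stratified within population (sizes preserved), recomputing T over the
same fixed windows each time. Two p-values are reported: a conservative
centred-exceedance p with the +1 correction, whose attainable minimum is
1/(B+1), and an asymptotic chi-square(1 df) p for (T_obs/sigma_hat)^2
with sigma_hat the ordinary (ddof=1) standard deviation of the T*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import HaplotypePanel
from .empirical_null import NullWindowSet
from .fst import WindowSpec, snps_in_window, wc_theta


@dataclass
class TStatistic:
    theta_focal_ab: float
    theta_focal_ac: float
    bg_ab: float
    bg_ac: float

    @property
    def T(self) -> float:
        return ((self.theta_focal_ab - self.theta_focal_ac)
                - (self.bg_ab - self.bg_ac))


@dataclass
class BootstrapResult:
    t_obs: float
    t_star: np.ndarray
    sigma_hat: float
    p_conservative: float
    p_asymptotic: float
    b_reps: int
    seed: int
    redraws: int = 0


def _pair_means(counts: np.ndarray, sizes: np.ndarray, focal_mask,
                null_masks) -> tuple[float, float]:
    """(focal window mean, background mean over null windows) for one pair."""
    theta = wc_theta(sizes, counts)
    fv = theta[focal_mask]
    fv = fv[~np.isnan(fv)]
    if fv.size == 0:
        raise ValueError("focal window has no defined SNPs for this pair")
    per_window = np.full(len(null_masks), np.nan)
    for i, m in enumerate(null_masks):
        v = theta[m]
        v = v[~np.isnan(v)]
        if v.size:
            per_window[i] = v.mean()
    if np.all(np.isnan(per_window)):
        raise ValueError("no defined null windows for this pair")
    return float(fv.mean()), float(np.nanmean(per_window))


def _group_setup(panel: HaplotypePanel, groups):
    """Per-population diploid dosage blocks for the populations of *groups*."""
    pop_of_row = panel.population_of_row
    dosage = (panel.alleles[0::2].astype(np.float64)
              + panel.alleles[1::2].astype(np.float64))
    pop_of_ind = pop_of_row[0::2]
    pops_of_group = {g: sorted({p for p, gg in panel.group_of_population.items()
                                if gg == g and p in panel.populations})
                     for g in groups}
    blocks = {}
    for g in groups:
        for p in pops_of_group[g]:
            idx = np.flatnonzero(pop_of_ind == p)
            blocks[p] = dosage[idx]
    return pops_of_group, blocks


def _counts_sizes(pops_of_group, blocks, groups, multipliers=None):
    counts = []
    sizes = []
    for g in groups:
        total = None
        size = 0
        for p in pops_of_group[g]:
            D = blocks[p]
            size += 2 * D.shape[0]
            if multipliers is None:
                c = D.sum(axis=0)
            else:
                c = multipliers[p].astype(np.float64) @ D
            total = c if total is None else total + c
        counts.append(total)
        sizes.append(size)
    return np.vstack(counts), np.array(sizes, dtype=np.float64)


def compute_T(panel: HaplotypePanel, focal: WindowSpec, group_a: str,
              group_b: str, group_c: str,
              nulls: NullWindowSet) -> TStatistic:
    """Observed T for groups (A, B, C) over a focal window and its nulls."""
    groups = (group_a, group_b, group_c)
    if len(set(groups)) != 3:
        raise ValueError("groups A, B, C must be distinct")
    pops_of_group, blocks = _group_setup(panel, groups)
    counts, sizes = _counts_sizes(pops_of_group, blocks, groups)
    focal_mask = snps_in_window(panel, focal)
    null_masks = nulls.snp_masks(panel)
    f_ab, bg_ab = _pair_means(counts[[0, 1]], sizes[[0, 1]],
                              focal_mask, null_masks)
    f_ac, bg_ac = _pair_means(counts[[0, 2]], sizes[[0, 2]],
                              focal_mask, null_masks)
    return TStatistic(f_ab, f_ac, bg_ab, bg_ac)


def bootstrap_test(panel: HaplotypePanel, focal: WindowSpec, group_a: str,
                   group_b: str, group_c: str, nulls: NullWindowSet,
                   b_reps: int = 1000, seed: int = 0) -> BootstrapResult:
    """Stratified individual bootstrap of T over fixed windows.

    Individuals are resampled with replacement within each population
    (population sizes preserved); the focal and null windows stay fixed.
    """
    groups = (group_a, group_b, group_c)
    if len(set(groups)) != 3:
        raise ValueError("groups A, B, C must be distinct")
    pops_of_group, blocks = _group_setup(panel, groups)
    focal_mask = snps_in_window(panel, focal)
    null_masks = nulls.snp_masks(panel)

    counts, sizes = _counts_sizes(pops_of_group, blocks, groups)
    t_obs = _t_value(counts, sizes, focal_mask, null_masks)

    rng = np.random.default_rng(seed)
    t_star = np.empty(b_reps)
    redraws = 0
    max_redraws = 100 * b_reps
    i = 0
    while i < b_reps:
        mult = {}
        for p, D in blocks.items():
            m = D.shape[0]
            idx = rng.integers(0, m, size=m)
            mult[p] = np.bincount(idx, minlength=m)
        counts_i, sizes_i = _counts_sizes(pops_of_group, blocks, groups, mult)
        try:
            t_star[i] = _t_value(counts_i, sizes_i, focal_mask, null_masks)
        except ValueError:
            redraws += 1  # degenerate resample (undefined focal): redraw
            if redraws > max_redraws:
                raise
            continue
        i += 1

    sigma = float(np.std(t_star, ddof=1))
    centred = np.abs(t_star - t_star.mean())
    p_cons = (1 + int(np.count_nonzero(centred >= abs(t_obs)))) / (b_reps + 1)
    if sigma == 0.0:
        p_asym = 1.0 if t_obs == 0.0 else 0.0
    else:
        p_asym = float(stats.chi2.sf((t_obs / sigma) ** 2, df=1))
    return BootstrapResult(t_obs=float(t_obs), t_star=t_star, sigma_hat=sigma,
                           p_conservative=p_cons, p_asymptotic=p_asym,
                           b_reps=b_reps, seed=seed, redraws=redraws)


def _t_value(counts, sizes, focal_mask, null_masks) -> float:
    f_ab, bg_ab = _pair_means(counts[[0, 1]], sizes[[0, 1]],
                              focal_mask, null_masks)
    f_ac, bg_ac = _pair_means(counts[[0, 2]], sizes[[0, 2]],
                              focal_mask, null_masks)
    return (f_ab - f_ac) - (bg_ab - bg_ac)
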