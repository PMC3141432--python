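"""Genic-matched random-window nulls and percentile-rank statistics.

A focal window's statistic is ranked against N random windows of the same
bp size on the same chromosome whose genic SNP fraction lies within an
absolute tolerance (default ±0.10) of the focal window's. Percentile
ranks use the mid-rank tie convention. Group-specific summaries (the mean
of a group's pairwise ranks) and a sliding-window scan build on the same
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import GenicTrack, HaplotypePanel
from .fst import (WindowSpec, mean_defined, pair_theta, snps_in_window)

DEFAULT_N_NULLS = 1000
DEFAULT_GENIC_TOL = 0.10
MAX_DRAWS = 1_000_000


class NullSamplingError(RuntimeError):
    """Raised when too few acceptable null windows can be drawn."""

    def __init__(self, achieved: int, requested: int):
        super().__init__(
            f"only {achieved}/{requested} acceptable null windows found")
        self.achieved = achieved
        self.requested = requested


@dataclass
class NullWindowSet:
    """N random windows genic-matched to a focal window."""

    focal: WindowSpec
    centers: np.ndarray          # bp centers of accepted windows
    genic_fractions: np.ndarray  # genic SNP fraction of each
    focal_genic_fraction: float
    tolerance: float
    seed: int

    @property
    def n(self) -> int:
        return self.centers.size

    def windows(self):
        return [WindowSpec(self.focal.chrom, float(c), self.focal.half_width,
                           "bp") for c in self.centers]

    def snp_masks(self, panel: HaplotypePanel) -> list:
        return [snps_in_window(panel, w) for w in self.windows()]


def genic_fraction(genic: GenicTrack, mask: np.ndarray) -> float:
    n = int(np.count_nonzero(mask))
    if n == 0:
        return np.nan
    return float(np.count_nonzero(genic.genic_flag & mask)) / n


def sample_matched_windows(panel: HaplotypePanel, genic: GenicTrack,
                           focal: WindowSpec, n_windows: int = DEFAULT_N_NULLS,
                           tolerance: float = DEFAULT_GENIC_TOL,
                           seed: int = 0,
                           max_draws: int = MAX_DRAWS) -> NullWindowSet:
    """Rejection-sample genic-matched random windows on the focal chromosome.

    Candidate centers are uniform over the chromosome's SNP span (shrunk
    by the half width). A candidate is accepted iff it holds at least one
    SNP, does not overlap the focal window, and its genic SNP fraction is
    within ``tolerance`` (absolute) of the focal fraction. Deterministic
    in *seed*.
    """
    if focal.unit != "bp":
        raise ValueError("null windows are matched on bp size")
    rng = np.random.default_rng(seed)
    on_chrom = panel.chrom == focal.chrom
    pos = panel.pos_bp[on_chrom]
    genic_chrom = genic.genic_flag[on_chrom]
    lo = pos.min() + focal.half_width
    hi = pos.max() - focal.half_width
    if hi <= lo:
        raise ValueError("chromosome too short for the requested window size")
    f_focal = genic_fraction(genic, snps_in_window(panel, focal))
    if np.isnan(f_focal):
        raise ValueError("focal window holds no SNPs")

    centers, fracs = [], []
    drawn = 0
    batch = max(4 * n_windows, 256)
    while len(centers) < n_windows and drawn < max_draws:
        cand = rng.uniform(lo, hi, size=min(batch, max_draws - drawn))
        drawn += cand.size
        for c in cand:
            if abs(c - focal.center) <= 2 * focal.half_width:
                continue  # overlaps the focal window
            i0 = np.searchsorted(pos, c - focal.half_width, side="left")
            i1 = np.searchsorted(pos, c + focal.half_width, side="right")
            n_in = i1 - i0
            if n_in == 0:
                continue
            f = genic_chrom[i0:i1].sum() / n_in
            if abs(f - f_focal) <= tolerance:
                centers.append(c)
                fracs.append(f)
                if len(centers) == n_windows:
                    break
    if len(centers) < n_windows:
        raise NullSamplingError(len(centers), n_windows)
    return NullWindowSet(focal, np.array(centers), np.array(fracs),
                         f_focal, tolerance, seed)


@dataclass
class PercentileResult:
    value: float
    percentile: float
    n_nulls: int


def percentile_rank(value: float, nulls: np.ndarray) -> PercentileResult:
    """Mid-rank percentile of a value within a null sample.

    rank = 100 * (#{null < value} + 0.5 * #{null == value}) / N
    """
    nulls = np.asarray(nulls, dtype=np.float64)
    nulls = nulls[~np.isnan(nulls)]
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    below = np.count_nonzero(nulls < value)
    ties = np.count_nonzero(nulls == value)
    rank = 100.0 * (below + 0.5 * ties) / nulls.size
    return PercentileResult(float(value), float(rank), int(nulls.size))


def null_window_means(panel: HaplotypePanel, theta: np.ndarray,
                      nulls: NullWindowSet) -> np.ndarray:
    """Mean theta of each null window (NaN where no defined SNPs)."""
    out = np.empty(nulls.n)
    for i, mask in enumerate(nulls.snp_masks(panel)):
        out[i] = mean_defined(theta, mask).mean_theta
    return out


def focal_percentile(panel: HaplotypePanel, labels, focal: WindowSpec,
                     nulls: NullWindowSet,
                     theta: np.ndarray | None = None) -> PercentileResult:
    """Percentile rank of the focal window's mean theta among its nulls."""
    if theta is None:
        theta = pair_theta(panel, labels[0], labels[1])
    wm = mean_defined(theta, snps_in_window(panel, focal))
    if not wm.defined:
        raise ValueError("focal window has no defined SNPs for this pair")
    return percentile_rank(wm.mean_theta, null_window_means(panel, theta, nulls))


@dataclass
class GsfstResult:
    group: str
    pairwise_ranks: dict
    mean_rank: float


def gsfst(group: str, pairwise_ranks: dict, all_groups) -> GsfstResult:
    """Group-specific F_ST summary: mean of the group's pairwise ranks.

    *pairwise_ranks* maps frozenset({group, other}) -> percentile rank and
    must contain exactly one entry per other group.
    """
    others = [g for g in all_groups if g != group]
    ranks = {}
    for other in others:
        key = frozenset((group, other))
        if key not in pairwise_ranks:
            raise KeyError(f"missing pairwise rank for {group}-{other}")
        ranks[other] = pairwise_ranks[key]
    extra = [k for k in pairwise_ranks if group in k and k not in
             {frozenset((group, o)) for o in others}]
    if extra:
        raise ValueError(f"unexpected pairwise ranks {extra}")
    mean = float(np.mean(list(ranks.values())))
    return GsfstResult(group, ranks, mean)


@dataclass
class SlidingScanResult:
    centers: np.ndarray
    percentiles: np.ndarray  # NaN where undefined
    window_means: np.ndarray
    n_snps: np.ndarray


def sliding_centers(start: float, end: float, window_size: float,
                    step: float) -> np.ndarray:
    """Window centers on a fixed grid anchored at the region start.

    Centers at start + k*step (k >= 1) while the full window fits in
    [start, end].
    """
    half = window_size / 2.0
    centers = []
    k = 1
    while True:
        c = start + k * step
        if c + half > end:
            break
        if c - half >= start:
            centers.append(c)
        k += 1
    return np.array(centers)


def sliding_scan(panel: HaplotypePanel, genic: GenicTrack, labels,
                 chrom: str, region_start: float, region_end: float,
                 window_size: float = 400_000.0, step: float = 200_000.0,
                 n_nulls: int = DEFAULT_N_NULLS,
                 tolerance: float = DEFAULT_GENIC_TOL,
                 seed: int = 0) -> SlidingScanResult:
    """Percentile rank of each sliding window against its own matched nulls."""
    centers = sliding_centers(region_start, region_end, window_size, step)
    if centers.size == 0:
        raise ValueError("empty region for the requested window size")
    theta = pair_theta(panel, labels[0], labels[1])
    percs = np.full(centers.size, np.nan)
    means = np.full(centers.size, np.nan)
    nsnps = np.zeros(centers.size, dtype=int)
    rng = np.random.default_rng(seed)
    for i, c in enumerate(centers):
        spec = WindowSpec(chrom, float(c), window_size / 2.0, "bp")
        wm = mean_defined(theta, snps_in_window(panel, spec))
        means[i], nsnps[i] = wm.mean_theta, wm.n_snps
        if not wm.defined:
            continue
        nulls = sample_matched_windows(panel, genic, spec, n_nulls,
                                       tolerance,
                                       seed=int(rng.integers(2 ** 31)))
        percs[i] = percentile_rank(
            wm.mean_theta, null_window_means(panel, theta, nulls)).percentile
    return SlidingScanResult(centers, percs, means, nsnps)


def pairwise_matrix(panel: HaplotypePanel, genic: GenicTrack,
                    focal: WindowSpec, units: list | None = None,
                    n_nulls: int = DEFAULT_N_NULLS,
                    tolerance: float = DEFAULT_GENIC_TOL, seed: int = 0):
    """Symmetric matrix of focal-window percentile ranks for all unit pairs.

    *units* defaults to the panel's populations. Cells where the pair is
    monomorphic across the window (or lacks nulls) are NaN; the diagonal
    is NaN. Returns (units, matrix).
    """
    if units is None:
        units = panel.populations
    if len(units) < 2:
        raise ValueError("need at least two populations")
    for u in units:
        rows = panel.rows_of_population(u) if u in panel.populations \
            else panel.rows_of_group(u)
        if rows.size < 2:
            raise ValueError(f"unit {u!r} has fewer than 2 haplotypes")
    k = len(units)
    mat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(k), 2):
        theta = pair_theta(panel, units[i], units[j])
        wm = mean_defined(theta, snps_in_window(panel, focal))
        if not wm.defined:
            continue
        nulls = sample_matched_windows(panel, genic, focal, n_nulls,
                                       tolerance,
                                       seed=int(rng.integers(2 ** 31)))
        null_means = null_window_means(panel, theta, nulls)
        if np.all(np.isnan(null_means)):
            continue
        res = percentile_rank(wm.mean_theta, null_means)
        mat[i, j] = mat[j, i] = res.percentile
    return units, mat
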