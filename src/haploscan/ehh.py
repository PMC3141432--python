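"""Haplotype-block cores and extended haplotype homozygosity (EHH/REHH).

Blocks are called with D-prime confidence-interval criteria on phased
two-locus counts (strong LD iff CI in [>=0.70, >=0.98]; strong
recombination iff the upper bound < 0.90; a block is a maximal interval
in which >=95% of informative pairs are strong LD). Each block's distinct
allele strings are its core haplotypes.

EHH at a distance d from a block edge is the probability that two
randomly chosen carrier chromosomes are identical over the segment from
the core to the SNP nearest d (inclusive). REHH divides a core's EHH by
the EHH of all the block's other chromosomes pooled (grouped by
core-plus-extension identity). Empirical p-values rank a core's REHH
within its haplotype-frequency bin over a chromosome-wide scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import HaplotypePanel

# Gabriel et al. thresholds; exposed because the source definition is the
# only statement of them.
STRONG_LD_LOWER = 0.70
STRONG_LD_UPPER = 0.98
STRONG_RECOMB_UPPER = 0.90
BLOCK_STRONG_FRACTION = 0.95
MIN_INFORMATIVE_MAF = 0.05
MIN_CORE_FREQ = 0.05

_DPRIME_GRID = np.linspace(0.0, 1.0, 401)
_LL_DROP_95 = 1.92  # chi2(1)/2 at 95%


@dataclass
class LdPair:
    i: int
    j: int
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Phased two-locus haplotype counts (n00, n01, n10, n11)."""
    code = 2 * a.astype(np.int64) + b.astype(np.int64)
    return np.bincount(code, minlength=4).astype(np.float64)


def _dprime_profile(n: np.ndarray):
    """Point D', r2 and profile-likelihood CI from haplotype counts.

    Allele frequencies are fixed at their sample values; the likelihood
    is profiled over D' (orientation fixed so D >= 0). The 95% CI is the
    D' range whose log-likelihood is within 1.92 of the maximum.
    """
    total = n.sum()
    pA = (n[2] + n[3]) / total
    pB = (n[1] + n[3]) / total
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site in LD computation")
    d = n[3] / total - pA * pB
    r2 = d * d / (pA * (1 - pA) * pB * (1 - pB))
    if d < 0:
        # flip coding of locus B so D >= 0; D', r2 are invariant
        n = n[[1, 0, 3, 2]]
        pB = 1 - pB
        d = -d
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    if dmax <= 0:
        raise ValueError("degenerate allele frequencies")
    d_prime = d / dmax

    dd = _DPRIME_GRID * dmax
    p = np.empty((dd.size, 4))
    p[:, 3] = pA * pB + dd
    p[:, 2] = pA * (1 - pB) - dd
    p[:, 1] = (1 - pA) * pB - dd
    p[:, 0] = (1 - pA) * (1 - pB) + dd
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.clip(p, 1e-300, None)), -np.inf)
    ll = np.zeros(dd.size)
    for cat in range(4):
        if n[cat] > 0:
            ll += n[cat] * logp[:, cat]  # skip empty cells: 0*log(0) := 0
    keep = ll >= ll.max() - _LL_DROP_95
    ci = _DPRIME_GRID[keep]
    return float(d_prime), float(r2), float(ci.min()), float(ci.max())


def ld_pair(panel: HaplotypePanel, snp_i: int, snp_j: int,
            rows: np.ndarray | None = None) -> LdPair:
    """D', r2 and the D' 95% profile-likelihood CI for a SNP pair."""
    if rows is None:
        rows = np.arange(panel.n_haplotypes)
    a = panel.alleles[rows, snp_i]
    b = panel.alleles[rows, snp_j]
    if a.min() == a.max() or b.min() == b.max():
        raise ValueError("monomorphic SNP in subset")
    dp, r2, lo, hi = _dprime_profile(_pair_counts(a, b))
    return LdPair(snp_i, snp_j, dp, r2, lo, hi)


def _dprime_ci_batch(n: np.ndarray):
    """Vectorised D' profile-likelihood CI for (P, 4) haplotype counts."""
    n = np.asarray(n, dtype=np.float64)
    total = n.sum(axis=1)
    pA = (n[:, 2] + n[:, 3]) / total
    pB = (n[:, 1] + n[:, 3]) / total
    d = n[:, 3] / total - pA * pB
    flip = d < 0
    n = np.where(flip[:, None], n[:, [1, 0, 3, 2]], n)
    pB = np.where(flip, 1 - pB, pB)
    d = np.abs(d)
    dmax = np.minimum(pA * (1 - pB), (1 - pA) * pB)
    dd = _DPRIME_GRID[None, :] * dmax[:, None]        # (P, G)
    p = np.empty(dd.shape + (4,))
    p[..., 3] = pA[:, None] * pB[:, None] + dd
    p[..., 2] = pA[:, None] * (1 - pB[:, None]) - dd
    p[..., 1] = (1 - pA[:, None]) * pB[:, None] - dd
    p[..., 0] = (1 - pA[:, None]) * (1 - pB[:, None]) + dd
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.clip(p, 1e-300, None)), -np.inf)
    ll = np.zeros(dd.shape)
    with np.errstate(invalid="ignore"):
        for cat in range(4):
            w = n[:, cat]
            contrib = logp[..., cat] * w[:, None]
            ll += np.where(w[:, None] > 0, contrib, 0.0)
    ll = np.nan_to_num(ll, nan=-np.inf)
    keep = ll >= ll.max(axis=1, keepdims=True) - _LL_DROP_95
    grid = _DPRIME_GRID
    lo = np.where(keep, grid[None, :], np.inf).min(axis=1)
    hi = np.where(keep, grid[None, :], -np.inf).max(axis=1)
    return lo, hi


def _classify_pairs(alleles: np.ndarray, snp_idx: np.ndarray,
                    pos_bp: np.ndarray, max_pair_bp: float):
    """Pair classification among informative SNPs.

    Returns a dict (ii, jj) -> +1 strong LD / -1 strong recombination /
    0 otherwise, keyed by positions within snp_idx.
    """
    k = snp_idx.size
    pairs = []
    for ii in range(k):
        for jj in range(ii + 1, k):
            if pos_bp[snp_idx[jj]] - pos_bp[snp_idx[ii]] > max_pair_bp:
                break
            pairs.append((ii, jj))
    cls: dict = {}
    sub = alleles[:, snp_idx].astype(np.int64)
    chunk = 4096
    for start in range(0, len(pairs), chunk):
        batch = pairs[start:start + chunk]
        a = sub[:, [p[0] for p in batch]]
        b = sub[:, [p[1] for p in batch]]
        code = 2 * a + b                                  # (rows, P)
        counts = np.stack([(code == c).sum(axis=0) for c in range(4)],
                          axis=1)                         # (P, 4)
        lo, hi = _dprime_ci_batch(counts)
        strong = (lo >= STRONG_LD_LOWER) & (hi >= STRONG_LD_UPPER)
        recomb = hi < STRONG_RECOMB_UPPER
        for (ii, jj), s, r in zip(batch, strong, recomb):
            cls[(ii, jj)] = 1 if s else (-1 if r else 0)
    return cls


def gabriel_blocks(panel: HaplotypePanel, region_snps: np.ndarray,
                   rows: np.ndarray | None = None,
                   max_pair_bp: float = 500_000.0,
                   min_maf: float = MIN_INFORMATIVE_MAF) -> list:
    """Haplotype blocks over a SNP index range for a chromosome subset.

    SNPs with minor-allele frequency below *min_maf* in the subset are
    ignored for block building. Blocks are maximal intervals (greedy,
    longest first, non-overlapping) in which at least 95% of informative
    pairs are strong LD; informative SNPs outside blocks become
    single-SNP cores. Returns a list of arrays of panel SNP indices.
    """
    if rows is None:
        rows = np.arange(panel.n_haplotypes)
    region_snps = np.asarray(region_snps)
    if region_snps.size == 0:
        raise ValueError("empty region")
    sub = panel.alleles[rows]
    freq = sub[:, region_snps].mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    informative = region_snps[maf >= min_maf]
    if informative.size == 0:
        return []
    cls = _classify_pairs(sub, informative, panel.pos_bp, max_pair_bp)

    k = informative.size
    candidates = []
    for ii in range(k):
        n_strong = n_inform = 0
        for jj in range(ii + 1, k):
            ok = True
            for mm in range(ii, jj):
                c = cls.get((mm, jj))
                if c is None:  # pair beyond max span: interval invalid
                    ok = False
                    break
                if c != 0:
                    n_inform += 1
                    if c == 1:
                        n_strong += 1
            if not ok:
                break
            if n_inform > 0 and n_strong / n_inform >= BLOCK_STRONG_FRACTION:
                candidates.append((ii, jj, n_strong, n_inform))
    # longest first (bp extent), ties by left edge
    candidates.sort(key=lambda c: (
        -(panel.pos_bp[informative[c[1]]] - panel.pos_bp[informative[c[0]]]),
        c[0]))
    used = np.zeros(k, dtype=bool)
    blocks = []
    for ii, jj, _, _ in candidates:
        if used[ii:jj + 1].any():
            continue
        used[ii:jj + 1] = True
        blocks.append(informative[ii:jj + 1])
    for ii in range(k):
        if not used[ii]:
            blocks.append(informative[ii:ii + 1])
    blocks.sort(key=lambda b: b[0])
    return blocks


@dataclass
class CoreHaplotype:
    block_snps: np.ndarray   # panel SNP indices of the block
    core_alleles: np.ndarray  # 0/1 string over the block SNPs
    carriers: np.ndarray     # positions within the analysed row subset
    frequency: float

    @property
    def core_string(self) -> str:
        return "".join(map(str, self.core_alleles))


def core_haplotypes(panel: HaplotypePanel, block_snps: np.ndarray,
                    rows: np.ndarray | None = None,
                    min_freq: float = 0.0) -> list:
    """Distinct allele strings of a block and their carriers.

    Cores partition the subset's chromosomes; *min_freq* filters the
    returned list (pass 0 to get all cores).
    """
    if rows is None:
        rows = np.arange(panel.n_haplotypes)
    sub = panel.alleles[np.ix_(rows, np.asarray(block_snps))]
    uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
    n = rows.size
    cores = []
    for u in range(uniq.shape[0]):
        carriers = np.flatnonzero(inverse == u)
        f = carriers.size / n
        if f >= min_freq:
            cores.append(CoreHaplotype(np.asarray(block_snps), uniq[u],
                                       carriers, f))
    cores.sort(key=lambda c: -c.frequency)
    return cores


def _row_group_counts(seg: np.ndarray) -> np.ndarray:
    """Sizes of identical-row groups of a 0/1 matrix (fast byte-view path)."""
    seg = np.ascontiguousarray(seg, dtype=np.uint8)
    if seg.shape[1] == 0:
        return np.array([seg.shape[0]])
    keys = seg.view(np.dtype((np.void, seg.shape[1])))[:, 0]
    _, counts = np.unique(keys, return_counts=True)
    return counts


def _pair_homozygosity(groups: np.ndarray) -> float:
    """sum_j C(c_j, 2) / C(n, 2) for group sizes c_j of n items."""
    n = groups.sum()
    if n < 2:
        raise ValueError("need at least two chromosomes")
    return float((groups * (groups - 1)).sum() / (n * (n - 1)))


def _horizon_snp(panel: HaplotypePanel, block_snps: np.ndarray,
                 direction: str, distance: float, unit: str = "bp") -> int:
    """Index of the SNP nearest *distance* from the block's proximal edge."""
    pos = panel.pos_bp if unit == "bp" else panel.pos_cM
    chrom = panel.chrom[block_snps[0]]
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    if direction == "downstream":
        edge = int(block_snps[-1])
        side = on_chrom[on_chrom >= edge]
        target = pos[edge] + distance
    elif direction == "upstream":
        edge = int(block_snps[0])
        side = on_chrom[on_chrom <= edge]
        target = pos[edge] - distance
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return int(side[np.argmin(np.abs(pos[side] - target))])


def _segment_columns(panel: HaplotypePanel, block_snps: np.ndarray,
                     direction: str, distance: float, unit: str) -> np.ndarray:
    """Block columns plus the extension out to the distance horizon."""
    horizon = _horizon_snp(panel, block_snps, direction, distance, unit)
    block_snps = np.asarray(block_snps)
    if direction == "downstream":
        return np.concatenate([block_snps[:-1],
                               np.arange(block_snps[-1], horizon + 1)])
    return np.concatenate([np.arange(horizon, block_snps[0] + 1),
                           block_snps[1:]])


def ehh(panel: HaplotypePanel, core: CoreHaplotype, direction: str,
        distance: float, rows: np.ndarray | None = None,
        unit: str = "bp") -> float:
    """EHH of a core at a distance from its proximal block edge.

    Carriers are grouped by identity of the haplotype from the core out
    to the SNP nearest the target distance (inclusive); EHH is the
    probability that two random carriers fall in the same group.
    """
    if rows is None:
        rows = np.arange(panel.n_haplotypes)
    if core.carriers.size < 2:
        raise ValueError("core has fewer than two carriers")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    cols = _segment_columns(panel, core.block_snps, direction, distance, unit)
    seg = panel.alleles[np.ix_(rows[core.carriers], cols)]
    return _pair_homozygosity(_row_group_counts(seg))


def rehh(panel: HaplotypePanel, core: CoreHaplotype, direction: str,
         distance: float, rows: np.ndarray | None = None,
         unit: str = "bp") -> float:
    """EHH of the core divided by the pooled EHH of the block's other cores.

    The pooled group is every block chromosome not carrying this core,
    grouped by identity of core-plus-extension haplotype (different cores
    are never identical). NaN when the denominator is zero; an error when
    the block has a single core or fewer than two pooled chromosomes.
    """
    if rows is None:
        rows = np.arange(panel.n_haplotypes)
    n = rows.size
    mask = np.ones(n, dtype=bool)
    mask[core.carriers] = False
    others = np.flatnonzero(mask)
    if others.size == 0:
        raise ValueError("single-core block: REHH undefined")
    if others.size < 2:
        raise ValueError("fewer than two pooled other chromosomes")
    cols = _segment_columns(panel, core.block_snps, direction, distance, unit)
    seg_all = panel.alleles[np.ix_(rows, cols)]
    ehh_core = _pair_homozygosity(_row_group_counts(seg_all[core.carriers]))
    ehh_others = _pair_homozygosity(_row_group_counts(seg_all[others]))
    if ehh_others == 0.0:
        return np.nan
    return ehh_core / ehh_others


@dataclass
class RehhRecord:
    block_start: int        # panel index of first block SNP
    block_end: int          # panel index of last block SNP
    core_string: str
    frequency: float
    direction: str
    distance: float
    rehh: float
    empirical_p: float = np.nan
    p_unstable: bool = False
    block_snps: tuple = ()  # panel indices of the block's (informative) SNPs

    def core_allele_at(self, snp_index: int) -> str | None:
        """Core allele at a panel SNP index, or None if not a block SNP."""
        if snp_index in self.block_snps:
            return self.core_string[self.block_snps.index(snp_index)]
        return None

    @property
    def bin_id(self) -> int:
        return frequency_bin(float(self.frequency))


_BIN_EDGES = np.round(np.arange(0.05, 1.0001, 0.05), 10)


def frequency_bin(freq: float) -> int:
    """Bin index of a core frequency over (0.05, 1.0] in 0.05-wide bins."""
    if not MIN_CORE_FREQ < freq <= 1.0:
        raise ValueError(f"frequency {freq} outside (0.05, 1.0]")
    return int(np.searchsorted(_BIN_EDGES, freq, side="left")) - 1


def scan_rehh(panel: HaplotypePanel, region_snps: np.ndarray,
              rows: np.ndarray, distances=(150_000.0, 300_000.0),
              unit: str = "bp", min_core_freq: float = MIN_CORE_FREQ,
              max_pair_bp: float = 500_000.0) -> list:
    """Block, core and REHH records over a SNP index range.

    Returns a list of :class:`RehhRecord`, one per (core, direction,
    distance) with core frequency > min_core_freq and a defined REHH.
    """
    records = []
    for block in gabriel_blocks(panel, region_snps, rows,
                                max_pair_bp=max_pair_bp):
        cores = core_haplotypes(panel, block, rows)
        if len(cores) < 2:
            continue
        for core in cores:
            if core.frequency <= min_core_freq or core.carriers.size < 2:
                continue
            for direction in ("upstream", "downstream"):
                for dist in distances:
                    try:
                        val = rehh(panel, core, direction, dist, rows, unit)
                    except ValueError:
                        continue
                    if np.isnan(val):
                        continue
                    records.append(RehhRecord(
                        int(block[0]), int(block[-1]), core.core_string,
                        core.frequency, direction, float(dist), float(val),
                        block_snps=tuple(int(i) for i in block)))
    return records


def empirical_p(chromosome_records: list, query: RehhRecord,
                min_bin_size: int = 20, exclude_query: bool = True):
    """Frequency-binned empirical p of a query REHH.

    p = (1 + #{bin records with REHH >= query}) / (bin size + 1), within
    records of the same direction and distance whose frequency falls in
    the query's 0.05-wide bin. An underpopulated bin (< min_bin_size) is
    widened symmetrically to adjacent bins and the result flagged
    unstable. Returns (p, unstable).
    """
    qbin = frequency_bin(query.frequency)
    pool = [r for r in chromosome_records
            if r.direction == query.direction and r.distance == query.distance
            and not (exclude_query and r is query)]
    width = 0
    while True:
        lo, hi = qbin - width, qbin + width
        vals = np.array([r.rehh for r in pool
                         if lo <= frequency_bin(r.frequency) <= hi])
        if vals.size >= min_bin_size or (lo <= 0 and hi >= len(_BIN_EDGES) - 2):
            break
        width += 1
    if vals.size == 0:
        raise ValueError("no records available for empirical p")
    p = (1 + int(np.count_nonzero(vals >= query.rehh))) / (vals.size + 1)
    return float(p), width > 0


def attach_empirical_p(chromosome_records: list, region_records: list,
                       min_bin_size: int = 20) -> None:
    """Fill empirical_p / p_unstable on each region record in place."""
    for rec in region_records:
        p, unstable = empirical_p(chromosome_records, rec,
                                  min_bin_size=min_bin_size)
        rec.empirical_p = p
        rec.p_unstable = unstable
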