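"""Structured phased-panel simulator with known differentiation.

Panels are drawn under the Balding–Nichols model: each SNP has an
ancestral frequency p, and each population's frequency is Beta-distributed
around p with variance F·p(1−p). Sites are in linkage equilibrium, so the
baseline haplotype-homozygosity landscape is exchangeable and any
long-haplotype signal is attributable to :func:`spike_sweep`, which copies
a donor haplotype into a fraction of a target population around a focal
SNP with exponentially distributed one-sided extents in genetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import GeneticMap, GenicTrack, HaplotypePanel


@dataclass
class SimConfig:
    """Parameters of a Balding–Nichols panel simulation."""

    n_pops: int = 4
    haplotypes_per_pop: int = 50
    n_snps: int = 1000
    chrom_length_bp: int = 10_000_000
    F_target: float = 0.1
    ancestral_freq_range: tuple = (0.05, 0.95)
    recomb_rate_cM_per_Mb: float = 1.0
    genic_fraction: float = 0.5
    seed: int = 0
    chrom: str = "1"
    groups_per_pop: dict | None = None  # population -> group; default 1:1

    def __post_init__(self) -> None:
        if not 0 <= self.F_target < 1:
            raise ValueError("F_target must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("degenerate ancestral_freq_range")
        if self.haplotypes_per_pop % 2 != 0:
            raise ValueError("haplotypes_per_pop must be even (diploids)")


@dataclass
class SweepSpec:
    """A partial-sweep spike: copy one donor haplotype into carriers."""

    focal_snp: int
    target_pops: list
    carrier_fraction: float = 0.3
    decay_scale_cM: float = 0.3
    focal_allele: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")
        if isinstance(self.target_pops, str):
            self.target_pops = [self.target_pops]


def simulate_panel(cfg: SimConfig):
    """Draw a panel, genic track and genetic map from a :class:`SimConfig`.

    Returns (panel, genic_track, genetic_map). Deterministic in cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=cfg.n_snps)

    F = cfg.F_target
    if F == 0:
        pop_freq = np.tile(p_anc, (cfg.n_pops, 1))
    else:
        scale = (1.0 - F) / F
        pop_freq = rng.beta(p_anc * scale, (1.0 - p_anc) * scale,
                            size=(cfg.n_pops, cfg.n_snps))

    # positions: uniform-random, sorted, distinct
    pos_bp = np.sort(rng.choice(
        np.arange(1, cfg.chrom_length_bp + 1, dtype=np.int64),
        size=cfg.n_snps, replace=False))
    pos_cM = pos_bp * cfg.recomb_rate_cM_per_Mb * 1e-6

    n_hap = cfg.n_pops * cfg.haplotypes_per_pop
    alleles = np.empty((n_hap, cfg.n_snps), dtype=np.uint8)
    for k in range(cfg.n_pops):
        sl = slice(k * cfg.haplotypes_per_pop, (k + 1) * cfg.haplotypes_per_pop)
        alleles[sl] = (rng.random((cfg.haplotypes_per_pop, cfg.n_snps))
                       < pop_freq[k]).astype(np.uint8)

    pops = [f"pop{k}" for k in range(cfg.n_pops)]
    samples, sample_of_row = [], []
    pop_of: dict = {}
    for k, pop in enumerate(pops):
        for j in range(cfg.haplotypes_per_pop // 2):
            sid = f"{pop}_ind{j}"
            samples.append(sid)
            sample_of_row.extend([sid, sid])
            pop_of[sid] = pop
    if cfg.groups_per_pop is not None:
        grp_of = dict(cfg.groups_per_pop)
    else:
        grp_of = {pop: f"grp{k}" for k, pop in enumerate(pops)}

    panel = HaplotypePanel(
        alleles=alleles,
        snp_ids=np.array([f"snp{i}" for i in range(cfg.n_snps)]),
        chrom=np.full(cfg.n_snps, cfg.chrom),
        pos_bp=pos_bp,
        pos_cM=pos_cM,
        sample_of_row=np.array(sample_of_row),
        population_of_sample=pop_of,
        group_of_population=grp_of,
    )
    genic = GenicTrack(_genic_blocks(cfg.n_snps, cfg.genic_fraction, rng))
    gmap = GeneticMap()
    gmap.add_chromosome(cfg.chrom, [1, cfg.chrom_length_bp],
                        [1e-6 * cfg.recomb_rate_cM_per_Mb,
                         cfg.chrom_length_bp * 1e-6 * cfg.recomb_rate_cM_per_Mb])
    return panel, genic, gmap


def _genic_blocks(n_snps: int, fraction: float, rng) -> np.ndarray:
    """Flag ~fraction of SNPs genic, in contiguous blocks of random length."""
    flags = np.zeros(n_snps, dtype=bool)
    if fraction <= 0:
        return flags
    if fraction >= 1:
        return ~flags
    target = int(round(fraction * n_snps))
    flagged = 0
    # draw block starts/lengths until the target count is reached
    while flagged < target:
        length = min(int(rng.integers(5, 50)), target - flagged)
        start = int(rng.integers(0, n_snps))
        stop = min(start + length, n_snps)
        newly = np.count_nonzero(~flags[start:stop])
        flags[start:stop] = True
        flagged += newly
    return flags


def spike_sweep(panel: HaplotypePanel, spec: SweepSpec) -> HaplotypePanel:
    """Copy one donor haplotype into a fraction of a target population.

    A donor chromosome carrying ``spec.focal_allele`` at the focal SNP is
    chosen within the (first) target population. For each recipient, the
    copied interval extends from the focal SNP by independent
    Exponential(decay_scale_cM) distances on each side, measured in cM.
    Chromosomes outside the target populations are untouched. Returns a
    new panel; the input is not modified.
    """
    rng = np.random.default_rng(spec.seed)
    j = spec.focal_snp
    if not 0 <= j < panel.n_snps:
        raise ValueError(f"focal SNP index {j} out of range")
    alleles = panel.alleles.copy()
    pop_of_row = panel.population_of_row

    target_rows = np.flatnonzero(np.isin(pop_of_row, spec.target_pops))
    if target_rows.size == 0:
        raise ValueError(f"target populations {spec.target_pops} not in panel")
    col = panel.alleles[target_rows, j]
    if col.min() == col.max():
        raise ValueError("focal SNP monomorphic in target population")

    donors = target_rows[col == spec.focal_allele]
    if donors.size == 0:
        raise ValueError(
            f"no target chromosome carries allele {spec.focal_allele}")
    donor = int(donors[rng.integers(donors.size)])
    donor_hap = panel.alleles[donor]

    n_recip = max(1, int(round(spec.carrier_fraction * target_rows.size)))
    recipients = rng.choice(target_rows, size=n_recip, replace=False)

    cm = panel.pos_cM
    focal_cm = cm[j]
    for r in recipients:
        if spec.decay_scale_cM == np.inf:
            mask = np.ones(panel.n_snps, dtype=bool)
        else:
            d_left = rng.exponential(spec.decay_scale_cM)
            d_right = rng.exponential(spec.decay_scale_cM)
            mask = (cm >= focal_cm - d_left) & (cm <= focal_cm + d_right)
        mask &= panel.chrom == panel.chrom[j]
        alleles[r, mask] = donor_hap[mask]

    out = replace(panel, alleles=alleles)
    return out
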