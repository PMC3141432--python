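import numpy as np
import pytest

from haploscan import GenicTrack, HaplotypePanel, SimConfig, simulate_panel


def make_panel(alleles, pos_bp=None, pos_cM=None, pops=None, chrom="1"):
    """Small hand-built panel; one population per entry of *pops* or all 'p0'."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_snp = alleles.shape
    assert n_hap % 2 == 0
    if pos_bp is None:
        pos_bp = np.arange(1, n_snp + 1) * 100
    if pos_cM is None:
        pos_cM = np.asarray(pos_bp) * 1e-6
    if pops is None:
        pops = ["p0"] * (n_hap // 2)
    samples = [f"ind{k}" for k in range(n_hap // 2)]
    pop_of = {s: p for s, p in zip(samples, pops)}
    grp_of = {p: f"g_{p}" for p in set(pops)}
    return HaplotypePanel(
        alleles=alleles,
        snp_ids=np.array([f"snp{i}" for i in range(n_snp)]),
        chrom=np.full(n_snp, chrom),
        pos_bp=np.asarray(pos_bp, dtype=np.int64),
        pos_cM=np.asarray(pos_cM, dtype=np.float64),
        sample_of_row=np.repeat(samples, 2),
        population_of_sample=pop_of,
        group_of_population=grp_of,
    )


@pytest.fixture
def ehh_panel():
    """10 chromosomes, block SNPs 0-1, two extension SNPs.

    Core '11' carriers extend as {a, a, b, c}; core '00' carriers extend
    as {d, d, d, e, f, f}: the hand-enumerated EHH = 1/6, REHH = 0.625
    configuration.
    """
    car = [[1, 1, 0, 0], [1, 1, 0, 0], [1, 1, 0, 1], [1, 1, 1, 0]]
    oth = [[0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0],
           [0, 0, 0, 1], [0, 0, 1, 0], [0, 0, 1, 0]]
    return make_panel(car + oth, pos_bp=[100, 200, 300, 400])


@pytest.fixture(scope="session")
def sim_panel():
    """Session-wide 4-population simulated panel with genic track and map."""
    cfg = SimConfig(n_pops=4, haplotypes_per_pop=40, n_snps=800,
                    chrom_length_bp=8_000_000, F_target=0.05, seed=11)
    return simulate_panel(cfg)


@pytest.fixture
def uniform_genic(request):
    """All-genic track for an arbitrary SNP count."""
    def _make(n):
        return GenicTrack(np.ones(n, dtype=bool))
    return _make
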