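import numpy as np
import pytest

from haploscan import (core_haplotypes, ehh, empirical_p, frequency_bin,
                       gabriel_blocks, ld_pair, rehh, scan_rehh)
from haploscan.ehh import RehhRecord, attach_empirical_p

from conftest import make_panel


def panel_from_haplotype_counts(hap_counts, pos_bp=None):
    """Two-SNP panel from {(a,b): count}."""
    rows = []
    for (a, b), k in hap_counts.items():
        rows.extend([[a, b]] * k)
    if len(rows) % 2:
        rows.append(rows[-1])
    return make_panel(np.array(rows, np.uint8), pos_bp=pos_bp or [100, 200])


class TestLdPair:
    def test_perfect_coupling(self):
        panel = panel_from_haplotype_counts({(0, 0): 50, (1, 1): 50})
        lp = ld_pair(panel, 0, 1)
        assert lp.d_prime == pytest.approx(1.0)
        assert lp.r2 == pytest.approx(1.0)

    def test_independent_sites(self):
        panel = panel_from_haplotype_counts(
            {(0, 0): 25, (0, 1): 25, (1, 0): 25, (1, 1): 25})
        lp = ld_pair(panel, 0, 1)
        assert lp.d_prime == pytest.approx(0.0, abs=1e-9)
        assert lp.r2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_counts(self):
        # counts (00:45, 01:5, 10:5, 11:45): D/Dmax and correlation by hand
        panel = panel_from_haplotype_counts(
            {(0, 0): 45, (0, 1): 5, (1, 0): 5, (1, 1): 45})
        lp = ld_pair(panel, 0, 1)
        assert lp.r2 == pytest.approx(0.64, abs=1e-12)
        assert lp.d_prime == pytest.approx(0.8, abs=1e-12)
        assert lp.ci_low <= 0.8 <= lp.ci_high

    def test_orientation_invariance(self):
        panel = panel_from_haplotype_counts(
            {(0, 0): 40, (0, 1): 10, (1, 0): 20, (1, 1): 30})
        flipped = make_panel(1 - panel.alleles, pos_bp=[100, 200])
        a, b = ld_pair(panel, 0, 1), ld_pair(flipped, 0, 1)
        assert a.d_prime == pytest.approx(b.d_prime)
        assert a.r2 == pytest.approx(b.r2)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-9)

    def test_ci_bounds_ordered(self):
        panel = panel_from_haplotype_counts(
            {(0, 0): 30, (0, 1): 20, (1, 0): 15, (1, 1): 35})
        lp = ld_pair(panel, 0, 1)
        assert 0.0 <= lp.ci_low <= lp.ci_high <= 1.0

    def test_monomorphic_rejected(self):
        panel = panel_from_haplotype_counts({(0, 0): 50, (0, 1): 50})
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(panel, 0, 1)


class TestGabrielBlocks:
    def test_two_perfectly_coupled_snps_one_block(self):
        panel = panel_from_haplotype_counts({(0, 0): 50, (1, 1): 50})
        blocks = gabriel_blocks(panel, np.array([0, 1]))
        assert len(blocks) == 1
        assert blocks[0].tolist() == [0, 1]

    def test_two_independent_snps_two_singletons(self):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(200, 2)).astype(np.uint8)
        panel = make_panel(alleles, pos_bp=[100, 200])
        blocks = gabriel_blocks(panel, np.array([0, 1]))
        assert len(blocks) == 2
        assert all(b.size == 1 for b in blocks)

    def test_strong_ld_plus_strong_recomb_splits(self):
        # SNPs 0,1 perfectly coupled; SNP 2 independent of both
        rng = np.random.default_rng(1)
        n = 200
        a = rng.integers(0, 2, size=n).astype(np.uint8)
        c = rng.integers(0, 2, size=n).astype(np.uint8)
        panel = make_panel(np.column_stack([a, a, c]),
                           pos_bp=[100, 200, 300])
        blocks = gabriel_blocks(panel, np.arange(3))
        assert sorted(b.tolist() for b in blocks) == [[0, 1], [2]]

    def test_rare_snps_ignored(self):
        rng = np.random.default_rng(2)
        n = 200
        a = rng.integers(0, 2, size=n).astype(np.uint8)
        rare = np.zeros(n, np.uint8)
        rare[:2] = 1  # MAF 0.01 < 0.05
        panel = make_panel(np.column_stack([a, rare, a]),
                           pos_bp=[100, 200, 300])
        blocks = gabriel_blocks(panel, np.arange(3))
        flat = np.concatenate(blocks)
        assert 1 not in flat

    def test_block_partition_property(self, sim_panel):
        panel, _, _ = sim_panel
        region = np.arange(100)
        blocks = gabriel_blocks(panel, region)
        flat = np.concatenate(blocks)
        assert len(flat) == len(set(flat.tolist()))
        for block in blocks:
            cores = core_haplotypes(panel, block)
            assert sum(c.carriers.size for c in cores) == panel.n_haplotypes

    def test_empty_region_rejected(self, sim_panel):
        panel, _, _ = sim_panel
        with pytest.raises(ValueError):
            gabriel_blocks(panel, np.array([], dtype=int))


class TestEhh:
    def test_distance_zero_is_one(self, ehh_panel):
        cores = core_haplotypes(ehh_panel, [0, 1])
        for core in cores:
            assert ehh(ehh_panel, core, "downstream", 0.0) == 1.0

    def test_hand_enumerated_one_sixth(self, ehh_panel):
        core = [c for c in core_haplotypes(ehh_panel, [0, 1])
                if c.core_string == "11"][0]
        got = ehh(ehh_panel, core, "downstream", 200.0)
        assert got == pytest.approx(1 / 6)

    def test_identical_carriers_stay_at_one(self):
        alleles = np.tile(np.array([[1, 1, 0, 1, 0]], np.uint8), (4, 1))
        other = np.array([[0, 0, 1, 0, 1]] * 2, np.uint8)
        panel = make_panel(np.vstack([alleles, other]))
        core = [c for c in core_haplotypes(panel, [0, 1])
                if c.core_string == "11"][0]
        for d in (0.0, 100.0, 300.0):
            assert ehh(panel, core, "downstream", d) == 1.0

    def test_fewer_than_two_carriers_rejected(self, ehh_panel):
        cores = core_haplotypes(ehh_panel, [0, 1])
        solo = cores[0]
        solo = type(solo)(solo.block_snps, solo.core_alleles,
                          np.array([0]), 0.1)
        with pytest.raises(ValueError):
            ehh(ehh_panel, solo, "downstream", 100.0)

    def test_monotone_non_increasing_with_distance(self, sim_panel):
        panel, _, _ = sim_panel
        blocks = gabriel_blocks(panel, np.arange(60))
        for block in blocks[:10]:
            for core in core_haplotypes(panel, block, min_freq=0.05):
                if core.carriers.size < 2:
                    continue
                pos = panel.pos_bp
                dists = np.linspace(0, 2_000_000, 9)
                vals = [ehh(panel, core, "downstream", d) for d in dists]
                assert np.all(np.diff(vals) <= 1e-12)


class TestRehh:
    def test_hand_enumerated_ratio(self, ehh_panel):
        core = [c for c in core_haplotypes(ehh_panel, [0, 1])
                if c.core_string == "11"][0]
        assert rehh(ehh_panel, core, "downstream", 200.0) \
            == pytest.approx(0.625)

    def test_identical_decay_gives_one(self):
        # two cores whose carriers all stay internally identical
        a = np.tile(np.array([[1, 1, 0, 0]], np.uint8), (4, 1))
        b = np.tile(np.array([[0, 0, 1, 1]], np.uint8), (4, 1))
        panel = make_panel(np.vstack([a, b]))
        core = [c for c in core_haplotypes(panel, [0, 1])
                if c.core_string == "11"][0]
        assert rehh(panel, core, "downstream", 200.0) == pytest.approx(1.0)

    def test_ratio_of_four(self):
        # core fully homozygous; 4 pooled others in two equal groups:
        # pooled EHH = (C(2,2)*2)/C(4,2) = 2/6 -> REHH = 3.0
        car = np.tile(np.array([[1, 1, 0, 0]], np.uint8), (4, 1))
        oth = np.array([[0, 0, 0, 0], [0, 0, 0, 0],
                        [0, 0, 1, 1], [0, 0, 1, 1]], np.uint8)
        panel = make_panel(np.vstack([car, oth]))
        core = [c for c in core_haplotypes(panel, [0, 1])
                if c.core_string == "11"][0]
        assert rehh(panel, core, "downstream", 200.0) == pytest.approx(3.0)

    def test_single_core_block_rejected(self):
        alleles = np.tile(np.array([[1, 0, 1]], np.uint8), (6, 1))
        panel = make_panel(alleles)
        core = core_haplotypes(panel, [0])[0]
        with pytest.raises(ValueError, match="single-core"):
            rehh(panel, core, "downstream", 100.0)


class TestEmpiricalP:
    def make_records(self, rehh_values, freq=0.30):
        return [RehhRecord(0, 0, "1", freq, "downstream", 300_000.0, v)
                for v in rehh_values]

    def test_extreme_rank(self):
        rng = np.random.default_rng(3)
        records = self.make_records(rng.uniform(0, 1, size=199))
        query = RehhRecord(9, 9, "1", 0.30, "downstream", 300_000.0, 2.0)
        p, unstable = empirical_p(records, query)
        assert p == pytest.approx(1 / 200)
        assert not unstable

    def test_median_rank(self):
        records = self.make_records(np.linspace(0, 1, 201))
        query = RehhRecord(9, 9, "1", 0.30, "downstream", 300_000.0, 0.5)
        p, _ = empirical_p(records, query)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_query_excluded_from_own_null(self):
        records = self.make_records(np.linspace(0, 1, 100))
        query = records[-1]  # in the scanned set
        p, _ = empirical_p(records, query)
        assert p == pytest.approx(1 / 100)  # 99 remaining records

    def test_underpopulated_bin_widens_and_flags(self):
        sparse = self.make_records([1.0] * 5, freq=0.30)
        dense = self.make_records(np.linspace(0, 1, 50), freq=0.35)
        query = RehhRecord(9, 9, "1", 0.30, "downstream", 300_000.0, 2.0)
        p, unstable = empirical_p(sparse + dense, query)
        assert unstable
        assert p == pytest.approx(1 / 56)

    def test_frequency_bins(self):
        assert frequency_bin(0.0501) == 0
        assert frequency_bin(0.10) == 0
        assert frequency_bin(0.101) == 1
        assert frequency_bin(1.0) == 18
        with pytest.raises(ValueError):
            frequency_bin(0.05)
        with pytest.raises(ValueError):
            frequency_bin(1.2)


class TestScan:
    def test_scan_produces_records_and_attaches_p(self, sim_panel):
        panel, _, _ = sim_panel
        rows = panel.rows_of_group("grp0")
        records = scan_rehh(panel, np.arange(300), rows,
                            distances=(300_000.0,))
        assert records, "scan found no records"
        region = [r for r in records if r.block_start < 150]
        attach_empirical_p(records, region, min_bin_size=10)
        for r in region:
            assert 0.0 < r.empirical_p <= 1.0
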