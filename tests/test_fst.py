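import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploscan import (WindowSpec, expanding_scan, global_theta,
                       multilocus_theta, pair_theta, snps_in_window,
                       wc_theta, window_mean_fst)
from haploscan.fst import mean_defined

from conftest import make_panel


def theta_oracle(sizes, counts):
    """Independent haploid variance-component oracle via mean squares.

    MSG = within mean square, MSP = between mean square;
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG), clamped at 0.
    """
    n = np.asarray(sizes, float)
    c = np.asarray(counts, float)
    r = n.size
    nsum = n.sum()
    p = c / n
    pbar = c.sum() / nsum
    if pbar in (0.0, 1.0):
        return np.nan
    msp = (n * (p - pbar) ** 2).sum() / (r - 1)
    msg = (n * p * (1 - p)).sum() / (nsum - r)
    n_c = (nsum - (n ** 2).sum() / nsum) / (r - 1)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return 0.0
    return float(np.clip((msp - msg) / denom, 0.0, 1.0))


class TestWcTheta:
    def test_equal_frequencies_clamp_to_zero(self):
        assert wc_theta([20, 20], [10, 10]) == 0.0

    def test_fixed_difference_is_exactly_one(self):
        assert wc_theta([20, 20], [20, 0]) == 1.0

    def test_worked_two_population_value(self):
        # independently hand-evaluated variance components
        assert wc_theta([20, 20], [10, 2]) == pytest.approx(0.284210526315789,
                                                            abs=1e-12)

    def test_monomorphic_site_undefined(self):
        assert np.isnan(wc_theta([20, 20], [0, 0]))
        assert np.isnan(wc_theta([20, 20], [20, 20]))

    def test_matches_mean_square_oracle_random_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            r = int(rng.integers(2, 6))
            n = rng.integers(2, 80, size=r)
            c = np.array([rng.integers(0, ni + 1) for ni in n])
            got = wc_theta(n, c)
            want = theta_oracle(n, c)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(1)
        n = np.array([30, 50, 20])
        c = np.vstack([rng.integers(0, ni + 1, size=40) for ni in n])
        vec = wc_theta(n, c)
        for j in range(40):
            scalar = wc_theta(n, c[:, j])
            if np.isnan(scalar):
                assert np.isnan(vec[j])
            else:
                assert vec[j] == pytest.approx(scalar, abs=1e-15)

    def test_errors(self):
        with pytest.raises(ValueError):
            wc_theta([20], [10])
        with pytest.raises(ValueError):
            wc_theta([20, 1], [10, 1])
        with pytest.raises(ValueError):
            wc_theta([20, 20], [25, 0])

    @given(st.integers(2, 60), st.integers(2, 60),
           st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=200, deadline=None)
    def test_orientation_and_pair_symmetry(self, n1, n2, c1, c2):
        c1, c2 = min(c1, n1), min(c2, n2)
        t = wc_theta([n1, n2], [c1, c2])
        flipped = wc_theta([n1, n2], [n1 - c1, n2 - c2])
        swapped = wc_theta([n2, n1], [c2, c1])
        if np.isnan(t):
            assert np.isnan(flipped) and np.isnan(swapped)
        else:
            assert flipped == pytest.approx(t, abs=1e-12)
            assert swapped == pytest.approx(t, abs=1e-12)
            assert 0.0 <= t <= 1.0


class TestPanelTheta:
    def test_orientation_symmetry_on_panel(self, sim_panel):
        panel, _, _ = sim_panel
        theta = pair_theta(panel, "grp0", "grp1")
        import dataclasses
        flipped = dataclasses.replace(panel, alleles=1 - panel.alleles)
        theta_f = pair_theta(flipped, "grp0", "grp1")
        assert np.allclose(theta, theta_f, equal_nan=True)

    def test_population_vs_group_labels(self, sim_panel):
        panel, _, _ = sim_panel
        # each simulated group holds exactly one population
        a = pair_theta(panel, "pop0", "pop1")
        b = pair_theta(panel, "grp0", "grp1")
        assert np.allclose(a, b, equal_nan=True)


class TestWindowMean:
    def test_mean_with_skip_rule(self):
        theta = np.array([0.0, 0.5, np.nan])
        wm = mean_defined(theta, np.array([True, True, True]))
        assert wm.mean_theta == pytest.approx(0.25)
        assert wm.n_snps == 2

    def test_all_monomorphic_flags_empty(self):
        theta = np.array([np.nan, np.nan])
        wm = mean_defined(theta, np.array([True, True]))
        assert not wm.defined

    def test_window_membership_closed_interval(self):
        panel = make_panel(np.zeros((2, 5), np.uint8),
                           pos_bp=[100, 200, 300, 400, 500])
        mask = snps_in_window(panel, WindowSpec("1", 300, 100, "bp"))
        assert mask.tolist() == [False, True, True, True, False]

    def test_cM_windows_select_by_genetic_distance(self):
        panel = make_panel(np.zeros((2, 4), np.uint8),
                           pos_bp=[100, 200, 300, 400],
                           pos_cM=[0.0, 0.1, 0.5, 0.9])
        mask = snps_in_window(panel, WindowSpec("1", 0.1, 0.15, "cM"))
        assert mask.tolist() == [True, True, False, False]

    def test_simulated_window_mean_tracks_F(self):
        # frozen from the large-replicate oracle: mean per-SNP clamped
        # theta under F=0.1 Balding-Nichols sits near 0.083 (Jensen bias
        # of the per-SNP ratio); the +-0.03 band contains it
        from haploscan import SimConfig, simulate_panel
        cfg = SimConfig(n_pops=2, haplotypes_per_pop=100, n_snps=400,
                        F_target=0.1, seed=5)
        panel, _, _ = simulate_panel(cfg)
        theta = pair_theta(panel, "grp0", "grp1")
        spec = WindowSpec("1", float(panel.pos_bp[200]), 4_000_000, "bp")
        wm = window_mean_fst(panel, ("grp0", "grp1"), spec, theta=theta)
        assert wm.n_snps > 100
        assert wm.mean_theta == pytest.approx(0.1, abs=0.03)


class TestExpandingScan:
    def test_default_size_list_is_six_doubling_windows(self, sim_panel):
        panel, _, _ = sim_panel
        rows = expanding_scan(panel, ("grp0", "grp1"), 400)
        assert [s for s, _, _ in rows] == [50, 100, 200, 400, 800, 1600]
        assert len(rows) == 6

    def test_constant_field_gives_identical_means(self):
        # every SNP column identical -> same theta everywhere
        col = np.array([1, 0, 1, 0, 0, 0, 1, 1], np.uint8)
        alleles = np.tile(col[:, None], (1, 9))
        panel = make_panel(alleles, pops=["a", "a", "b", "b"],
                           pos_bp=np.arange(1, 10) * 50_000)
        rows = expanding_scan(panel, ("g_a", "g_b"), 4, sizes_kb=(50, 100, 200))
        means = {wm.mean_theta for _, _, wm in rows}
        assert len(means) == 1

    def test_monomorphic_focal_with_polymorphic_neighbours(self):
        rng = np.random.default_rng(2)
        alleles = rng.integers(0, 2, size=(8, 9)).astype(np.uint8)
        alleles[:, 4] = 0  # focal SNP monomorphic
        panel = make_panel(alleles, pops=["a", "a", "b", "b"],
                           pos_bp=np.arange(1, 10) * 10_000)
        rows = expanding_scan(panel, ("g_a", "g_b"), 4,
                              sizes_kb=(50, 100, 200))
        assert all(wm.defined for _, _, wm in rows)

    def test_cM_analogue_runs(self, sim_panel):
        panel, _, _ = sim_panel
        rows = expanding_scan(panel, ("grp0", "grp1"), 400, unit="cM")
        assert len(rows) == 6
        assert all(wm.n_snps >= 0 for _, _, wm in rows)


def test_multilocus_theta_recovers_F():
    from haploscan import SimConfig, simulate_panel
    from haploscan.fst import allele_counts
    cfg = SimConfig(n_pops=2, haplotypes_per_pop=100, n_snps=2000,
                    F_target=0.2, seed=7)
    panel, _, _ = simulate_panel(cfg)
    rows = [panel.rows_of_group(g) for g in ("grp0", "grp1")]
    sizes = [r.size for r in rows]
    counts = np.vstack([allele_counts(panel, r) for r in rows])
    assert multilocus_theta(sizes, counts) == pytest.approx(0.2, abs=0.02)


class TestGlobalTheta:
    def test_bounds_and_symmetry(self, sim_panel):
        panel, _, _ = sim_panel
        theta = global_theta(panel)
        ok = theta[~np.isnan(theta)]
        assert np.all((ok >= 0) & (ok <= 1))
        import dataclasses
        flipped = dataclasses.replace(panel, alleles=1 - panel.alleles)
        assert np.allclose(theta, global_theta(flipped), equal_nan=True)

    def test_subset_of_groups(self, sim_panel):
        panel, _, _ = sim_panel
        t3 = global_theta(panel, ["grp0", "grp1", "grp2"])
        assert t3.shape == (panel.n_snps,)
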