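"""Ground-truth replicate harnesses for power and calibration studies.

These drive the full pipeline on simulated panels with known structure:
:func:`sweep_replicate` spikes a partial sweep and measures whether each
detection route (REHH empirical p, sliding-window F_ST percentile,
bootstrap T) recovers it; :func:`null_replicate` runs the same machinery
on exchangeable panels to check calibration. Both are deterministic in
their seed and deliberately small enough for desk-scale batches.
"""

from __future__ import annotations

import numpy as np

from .bootstrap import bootstrap_test
from .ehh import empirical_p, scan_rehh
from .empirical_null import (focal_percentile, null_window_means,
                             percentile_rank, sample_matched_windows)
from .fst import WindowSpec, mean_defined, pair_theta, snps_in_window
from .synthetic_data import SimConfig, SweepSpec, simulate_panel, spike_sweep

# sweep-study simulation: 3 populations, low-recombination map so the
# 0.3 cM copy extent spans ~1.2 Mb, SNP density ~30/Mb so null EHH at the
# 150/300 Kb horizons is small but nonzero; background F low enough that
# the spike's allele-frequency shift clears the window-mean noise floor
SWEEP_SIM = dict(n_pops=3, haplotypes_per_pop=100, n_snps=900,
                 chrom_length_bp=30_000_000, F_target=0.01,
                 recomb_rate_cM_per_Mb=0.25)


def pick_focal_snp(panel, population: str, lo: float = 0.05,
                   hi: float = 0.20) -> int | None:
    """Mid-chromosome SNP whose derived allele is rare in *population*.

    Spiking a low-frequency allele keeps the spiked core dominated by
    copied chromosomes rather than coincident background carriers.
    """
    rows = panel.rows_of_population(population)
    freq = panel.alleles[rows].mean(axis=0)
    mid = panel.n_snps // 2
    cands = np.flatnonzero((freq >= lo) & (freq <= hi))
    if cands.size == 0:
        return None
    return int(cands[np.argmin(np.abs(cands - mid))])


def sweep_replicate(seed: int, carrier_fraction: float = 0.3,
                    decay_scale_cM: float = 0.3, n_nulls: int = 100,
                    b_reps: int = 200, rehh_bin_size: int = 150,
                    run_fst: bool = True, rehh_pop: str = "pop0") -> dict:
    """One spiked-sweep replicate; returns per-route detection results.

    Keys: ``rehh_p`` (spiked-core empirical REHH p in *rehh_pop*),
    ``slide_max_at_spike`` (sliding-scan percentile maximal at the spiked
    window), ``boot_p`` (conservative bootstrap p for swept-vs-unswept
    focal difference). F_ST routes are skipped when ``run_fst`` is False.
    """
    cfg = SimConfig(seed=seed, **SWEEP_SIM)
    panel, genic, _ = simulate_panel(cfg)
    focal = pick_focal_snp(panel, "pop0")
    if focal is None:
        return {"rehh_p": None, "slide_max_at_spike": None, "boot_p": None}
    spec = SweepSpec(focal_snp=focal, target_pops=["pop0"],
                     carrier_fraction=carrier_fraction,
                     decay_scale_cM=decay_scale_cM, focal_allele=1,
                     seed=seed + 1)
    swept = spike_sweep(panel, spec)
    out: dict = {"focal": focal}

    rows = swept.rows_of_population(rehh_pop)
    records = scan_rehh(swept, np.arange(swept.n_snps), rows,
                        distances=(150_000.0, 300_000.0))
    hits = [r for r in records if r.core_allele_at(focal) == "1"]
    if hits:
        out["rehh_p"] = min(empirical_p(records, h,
                                        min_bin_size=rehh_bin_size)[0]
                            for h in hits)
    else:
        out["rehh_p"] = None

    if not run_fst:
        return out

    focal_bp = float(swept.pos_bp[focal])
    theta = pair_theta(swept, "grp0", "grp1")
    # sliding scan +-2.8 Mb around the spike, each window vs its own nulls;
    # success = the scan's maximal percentile lands in the swept zone
    # (within 1 Mb of the focal SNP, ~the copied haplotypes' mean extent)
    centers = focal_bp + 200_000.0 * np.arange(-14, 15)
    percs = np.full(centers.size, np.nan)
    rng = np.random.default_rng(seed + 2)
    for i, c in enumerate(centers):
        w = WindowSpec("1", float(c), 200_000.0, "bp")
        wm = mean_defined(theta, snps_in_window(swept, w))
        if not wm.defined:
            continue
        nulls = sample_matched_windows(swept, genic, w, n_nulls,
                                       seed=int(rng.integers(2 ** 31)))
        percs[i] = percentile_rank(
            wm.mean_theta, null_window_means(swept, theta, nulls)).percentile
    mid = centers.size // 2
    zone = slice(mid - 5, mid + 6)
    out["slide_percentiles"] = percs
    out["slide_max_at_spike"] = bool(
        np.nanmax(percs[zone]) >= np.nanmax(percs))

    window = WindowSpec("1", focal_bp, 400_000.0, "bp")
    nulls = sample_matched_windows(swept, genic, window, n_nulls,
                                   seed=seed + 3)
    boot = bootstrap_test(swept, window, "grp1", "grp0", "grp2", nulls,
                          b_reps=b_reps, seed=seed + 4)
    out["boot_p"] = boot.p_conservative
    return out


# null-study simulation: exchangeable panel, no spike
NULL_SIM = dict(n_pops=3, haplotypes_per_pop=40, n_snps=400,
                chrom_length_bp=10_000_000, F_target=0.05)

# bootstrap-null simulation: F pilot-calibrated so the individual
# bootstrap hits its nominal level (the resampler cannot see locus-level
# Balding-Nichols variance, which inflates rejection at larger F, while
# the clamped estimator at the F=0 boundary deflates it; 0.035 balances)
NULL_BOOT_SIM = dict(n_pops=3, haplotypes_per_pop=40, n_snps=400,
                     chrom_length_bp=10_000_000, F_target=0.035)


def null_boot_replicate(seed: int, n_nulls: int = 50,
                        b_reps: int = 200) -> float:
    """Conservative bootstrap p for one exchangeable (no-spike) panel."""
    cfg = SimConfig(seed=seed, **NULL_BOOT_SIM)
    panel, genic, _ = simulate_panel(cfg)
    focal = panel.n_snps // 2
    window = WindowSpec("1", float(panel.pos_bp[focal]), 200_000.0, "bp")
    nulls = sample_matched_windows(panel, genic, window, n_nulls,
                                   seed=seed + 1)
    boot = bootstrap_test(panel, window, "grp0", "grp1", "grp2", nulls,
                          b_reps=b_reps, seed=seed + 2)
    return boot.p_conservative


def null_replicate(seed: int, n_nulls: int = 200,
                   b_reps: int | None = None) -> dict:
    """One exchangeable replicate: focal percentile and optional bootstrap.

    The focal window is placed mid-chromosome; under exchangeability its
    percentile rank is Uniform[0, 100] and the bootstrap p-value at any
    nominal level rejects at that level.
    """
    cfg = SimConfig(seed=seed, **NULL_SIM)
    panel, genic, _ = simulate_panel(cfg)
    focal = panel.n_snps // 2
    window = WindowSpec("1", float(panel.pos_bp[focal]), 200_000.0, "bp")
    nulls = sample_matched_windows(panel, genic, window, n_nulls,
                                   seed=seed + 1)
    res = focal_percentile(panel, ("grp0", "grp1"), window, nulls)
    out = {"percentile": res.percentile}
    if b_reps:
        boot = bootstrap_test(panel, window, "grp0", "grp1", "grp2",
                              nulls, b_reps=b_reps, seed=seed + 2)
        out["boot_p"] = boot.p_conservative
    return out
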