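# haploscan

Selection scans on phased haplotype panels:

* **Per-SNP Weir–Cockerham F_ST** (haploid/chromosome-level variance
  components, negative estimates clamped to 0, monomorphic sites skipped)
  averaged over bp- or cM-defined windows, including an expanding-window
  scan (50 Kb → 1.6 Mb, doubling) centred on a focal SNP.
* **Genic-matched empirical nulls**: each focal window is ranked against N
  random same-size windows on the same chromosome whose genic SNP
  fraction matches within ±10 percentage points; mid-rank percentiles,
  group-specific F_ST summaries (mean of a group's pairwise ranks),
  sliding-window scans (default 400 Kb / 200 Kb step) and all-populations
  pairwise percentile matrices.
* **Bootstrap test** of whether the focal-window F_ST difference between
  two population pairs exceeds the chromosomal background difference:
  individuals resampled with replacement within populations over fixed
  windows; conservative exceedance p (minimum 1/(B+1)) and an asymptotic
  chi-square(1) p for (T/σ̂)².
* **EHH/REHH scan**: haplotype blocks from D′ confidence-interval
  criteria on phased two-locus counts, block cores (frequency > 5%),
  bidirectional EHH decay, REHH at 150/300 Kb, and frequency-binned
  empirical p-values against the chromosome-wide core distribution, with
  extreme-count enrichment tables, two-sided Fisher exact tests and Q-Q
  series.
* **Synthetic panels**: a Balding–Nichols simulator (known
  differentiation F, genetic map, genic track) plus a partial-sweep
  spiker (copies one donor haplotype into a fraction of a target
  population with exponentially distributed extents in cM), so every
  statistic can be validated against ground truth.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the slow end-to-end calibration and
power checks (simulation batches); the rest of the suite is fast.

## CLI

```sh
haploscan simulate --n-pops 4 --haplotypes-per-pop 60 --n-snps 2000 \
    --f-target 0.05 --seed 1 --out-prefix demo/panel

haploscan fst-scan  --haplotypes demo/panel.haps.tsv --sample-map demo/panel.samples.tsv \
    --pair grp0,grp1 --focal-snp snp1000 --out demo/expand.tsv
haploscan fst-null  --haplotypes ... --pair grp0,grp1 --focal-snp snp1000 \
    --window-kb 400 --n-nulls 1000 --seed 1 --out demo/null.tsv
haploscan fst-slide --haplotypes ... --pair grp0,grp1 --chrom 1 \
    --start 1000000 --end 7000000 --out demo/slide.tsv
haploscan boot-test --haplotypes ... --focal-snp snp1000 \
    --pop-a grp1 --pop-b grp0 --pop-c grp2 --reps 1000 --seed 1 --out demo/boot.json
haploscan rehh-scan --haplotypes ... --group grp0 --chrom 1 \
    --region-start 4000000 --region-end 6000000 --out demo/rehh.tsv
haploscan enrich    --rehh-table grp0=demo/rehh.tsv --rehh-table grp1=... \
    --out demo/enrich.tsv
haploscan run-all   --config run.yaml --out-dir demo/out
```

Inputs are a tabular haplotype dialect (metadata rows `#snp_id`,
`#chrom`, `#pos_bp`, `#pos_cM`, `#genic`, then one row per chromosome
copy) or phased VCF, plus a TSV sample map (sample, population, group), a
TSV genetic map and a BED genic track. All outputs are TSV/JSON and carry
the producing seed and a config hash.

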