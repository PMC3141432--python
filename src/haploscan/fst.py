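"""Per-SNP Weir–Cockerham F_ST on haploid (chromosome-level) samples.

The estimator is the 1984 variance-component ratio a/(a+b) specialised to
haploid data (no within-individual component). Per-SNP estimates are
clamped to 0 when negative and undefined (NaN) at sites monomorphic
across the samples being compared; window statistics are arithmetic means
of the clamped per-SNP values, skipping undefined sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import HaplotypePanel

DEFAULT_EXPANDING_SIZES_KB = (50, 100, 200, 400, 800, 1600)


def wc_components(sizes, counts):
    """Haploid Weir–Cockerham variance components per SNP.

    Parameters
    ----------
    sizes
        (r,) haplotype sample size per population.
    counts
        (r,) or (r, n_snps) derived-allele count per population.

    Returns
    -------
    (a, b)
        Between- and within-population variance components (1-D arrays);
        NaN at sites monomorphic across the populations compared.
    """
    n = np.asarray(sizes, dtype=np.float64)
    c = np.asarray(counts, dtype=np.float64)
    if c.ndim == 1:
        c = c[:, None]
    r = n.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    if np.any(n < 2):
        raise ValueError("each population needs at least two haplotypes")
    if np.any(c > n[:, None]) or np.any(c < 0):
        raise ValueError("allele count outside [0, n_i]")

    nsum = n.sum()
    nbar = nsum / r
    n_c = (nsum - (n ** 2).sum() / nsum) / (r - 1)
    p_i = c / n[:, None]
    pbar = c.sum(axis=0) / nsum
    s2 = (n[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)

    inner = pbar * (1.0 - pbar) - s2 * (r - 1) / r
    b = nbar / (nbar - 1.0) * inner
    a = nbar / n_c * (s2 - inner / (nbar - 1.0))
    mono = (pbar == 0.0) | (pbar == 1.0)
    a = np.where(mono, np.nan, a)
    b = np.where(mono, np.nan, b)
    return a, b


def wc_theta(sizes, counts):
    """Per-SNP haploid Weir–Cockerham theta a/(a+b), clamped to [0, 1].

    Returns a float for 1-D counts, else a 1-D array; NaN where the site
    is monomorphic across the populations compared.
    """
    scalar = np.asarray(counts).ndim == 1
    a, b = wc_components(sizes, counts)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(denom != 0.0, a / np.where(denom == 0, 1, denom), 0.0)
    theta = np.clip(theta, 0.0, 1.0)
    theta = np.where(np.isnan(denom), np.nan, theta)
    if scalar:
        return float(theta[0])
    return theta


def multilocus_theta(sizes, counts) -> float:
    """Multi-locus Weir–Cockerham theta: ratio of summed components.

    Sums the per-SNP variance components over defined sites before taking
    the ratio. Unlike the mean of per-SNP ratios, this combination is a
    consistent estimator of the differentiation parameter and is the one
    to use for parameter recovery; windows average the per-SNP ratios
    because that is the window statistic everything downstream ranks.
    """
    a, b = wc_components(sizes, counts)
    num = np.nansum(a)
    den = np.nansum(a + b)
    if den == 0:
        return np.nan
    return float(num / den)


def allele_counts(panel: HaplotypePanel, rows: np.ndarray) -> np.ndarray:
    """Derived-allele count per SNP over a row subset."""
    return panel.alleles[rows].sum(axis=0, dtype=np.int64)


def _resolve_rows(panel: HaplotypePanel, label: str) -> np.ndarray:
    """Rows of a group (populations pooled) or of a single population."""
    if label in panel.group_of_population.values():
        return panel.rows_of_group(label)
    if label in panel.populations:
        return panel.rows_of_population(label)
    raise KeyError(f"unknown group/population label {label!r}")


def pair_theta(panel: HaplotypePanel, label_a: str, label_b: str) -> np.ndarray:
    """Per-SNP clamped theta for a pair of groups or populations."""
    rows_a = _resolve_rows(panel, label_a)
    rows_b = _resolve_rows(panel, label_b)
    sizes = np.array([rows_a.size, rows_b.size])
    counts = np.vstack([allele_counts(panel, rows_a),
                        allele_counts(panel, rows_b)])
    return wc_theta(sizes, counts)


def global_theta(panel: HaplotypePanel, labels=None) -> np.ndarray:
    """Per-SNP theta over all groups (default) or the given labels."""
    if labels is None:
        labels = panel.groups
    rows = [_resolve_rows(panel, g) for g in labels]
    sizes = np.array([r.size for r in rows])
    counts = np.vstack([allele_counts(panel, r) for r in rows])
    return wc_theta(sizes, counts)


@dataclass
class WindowSpec:
    """A closed interval [center - half_width, center + half_width]."""

    chrom: str
    center: float
    half_width: float
    unit: str = "bp"  # "bp" or "cM"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.unit not in ("bp", "cM"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


def snps_in_window(panel: HaplotypePanel, window: WindowSpec) -> np.ndarray:
    """Boolean per-SNP mask of window membership (closed interval)."""
    pos = panel.pos_bp if window.unit == "bp" else panel.pos_cM
    return ((panel.chrom == window.chrom)
            & (pos >= window.lo) & (pos <= window.hi))


@dataclass
class WindowMean:
    """Mean clamped theta over defined SNPs of one window."""

    mean_theta: float
    n_snps: int

    @property
    def defined(self) -> bool:
        return self.n_snps > 0


def mean_defined(theta: np.ndarray, mask: np.ndarray) -> WindowMean:
    """Mean of per-SNP theta over a mask, skipping undefined (NaN) sites."""
    vals = theta[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return WindowMean(np.nan, 0)
    return WindowMean(float(vals.mean()), int(vals.size))


def window_mean_fst(panel: HaplotypePanel, labels, window: WindowSpec,
                    theta: np.ndarray | None = None) -> WindowMean:
    """Window-mean F_ST for a pair (2 labels) or a multi-group comparison.

    Passing a precomputed per-SNP *theta* avoids recomputation across many
    windows of the same comparison.
    """
    if theta is None:
        if isinstance(labels, str):
            raise TypeError("labels must be a sequence of labels")
        theta = (pair_theta(panel, labels[0], labels[1]) if len(labels) == 2
                 else global_theta(panel, labels))
    return mean_defined(theta, snps_in_window(panel, window))


def expanding_scan(panel: HaplotypePanel, labels, focal_snp: int,
                   sizes_kb=DEFAULT_EXPANDING_SIZES_KB, unit: str = "bp",
                   theta: np.ndarray | None = None):
    """Window means at doubling sizes centred on a focal SNP.

    *sizes_kb* are full window widths in Kb for unit="bp"; for unit="cM"
    they are read as full widths in units of 0.001 cM per "Kb" analogue
    (i.e. a 400 entry means 0.4 cM), keeping one size list for both modes.

    Returns a list of (size, WindowSpec, WindowMean).
    """
    if theta is None:
        theta = (pair_theta(panel, labels[0], labels[1]) if len(labels) == 2
                 else global_theta(panel, labels))
    chrom = panel.chrom[focal_snp]
    center = (panel.pos_bp[focal_snp] if unit == "bp"
              else panel.pos_cM[focal_snp])
    out = []
    for size in sizes_kb:
        half = size * 500.0 if unit == "bp" else size * 5e-4
        spec = WindowSpec(chrom, float(center), half, unit)
        out.append((size, spec, mean_defined(theta, snps_in_window(panel, spec))))
    return out
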