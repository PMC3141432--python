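"""Domain types and file I/O for phased haplotype panels.

The central object is :class:`HaplotypePanel`: a phased 0/1 allele matrix
with one row per chromosome copy (two consecutive rows per diploid
individual) and one column per SNP, plus per-SNP physical (bp) and genetic
(cM) coordinates and a sample -> population -> group labelling.

Auxiliary types carry the per-SNP genic annotation (:class:`GenicTrack`),
a piecewise-linear genetic map (:class:`GeneticMap`) and the list of focal
SNPs a scan is centred on (:class:`FocalSnpList`).

Supported on-disk formats:

* a simple tabular haplotype dialect (see :func:`read_panel_table`),
* phased VCF (``|``-separated genotypes) via cyvcf2,
* TSV sample maps (sample, population, group),
* TSV genetic maps (chrom, pos_bp, cM),
* BED genic annotation (half-open intervals, converted to per-SNP flags).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class PanelFormatError(ValueError):
    """Raised when an input file violates the panel format contract."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype matrix with coordinates and labels.

    Parameters
    ----------
    alleles
        uint8 matrix of shape (n_haplotypes, n_snps) with entries in {0, 1}.
        Rows 2k and 2k+1 belong to individual k.
    snp_ids
        SNP identifiers, one per column.
    chrom
        Chromosome label per SNP.
    pos_bp
        1-based physical position per SNP, strictly increasing within
        each chromosome.
    pos_cM
        Genetic position per SNP, non-decreasing within each chromosome.
    sample_of_row
        Sample identifier per haplotype row.
    population_of_sample
        Mapping sample id -> population label.
    group_of_population
        Mapping population label -> group label.
    """

    alleles: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cM: np.ndarray
    sample_of_row: np.ndarray
    population_of_sample: dict
    group_of_population: dict

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.pos_cM = np.asarray(self.pos_cM, dtype=np.float64)
        self.sample_of_row = np.asarray(self.sample_of_row)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n_hap, n_snp = self.alleles.shape
        if n_hap % 2 != 0:
            raise PanelFormatError(f"odd haplotype row count {n_hap}")
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelFormatError("non-binary allele code in matrix")
        for arr, name in ((self.snp_ids, "snp_ids"), (self.chrom, "chrom"),
                          (self.pos_bp, "pos_bp"), (self.pos_cM, "pos_cM")):
            if arr.shape[0] != n_snp:
                raise PanelFormatError(f"{name} length != SNP count")
        if self.sample_of_row.shape[0] != n_hap:
            raise PanelFormatError("sample_of_row length != haplotype count")
        for k in range(0, n_hap, 2):
            if self.sample_of_row[k] != self.sample_of_row[k + 1]:
                raise PanelFormatError(
                    f"rows {k},{k+1} belong to different samples")
        for c in np.unique(self.chrom):
            bp = self.pos_bp[self.chrom == c]
            cm = self.pos_cM[self.chrom == c]
            if np.any(np.diff(bp) <= 0):
                raise PanelFormatError(
                    f"pos_bp not strictly increasing on chromosome {c}")
            if np.any(np.diff(cm) < 0):
                raise PanelFormatError(
                    f"pos_cM decreasing on chromosome {c}")
        for s in self.samples:
            if s not in self.population_of_sample:
                raise PanelFormatError(f"sample {s!r} has no population")
        for p in set(self.population_of_sample.values()):
            if p not in self.group_of_population:
                raise PanelFormatError(f"population {p!r} has no group")

    # -- derived views ------------------------------------------------
    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def samples(self) -> np.ndarray:
        """Sample ids in row order (one entry per individual)."""
        return self.sample_of_row[::2]

    @property
    def population_of_row(self) -> np.ndarray:
        return np.array([self.population_of_sample[s]
                         for s in self.sample_of_row])

    @property
    def group_of_row(self) -> np.ndarray:
        return np.array([self.group_of_population[p]
                         for p in self.population_of_row])

    @property
    def populations(self) -> list:
        """Population labels in order of first appearance."""
        seen: dict = {}
        for p in self.population_of_row:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance."""
        seen: dict = {}
        for g in self.group_of_row:
            seen.setdefault(g, None)
        return list(seen)

    def rows_of_population(self, population: str) -> np.ndarray:
        return np.flatnonzero(self.population_of_row == population)

    def rows_of_group(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.group_of_row == group)

    def snp_index(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.snp_ids == snp_id)
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(hits[0])


@dataclass
class GenicTrack:
    """Boolean per-SNP flag: True iff the SNP lies in a transcribed region."""

    genic_flag: np.ndarray

    def __post_init__(self) -> None:
        self.genic_flag = np.asarray(self.genic_flag, dtype=bool)

    @classmethod
    def from_bed(cls, bed_path: str, panel: HaplotypePanel) -> "GenicTrack":
        """Convert half-open BED intervals to per-SNP flags (1-based SNPs)."""
        flags = np.zeros(panel.n_snps, dtype=bool)
        with open(bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                on = (panel.chrom == chrom) & (panel.pos_bp > start) \
                    & (panel.pos_bp <= end)
                flags |= on
        return cls(flags)


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM map, one anchor series per chromosome.

    Queries beyond the anchor range clamp to the terminal anchor value
    (zero extrapolation slope).
    """

    anchors: dict = field(default_factory=dict)  # chrom -> (bp, cM) arrays

    def add_chromosome(self, chrom: str, pos_bp, pos_cM) -> None:
        bp = np.asarray(pos_bp, dtype=np.float64)
        cm = np.asarray(pos_cM, dtype=np.float64)
        order = np.argsort(bp)
        bp, cm = bp[order], cm[order]
        if np.any(np.diff(cm) < 0):
            raise PanelFormatError(f"cM decreasing in map for {chrom}")
        self.anchors[str(chrom)] = (bp, cm)

    def interpolate(self, chrom: str, pos_bp):
        """Interpolate cM at pos_bp (scalar or array) on a chromosome."""
        key = str(chrom)
        if key not in self.anchors:
            raise KeyError(f"unknown chromosome {chrom!r} in genetic map")
        bp, cm = self.anchors[key]
        return np.interp(pos_bp, bp, cm)

    @classmethod
    def read_tsv(cls, path: str) -> "GeneticMap":
        """Read a TSV genetic map with columns chrom, pos_bp, cM."""
        chroms: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("chrom", "chr", "chromosome"):
                    continue
                c, bp, cm = parts[0], float(parts[1]), float(parts[2])
                chroms.setdefault(c, ([], []))
                chroms[c][0].append(bp)
                chroms[c][1].append(cm)
        out = cls()
        for c, (bp, cm) in chroms.items():
            out.add_chromosome(c, bp, cm)
        return out

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos_bp\tcM\n")
            for c, (bp, cm) in self.anchors.items():
                for b, m in zip(bp, cm):
                    fh.write(f"{c}\t{int(b)}\t{m:.8g}\n")


@dataclass
class FocalSnpList:
    """Focal (risk) SNPs a scan is centred on."""

    snp_ids: list
    chroms: list
    pos_bp: list
    allele_codes: list | None = None  # optional protective/susceptibility

    def validate_against(self, panel: HaplotypePanel) -> None:
        for sid in self.snp_ids:
            panel.snp_index(sid)  # raises KeyError if absent

    @classmethod
    def read_tsv(cls, path: str) -> "FocalSnpList":
        ids, chroms, pos = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("snp_id", "snp"):
                    continue
                ids.append(parts[0])
                chroms.append(parts[1])
                pos.append(int(parts[2]))
        return cls(ids, chroms, pos)


def interpolate_cM(genetic_map: GeneticMap, chrom: str, pos_bp):
    """Piecewise-linear genetic position at a physical position.

    Clamps beyond the terminal anchors; raises KeyError on an unknown
    chromosome.
    """
    return genetic_map.interpolate(chrom, pos_bp)


# ---------------------------------------------------------------------
# sample map I/O
# ---------------------------------------------------------------------

def read_sample_map(path: str) -> tuple[dict, dict]:
    """Read a TSV of (sample, population, group) rows.

    Returns (population_of_sample, group_of_population). A population
    listed under two different groups is an error.
    """
    pop_of: dict = {}
    grp_of: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() == "sample":
                continue
            if len(parts) < 3:
                raise PanelFormatError(f"sample map row too short: {line!r}")
            sample, pop, grp = parts[0], parts[1], parts[2]
            pop_of[sample] = pop
            if pop in grp_of and grp_of[pop] != grp:
                raise PanelFormatError(
                    f"population {pop!r} assigned to two groups")
            grp_of[pop] = grp
    return pop_of, grp_of


def write_sample_map(panel: HaplotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tgroup\n")
        for s in panel.samples:
            p = panel.population_of_sample[s]
            g = panel.group_of_population[p]
            fh.write(f"{s}\t{p}\t{g}\n")


# ---------------------------------------------------------------------
# tabular haplotype dialect
# ---------------------------------------------------------------------

_META_KEYS = ("#snp_id", "#chrom", "#pos_bp", "#pos_cM", "#genic")


def read_panel_table(haplotype_file: str, sample_map_file: str,
                     ) -> tuple[HaplotypePanel, GenicTrack]:
    """Read the tabular haplotype dialect.

    The file holds five tab-separated metadata rows (``#snp_id``,
    ``#chrom``, ``#pos_bp``, ``#pos_cM``, ``#genic``) followed by one row
    per chromosome copy: a sample id and one 0/1 call per SNP.
    """
    meta: dict = {}
    rows = []
    row_samples = []
    with open(haplotype_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if parts[0] in _META_KEYS:
                meta[parts[0]] = parts[1:]
                continue
            row_samples.append(parts[0])
            calls = parts[1:]
            for c in calls:
                if c not in ("0", "1"):
                    raise PanelFormatError(
                        f"non-binary allele code {c!r} in row for "
                        f"{parts[0]!r}")
            rows.append(np.array(calls, dtype=np.uint8))
    for key in _META_KEYS:
        if key not in meta:
            raise PanelFormatError(f"missing metadata row {key}")
    if not rows:
        raise PanelFormatError("no haplotype rows")
    pop_of, grp_of = read_sample_map(sample_map_file)
    panel = HaplotypePanel(
        alleles=np.vstack(rows),
        snp_ids=np.array(meta["#snp_id"]),
        chrom=np.array(meta["#chrom"]),
        pos_bp=np.array(meta["#pos_bp"], dtype=np.int64),
        pos_cM=np.array(meta["#pos_cM"], dtype=np.float64),
        sample_of_row=np.array(row_samples),
        population_of_sample=pop_of,
        group_of_population=grp_of,
    )
    genic = GenicTrack(np.array(meta["#genic"], dtype=np.int8).astype(bool))
    return panel, genic


def write_panel_table(panel: HaplotypePanel, genic: GenicTrack,
                      path: str) -> None:
    """Write the tabular haplotype dialect (inverse of read_panel_table)."""
    with open(path, "w") as fh:
        fh.write("#snp_id\t" + "\t".join(map(str, panel.snp_ids)) + "\n")
        fh.write("#chrom\t" + "\t".join(map(str, panel.chrom)) + "\n")
        fh.write("#pos_bp\t" + "\t".join(map(str, panel.pos_bp)) + "\n")
        fh.write("#pos_cM\t"
                 + "\t".join(f"{x:.10g}" for x in panel.pos_cM) + "\n")
        fh.write("#genic\t"
                 + "\t".join(str(int(x)) for x in genic.genic_flag) + "\n")
        for k in range(panel.n_haplotypes):
            fh.write(str(panel.sample_of_row[k]) + "\t"
                     + "\t".join(map(str, panel.alleles[k])) + "\n")


# ---------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------

def read_panel_vcf(vcf_file: str, sample_map_file: str,
                   genetic_map: GeneticMap | None = None,
                   default_cM_per_Mb: float = 1.0) -> HaplotypePanel:
    """Read a phased VCF (``|``-separated GT) into a panel.

    Genetic positions come from *genetic_map* when given; otherwise a
    constant rate of *default_cM_per_Mb* is assumed. Unphased or missing
    genotypes and multi-allelic sites are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_file)
    samples = list(vcf.samples)
    pop_of, grp_of = read_sample_map(sample_map_file)

    snp_ids, chroms, pos_bp = [], [], []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise PanelFormatError(
                f"multi-allelic site {var.ID or var.POS}")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                raise PanelFormatError(
                    f"missing genotype at {var.ID or var.POS}")
            if not phased:
                raise PanelFormatError(
                    f"unphased genotype at {var.ID or var.POS} "
                    f"(sample {samples[i]})")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        pos_bp.append(var.POS)
        columns.append(col)
    if not columns:
        raise PanelFormatError("no variants in VCF")
    chroms = np.array(chroms)
    pos_bp = np.array(pos_bp, dtype=np.int64)
    if genetic_map is not None:
        pos_cM = np.array([genetic_map.interpolate(c, p)
                           for c, p in zip(chroms, pos_bp)])
    else:
        pos_cM = pos_bp * default_cM_per_Mb * 1e-6
    sample_of_row = np.repeat(np.array(samples), 2)
    return HaplotypePanel(
        alleles=np.column_stack(columns),
        snp_ids=np.array(snp_ids),
        chrom=chroms,
        pos_bp=pos_bp,
        pos_cM=pos_cM,
        sample_of_row=sample_of_row,
        population_of_sample=pop_of,
        group_of_population=grp_of,
    )


def read_panel(haplotype_file: str, sample_map_file: str, **kwargs):
    """Dispatch on file extension: ``.vcf`` -> VCF reader, else tabular.

    Returns a :class:`HaplotypePanel` for VCF input, or a
    (panel, :class:`GenicTrack`) pair for the tabular dialect (which
    carries the genic flags inline).
    """
    if os.path.basename(haplotype_file).endswith(".vcf"):
        return read_panel_vcf(haplotype_file, sample_map_file, **kwargs)
    return read_panel_table(haplotype_file, sample_map_file)
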