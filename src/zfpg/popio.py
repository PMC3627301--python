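"""Genotype and alignment I/O, the central data model, and locus filters.

The package works on three kinds of input: biallelic SNP genotypes (VCF with
a chromosome/position map), a sample-to-population (and optionally
population-to-group) map, and a pre-aligned mtDNA FASTA.  Genotypes are held
as alt-allele counts (0/1/2, -1 for missing) in a samples x loci int8 matrix.

Coordinates are VCF-style 1-based; every window or bin downstream is a
half-open interval [start, end) in basepairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1  # internal code for a missing genotype


@dataclass(frozen=True)
class LocusRecord:
    """A single biallelic SNP with its genomic coordinate."""

    locus_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"locus {self.locus_id}: pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.locus_id}: ref and alt alleles identical")


@dataclass
class GenotypeDataset:
    """Samples x biallelic loci with population (and optional group) labels.

    genotypes[i, j] is the alt-allele count of sample i at locus j
    (0, 1, 2, or -1 for missing).
    """

    samples: list[str]
    loci: list[LocusRecord]
    genotypes: np.ndarray  # int8, shape (n_samples, n_loci)
    popmap: dict[str, str]
    groupmap: dict[str, str] | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        for s in self.samples:
            if s not in self.popmap:
                raise ValueError(f"sample {s} not in popmap")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids are not unique")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.popmap[s] == population]
        if not idx:
            raise KeyError(f"population {population} has no samples")
        return np.array(idx, dtype=int)

    def pop_labels(self) -> np.ndarray:
        return np.array([self.popmap[s] for s in self.samples])

    def locus_index(self, locus_id: str) -> int:
        for j, l in enumerate(self.loci):
            if l.locus_id == locus_id:
                return j
        raise KeyError(f"locus {locus_id} not in dataset")

    def subset_loci(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            samples=list(self.samples),
            loci=[self.loci[j] for j in keep],
            genotypes=self.genotypes[:, keep].copy(),
            popmap=dict(self.popmap),
            groupmap=dict(self.groupmap) if self.groupmap else None,
        )

    def subset_samples(self, keep_samples: list[str]) -> "GenotypeDataset":
        idx = [self.samples.index(s) for s in keep_samples]
        return GenotypeDataset(
            samples=list(keep_samples),
            loci=list(self.loci),
            genotypes=self.genotypes[idx, :].copy(),
            popmap=dict(self.popmap),
            groupmap=dict(self.groupmap) if self.groupmap else None,
        )

    def merge_populations(self, pops: list[str], merged_name: str) -> "GenotypeDataset":
        """Relabel several populations as one (e.g. pooling a representative
        wild sample from several weakly differentiated sites)."""
        popmap = {
            s: (merged_name if p in pops else p) for s, p in self.popmap.items()
        }
        groupmap = dict(self.groupmap) if self.groupmap else None
        if groupmap is not None:
            grp = {groupmap.get(p) for p in pops if p in groupmap}
            groupmap = {p: g for p, g in groupmap.items() if p not in pops}
            if len(grp) == 1:
                groupmap[merged_name] = grp.pop()
        return GenotypeDataset(
            samples=list(self.samples),
            loci=list(self.loci),
            genotypes=self.genotypes.copy(),
            popmap=popmap,
            groupmap=groupmap,
        )


@dataclass
class HaplotypeAlignment:
    """Aligned mtDNA sequences with population labels."""

    names: list[str]
    sequences: list[str]
    popmap: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("alignment is empty")
        L = len(self.sequences[0])
        if L < 1:
            raise ValueError("alignment length must be >= 1")
        for name, seq in zip(self.names, self.sequences):
            if len(seq) != L:
                raise ValueError(
                    f"record {name} has length {len(seq)}, expected {L}"
                )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.names:
            seen.setdefault(self.popmap[n], None)
        return list(seen)

    def pop_sequences(self, population: str) -> list[str]:
        return [
            s for n, s in zip(self.names, self.sequences)
            if self.popmap.get(n) == population
        ]

    def matrix(self) -> np.ndarray:
        """Alignment as a (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences])


# ---------------------------------------------------------------------------
# popmap / groupmap TSV
# ---------------------------------------------------------------------------

def read_popmap(path) -> tuple[dict[str, str], dict[str, str] | None]:
    """Read a 2- or 3-column TSV: sample, population[, group]."""
    popmap: dict[str, str] = {}
    groupmap: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            popmap[parts[0]] = parts[1]
            if len(parts) >= 3 and parts[2]:
                groupmap[parts[1]] = parts[2]
    return popmap, (groupmap or None)


def write_popmap(path, popmap: dict[str, str], groupmap: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            if groupmap and pop in groupmap:
                fh.write(f"{sample}\t{pop}\t{groupmap[pop]}\n")
            else:
                fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_genotypes(vcf_path, popmap_path, groupmap_path=None) -> GenotypeDataset:
    """Read biallelic SNP genotypes from a VCF plus a popmap TSV.

    Loci are ordered by (chrom, pos); sample order follows the VCF header.
    Raises on multiallelic records and on samples missing from the popmap.
    """
    popmap, groupmap_inline = read_popmap(popmap_path)
    groupmap = groupmap_inline
    if groupmap_path is not None:
        gm, _ = read_popmap(groupmap_path)
        groupmap = gm

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in popmap:
            raise ValueError(f"sample {s} not in popmap")

    loci: list[LocusRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1 or var.REF is None or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            vid = var.ID or f"{var.CHROM}:{var.POS}"
            raise ValueError(f"locus {vid} is not a biallelic SNP")
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(
            LocusRecord(vid, var.CHROM, var.POS, var.REF, var.ALT[0])
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.empty(len(samples), dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        col[gt == 2] = MISSING
        columns.append(col)
    vcf.close()

    if columns:
        order = sorted(range(len(loci)), key=lambda j: (loci[j].chrom, loci[j].pos))
        loci = [loci[j] for j in order]
        matrix = np.column_stack([columns[j] for j in order])
    else:
        matrix = np.zeros((len(samples), 0), dtype=np.int8)

    popmap = {s: popmap[s] for s in samples}
    return GenotypeDataset(samples, loci, matrix, popmap, groupmap)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(ds: GenotypeDataset, vcf_path, popmap_path) -> None:
    """Write a minimal VCF 4.2 (GT only) and a popmap TSV; round-trips with
    :func:`read_genotypes`."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(l.chrom for l in ds.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples)
            + "\n"
        )
        for j, loc in enumerate(ds.loci):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in ds.genotypes[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.locus_id}\t{loc.ref_allele}\t"
                f"{loc.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    write_popmap(popmap_path, ds.popmap, ds.groupmap)


# ---------------------------------------------------------------------------
# FASTA alignment
# ---------------------------------------------------------------------------

def read_alignment(fasta_path, popmap_path) -> HaplotypeAlignment:
    """Read a pre-aligned FASTA; sequences are uppercased on load."""
    popmap, _ = read_popmap(popmap_path)
    names, seqs = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not names:
        raise ValueError(f"no FASTA records in {fasta_path}")
    L = len(seqs[0])
    for n, s in zip(names, seqs):
        if len(s) != L:
            raise ValueError(f"record {n} has length {len(s)}, expected {L}")
    return HaplotypeAlignment(names, seqs, popmap)


def write_alignment(aln: HaplotypeAlignment, fasta_path, popmap_path) -> None:
    with open(fasta_path, "w") as fh:
        for n, s in zip(aln.names, aln.sequences):
            fh.write(f">{n}\n{s}\n")
    write_popmap(popmap_path, aln.popmap)


# ---------------------------------------------------------------------------
# Locus filters
# ---------------------------------------------------------------------------

def pooled_maf(ds: GenotypeDataset) -> np.ndarray:
    """Minor-allele frequency per locus over all non-missing genotypes pooled
    across every sample (populations and lab strains together)."""
    g = ds.genotypes
    usable = g != MISSING
    alt = np.where(usable, g, 0).sum(axis=0)
    n_alleles = 2 * usable.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_loci(
    ds: GenotypeDataset, maf_min: float = 0.01, remove_fixed: bool = True
) -> GenotypeDataset:
    """Drop fixed loci and loci with pooled MAF below ``maf_min``.

    Missing genotypes are excluded locus-wise from the frequency; locus
    order is preserved.  Idempotent.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    maf = pooled_maf(ds)
    with np.errstate(invalid="ignore"):
        below = np.nan_to_num(maf, nan=0.0) < maf_min
        fixed = np.nan_to_num(maf, nan=0.0) <= 0.0
    keep = ~below
    if remove_fixed:
        keep &= ~fixed
    log.info(
        "filter_loci: %d fixed, %d below MAF %.3g removed; %d of %d retained",
        int(fixed.sum()),
        int((below & ~fixed).sum()),
        int(keep.sum()),
        ds.n_loci,
    )
    return ds.subset_loci(keep)


def ld_prune(ds: GenotypeDataset, r2_max: float = 0.5, seed: int = 0) -> GenotypeDataset:
    """Remove one member of every syntenic pair with r^2 above ``r2_max``.

    Pairs are scanned in (chrom, pos_i, pos_j) order; for each violating
    pair the removed member is a fair coin flip from the seeded stream, so
    the surviving set is deterministic for a fixed seed.  r^2 is the
    EM-based estimate over pooled samples (see :mod:`zfpg.ld`).
    """
    from . import ld as _ld  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    removed = np.zeros(ds.n_loci, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for j, loc in enumerate(ds.loci):
        by_chrom.setdefault(loc.chrom, []).append(j)
    n_pruned = 0
    for chrom in sorted(by_chrom):
        idx = sorted(by_chrom[chrom], key=lambda j: ds.loci[j].pos)
        for a_i, j1 in enumerate(idx):
            if removed[j1]:
                continue
            for j2 in idx[a_i + 1 :]:
                if removed[j1]:
                    break
                if removed[j2]:
                    continue
                r2, _ = _ld.r2_pair(ds.genotypes[:, j1], ds.genotypes[:, j2])
                if r2 is not None and r2 > r2_max:
                    victim = j1 if rng.random() < 0.5 else j2
                    removed[victim] = True
                    n_pruned += 1
    log.info("ld_prune: removed %d loci at r2 > %.3g", n_pruned, r2_max)
    return ds.subset_loci(~removed)
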