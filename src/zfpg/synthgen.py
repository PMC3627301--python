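"""Synthetic SNP datasets and mtDNA alignments with known ground truth.

The SNP generator shares the structured-coalescent engine of
:mod:`zfpg.fdist`: each locus is an independent genealogy under the
two-level island model, carrying a single mutation, so every simulated
locus is a polymorphic SNP.  Diploid genotypes are formed by pairing
sampled gene copies within demes.  The generator therefore produces data
whose neutral loci follow exactly the null model the outlier test assumes;
selection signals are planted afterwards by :func:`plant_sweeps`.

The mtDNA simulator emulates a deeply structured cytochrome-b alignment:
a small number of clades separated by ~5-6% net divergence, strong
transition bias (about 22:1) and AT-rich base composition (about 61%),
with shallow within-clade variation.

Loci are simulated without intra-chromosome linkage; controllable LD for
testing the LD scans is created either by sweep planting or by
:func:`plant_ld_block`, which copies a genotype column with flip noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import fdist
from .popio import MISSING, GenotypeDataset, LocusRecord, HaplotypeAlignment

log = logging.getLogger(__name__)

DEFAULT_CHROM_LENGTHS = [40_000_000] * 25  # 25 chromosomes of 40 Mb


@dataclass
class SimConfig:
    """Conditions for one synthetic SNP dataset.

    sampled_pops: (population name, group index, deme index, diploid
    individuals) per sampled population.  M1/M2 are scaled migration
    rates; setting target_fst calibrates them (holding M1/M2 = 10) so the
    realized multilocus theta matches.
    """

    sampled_pops: list[tuple[str, int, int, int]]
    n_loci: int = 1832
    n_groups: int = 5
    demes_per_group: int = 20
    chrom_lengths: list[int] = field(default_factory=lambda: list(DEFAULT_CHROM_LENGTHS))
    M1: float = 10.0
    M2: float = 1.0
    target_fst: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1 or self.n_groups < 1 or self.demes_per_group < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if sum(n for *_, n in self.sampled_pops) < 1:
            raise ValueError("need at least one sampled individual")


@dataclass
class SweepSpec:
    """A planted selective sweep.

    Within ``radius`` of ``pos`` on ``chrom``, heterozygosity in the
    populations of ``favored_group`` is reduced by a factor that is
    ``intensity`` at distance 0 and decays linearly to 0 at the radius.
    ``differentiation_boost`` additionally drives the SNP nearest the
    sweep position to near-fixation of opposite alleles between the
    favored group and the rest.
    """

    chrom: str
    pos: int
    favored_group: int
    radius: int = 3_000_000
    intensity: float = 1.0
    differentiation_boost: bool = False

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError("intensity must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    M1: float
    M2: float
    locus_labels: dict[str, str]  # locus id -> "neutral" | "sweep"
    sweeps: list[SweepSpec]
    realized_fst: float


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def _fdist_config(cfg: SimConfig) -> fdist.FdistConfig:
    layout = [(g, d, 2 * n) for _, g, d, n in cfg.sampled_pops]
    return fdist.FdistConfig(
        sample_layout=layout,
        n_groups=cfg.n_groups,
        demes_per_group=cfg.demes_per_group,
        M1=cfg.M1,
        M2=cfg.M2,
        seed=cfg.seed,
    )


def simulate_snp_dataset(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a biallelic SNP dataset under the hierarchical island model.

    Each locus is one independent structured-coalescent genealogy carrying
    a single mutation; positions are uniform over the chromosome lengths;
    genotypes are diploid pairings of sampled gene copies within demes.
    Missing entries are dropped in independently at ``missing_rate``.
    Deterministic for a fixed seed.
    """
    if cfg.target_fst is not None:
        probe_cfg = replace(cfg, target_fst=None)
        M1, M2 = fdist.calibrate(_fdist_config(probe_cfg), cfg.target_fst)
        cfg = replace(cfg, M1=M1, M2=M2, target_fst=None)
    fcfg = _fdist_config(cfg)
    rng = np.random.default_rng(cfg.seed)

    # sample names and popmap
    samples: list[str] = []
    popmap: dict[str, str] = {}
    groupmap: dict[str, str] = {}
    pop_slices: list[tuple[int, int]] = []
    row = 0
    for name, g, _, n in cfg.sampled_pops:
        for i in range(n):
            sid = f"{name}_{i + 1:03d}"
            samples.append(sid)
            popmap[sid] = name
        groupmap[name] = f"G{g + 1}"
        pop_slices.append((row, row + n))
        row += n

    # locus coordinates: uniform over the genome, unique, sorted
    lengths = np.asarray(cfg.chrom_lengths, dtype=np.int64)
    total = lengths.sum()
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    coords: set[tuple[int, int]] = set()
    while len(coords) < cfg.n_loci:
        flat = rng.integers(0, total, size=cfg.n_loci - len(coords))
        for f in flat:
            c = int(np.searchsorted(offsets, f, side="right") - 1)
            coords.add((c, int(f - offsets[c]) + 1))
    coord_list = sorted(coords)

    ref_alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    loci = []
    columns = np.empty((row, cfg.n_loci), dtype=np.int8)
    num = den = 0.0
    for j, (c, pos) in enumerate(coord_list):
        counts = fdist.coalesce_locus(fcfg, rng)
        col = np.empty(row, dtype=np.int8)
        n_ind = np.empty(len(counts), dtype=int)
        n_het = np.empty(len(counts), dtype=int)
        for i, ((lo, hi), (_, _, _, n)) in enumerate(zip(pop_slices, cfg.sampled_pops)):
            copies = np.zeros(2 * n, dtype=np.int8)
            copies[: counts[i]] = 1
            rng.shuffle(copies)
            geno = copies.reshape(n, 2).sum(axis=1)
            col[lo:hi] = geno
            n_ind[i] = n
            n_het[i] = int(np.sum(geno == 1))
        comp = fdist.wc_theta_locus(n_ind, counts, n_het)
        num += comp.a
        den += comp.a + comp.b + comp.c
        columns[:, j] = col
        ra = ref_alt[j % len(ref_alt)]
        loci.append(
            LocusRecord(f"snp{j + 1:05d}", _chrom_name(c), pos, ra[0], ra[1])
        )

    if cfg.missing_rate > 0:
        miss = rng.random(columns.shape) < cfg.missing_rate
        columns[miss] = MISSING

    ds = GenotypeDataset(samples, loci, columns, popmap, groupmap)
    truth = SimTruth(
        M1=cfg.M1,
        M2=cfg.M2,
        locus_labels={l.locus_id: "neutral" for l in loci},
        sweeps=[],
        realized_fst=float(num / den) if den != 0 else float("nan"),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Sweep planting
# ---------------------------------------------------------------------------

def plant_sweeps(
    ds: GenotypeDataset,
    truth: SimTruth,
    sweeps: list[SweepSpec],
    seed: int = 0,
) -> tuple[GenotypeDataset, SimTruth]:
    """Plant local heterozygosity valleys (and optional focal-locus
    differentiation) into a simulated dataset.

    For each locus within a sweep's radius, every population of the
    favored group has each of its locally-minor allele copies replaced by
    the locally-major allele with probability
    phi = intensity * (1 - distance/radius): heterozygotes become the
    major homozygote with probability phi, and minor homozygotes lose
    copies likewise.  This per-copy thinning emulates hitchhiking (linked
    haplotypes dragged toward fixation), reduces within-population
    heterozygosity by approximately phi at the sweep centre, and acts on
    genotypes individual by individual so Hardy-Weinberg structure stays
    testable.  With ``differentiation_boost``, the SNP nearest the sweep
    position is recoded so favored-group populations carry the alt allele
    at frequency >= 0.95 and the others the ref allele.
    """
    rng = np.random.default_rng(seed)
    g = ds.genotypes.copy()
    labels = dict(truth.locus_labels)
    group_of_pop = ds.groupmap or {}
    chroms = {l.chrom for l in ds.loci}

    kept_sweeps: list[SweepSpec] = []
    for sw in sweeps:
        if sw.chrom not in chroms:
            raise ValueError(f"sweep chromosome {sw.chrom} not in dataset")
        favored = f"G{sw.favored_group + 1}"
        fav_pops = [p for p, grp in group_of_pop.items() if grp == favored]
        if not fav_pops:
            raise ValueError(f"no populations in favored group {favored}")
        in_radius = [
            j for j, l in enumerate(ds.loci)
            if l.chrom == sw.chrom and abs(l.pos - sw.pos) < sw.radius
        ]
        if not in_radius:
            warnings.warn(
                f"no SNP within {sw.radius} bp of {sw.chrom}:{sw.pos}; sweep skipped",
                stacklevel=2,
            )
            continue
        kept_sweeps.append(sw)
        for j in in_radius:
            dist = abs(ds.loci[j].pos - sw.pos)
            frac = sw.intensity * (1.0 - dist / sw.radius)
            labels[ds.loci[j].locus_id] = "sweep"
            # the swept (major) allele is shared across the favored group
            fav_idx = np.concatenate([ds.pop_indices(p) for p in fav_pops])
            fav_col = g[fav_idx, j]
            fav_usable = fav_col != MISSING
            major_is_alt = (
                fav_usable.any()
                and int(fav_col[fav_usable].sum()) > fav_usable.sum()
            )
            for p in fav_pops:
                idx = ds.pop_indices(p)
                col = g[idx, j]
                usable = col != MISSING
                if not usable.any():
                    continue
                minor = (2 - col) if major_is_alt else col
                # thin each minor allele copy with probability frac
                lost = rng.binomial(np.where(usable, minor, 0), frac)
                new_minor = np.where(usable, minor - lost, minor)
                col = (2 - new_minor) if major_is_alt else new_minor
                col[~usable] = MISSING
                g[idx, j] = col.astype(np.int8)
        if sw.differentiation_boost:
            j_focal = min(
                (j for j, l in enumerate(ds.loci) if l.chrom == sw.chrom),
                key=lambda j: abs(ds.loci[j].pos - sw.pos),
            )
            labels[ds.loci[j_focal].locus_id] = "sweep"
            for p in ds.populations:
                idx = ds.pop_indices(p)
                col = g[idx, j_focal]
                fixed_code = 2 if group_of_pop.get(p) == favored else 0
                miss = col == MISSING
                newcol = np.full(col.shape, fixed_code, dtype=np.int8)
                # leave ~5% residual polymorphism so the locus stays variable
                flip = rng.random(col.size) < 0.025
                newcol[flip] = 1
                newcol[miss] = MISSING
                g[idx, j_focal] = newcol

    out = GenotypeDataset(
        samples=list(ds.samples),
        loci=list(ds.loci),
        genotypes=g,
        popmap=dict(ds.popmap),
        groupmap=dict(ds.groupmap) if ds.groupmap else None,
    )
    new_truth = SimTruth(
        M1=truth.M1,
        M2=truth.M2,
        locus_labels=labels,
        sweeps=list(truth.sweeps) + kept_sweeps,
        realized_fst=truth.realized_fst,
    )
    return out, new_truth


def plant_ld_block(
    ds: GenotypeDataset,
    locus_id: str,
    n_copies: int,
    spacing: int,
    flip_prob: float = 0.05,
    seed: int = 0,
) -> GenotypeDataset:
    """Duplicate a genotype column at regular spacing with flip noise.

    Creates controllable r^2 around a focal locus (a block-copy stand-in
    for linkage, since the neutral engine simulates loci independently).
    Each copied genotype entry is resampled to a random genotype with
    probability ``flip_prob``; smaller values give higher r^2.
    """
    rng = np.random.default_rng(seed)
    j = ds.locus_index(locus_id)
    src = ds.loci[j]
    col = ds.genotypes[:, j]
    loci = list(ds.loci)
    cols = [ds.genotypes[:, k] for k in range(ds.n_loci)]
    for i in range(1, n_copies + 1):
        pos = src.pos + i * spacing
        new = col.copy()
        flip = (new != MISSING) & (rng.random(new.size) < flip_prob)
        new[flip] = rng.integers(0, 3, size=int(flip.sum()), dtype=np.int8)
        loci.append(
            LocusRecord(f"{locus_id}_cp{i}", src.chrom, pos, src.ref_allele, src.alt_allele)
        )
        cols.append(new)
    order = sorted(range(len(loci)), key=lambda k: (loci[k].chrom, loci[k].pos))
    return GenotypeDataset(
        samples=list(ds.samples),
        loci=[loci[k] for k in order],
        genotypes=np.column_stack([cols[k] for k in order]),
        popmap=dict(ds.popmap),
        groupmap=dict(ds.groupmap) if ds.groupmap else None,
    )


# ---------------------------------------------------------------------------
# mtDNA simulator
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _mutate(
    seq: np.ndarray, n_subs: int, ts_odds: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply n_subs substitutions at distinct sites; transition with odds
    ts_odds : 1 against transversion."""
    out = seq.copy()
    if n_subs == 0:
        return out
    sites = rng.choice(seq.size, size=min(n_subs, seq.size), replace=False)
    for s in sites:
        base = out[s]
        if np.isinf(ts_odds) or rng.random() < ts_odds / (ts_odds + 1.0):
            out[s] = _TRANSITION[base]
        else:
            out[s] = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
    return out


def simulate_mtdna(
    n_clades: int,
    seqs_per_clade,
    seq_length: int = 1122,
    clade_net_divergence: float = 0.055,
    within_clade_theta: float = 0.004,
    ts_tv_ratio: float = 22.0,
    at_content: float = 0.61,
    seed: int = 0,
) -> HaplotypeAlignment:
    """Simulate a clade-structured mtDNA alignment.

    A root sequence is drawn at the given base composition; each clade
    stem receives Poisson(clade_net_divergence * length / 2) substitutions
    (so between-clade p-distance is centred on the net divergence); each
    sequence then receives Poisson(within_clade_theta * length / 2)
    private substitutions (so within-clade pi is centred on
    within_clade_theta).  Substitution types follow ts_tv_ratio : 1
    transition:transversion odds.  Population labels are ``cladeN``.
    """
    if clade_net_divergence >= 0.75:
        raise ValueError("clade_net_divergence >= 0.75 saturates the alignment")
    if isinstance(seqs_per_clade, int):
        seqs_per_clade = [seqs_per_clade] * n_clades
    if len(seqs_per_clade) != n_clades:
        raise ValueError("seqs_per_clade length must equal n_clades")
    rng = np.random.default_rng(seed)
    p_at = at_content / 2.0
    p_cg = (1.0 - at_content) / 2.0
    root = rng.choice(
        np.array(["A", "T", "C", "G"]),
        size=seq_length,
        p=[p_at, p_at, p_cg, p_cg],
    )
    names, seqs = [], []
    popmap = {}
    stem_lambda = clade_net_divergence * seq_length / 2.0
    tip_lambda = within_clade_theta * seq_length / 2.0
    for c in range(n_clades):
        ancestor = _mutate(root, int(rng.poisson(stem_lambda)), ts_tv_ratio, rng)
        for i in range(seqs_per_clade[c]):
            tip = _mutate(ancestor, int(rng.poisson(tip_lambda)), ts_tv_ratio, rng)
            name = f"clade{c + 1}_seq{i + 1:02d}"
            names.append(name)
            seqs.append("".join(tip))
            popmap[name] = f"clade{c + 1}"
    return HaplotypeAlignment(names, seqs, popmap)


def count_ts_tv(aln: HaplotypeAlignment) -> tuple[int, int]:
    """Observed transition and transversion counts over all sequence pairs
    (site-wise, relative to the alignment's majority state)."""
    m = aln.matrix()
    n, L = m.shape
    ts = tv = 0
    for c in range(L):
        col = m[:, c]
        states = sorted(set(col) & {"A", "C", "G", "T"})
        if len(states) < 2:
            continue
        for i in range(len(states)):
            for j in range(i + 1, len(states)):
                a, b = states[i], states[j]
                npairs = int(np.sum(col == a)) * int(np.sum(col == b))
                if _TRANSITION[a] == b:
                    ts += npairs
                else:
                    tv += npairs
    return ts, tv
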