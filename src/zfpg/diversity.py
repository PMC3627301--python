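"""Within-population diversity statistics for SNPs and mtDNA.

SNP side: unbiased expected heterozygosity, Levene-style exact tests for
Hardy-Weinberg proportions, and the pooled two-sample t comparison of mean
heterozygosity between groups of populations (e.g. laboratory strains
versus wild sites).

mtDNA side: segregating sites, haplotype diversity h, nucleotide diversity
pi, net divergence Da, Tamura-Nei (TN93) distances, and a fixed-group
AMOVA yielding Phi_CT / Phi_SC / Phi_ST with permutation P-values.

All mtDNA statistics use complete deletion: any column containing a gap or
N in an included sequence is excluded.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .popio import MISSING, GenotypeDataset, HaplotypeAlignment

log = logging.getLogger(__name__)

_NUCS = ("A", "C", "G", "T")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class HapStats:
    """Summary of one population's haplotypes: S, h, pi (per-site), n."""

    S: int
    h: float
    pi: float
    n: int


@dataclass
class AmovaResult:
    """Hierarchical variance components and Phi-statistics.

    sigma_a: among groups; sigma_b: among populations within groups;
    sigma_c: within populations.  Phi_ST = (sigma_a+sigma_b)/total,
    Phi_CT = sigma_a/total, Phi_SC = sigma_b/(sigma_b+sigma_c).
    """

    sigma_a: float
    sigma_b: float
    sigma_c: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None
    degenerate: bool = False


@dataclass
class DistanceModel:
    """Pairwise-distance model: uncorrected p-distance or TN93.

    For TN93 the base frequencies are estimated from the alignment unless
    supplied explicitly.
    """

    kind: str = "p"  # "p" or "tn93"
    freqs: dict[str, float] | None = None

    def __post_init__(self):
        if self.kind not in ("p", "tn93"):
            raise ValueError(f"unknown distance model {self.kind!r}")
        if self.freqs is not None:
            tot = sum(self.freqs.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-6):
                raise ValueError("base frequencies must sum to 1")


# ---------------------------------------------------------------------------
# SNP heterozygosity and Hardy-Weinberg
# ---------------------------------------------------------------------------

def expected_het(ds: GenotypeDataset, population: str, locus: str) -> float | None:
    """Unbiased expected heterozygosity He = (2n/(2n-1)) * (1 - p^2 - q^2).

    n is the number of non-missing diploid individuals in the population at
    the locus; returns None (logged) when fewer than 2 are usable.
    """
    j = ds.locus_index(locus)
    g = ds.genotypes[ds.pop_indices(population), j]
    g = g[g != MISSING]
    n = g.size
    if n < 2:
        log.warning("expected_het: <2 usable genotypes for %s at %s", population, locus)
        return None
    p = g.sum() / (2 * n)
    return float((2 * n / (2 * n - 1)) * (1 - p * p - (1 - p) * (1 - p)))


def mean_expected_het(ds: GenotypeDataset, population: str) -> float:
    """Population mean H_S: average He over all retained loci (zeros for
    monomorphic loci included); loci with <2 usable genotypes are skipped."""
    idx = ds.pop_indices(population)
    g = ds.genotypes[idx, :]
    usable = g != MISSING
    n = usable.sum(axis=0)
    alt = np.where(usable, g, 0).sum(axis=0)
    ok = n >= 2
    p = alt[ok] / (2 * n[ok])
    he = (2 * n[ok] / (2 * n[ok] - 1)) * (1 - p**2 - (1 - p) ** 2)
    return float(he.mean()) if he.size else float("nan")


def _levene_log_prob(n_het: int, n: int, n_a: int) -> float:
    """log P(heterozygote count = n_het | n diploids, n_a copies of allele A)
    under the exact conditional (Levene) distribution."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_het) // 2
    n_bb = (n_b - n_het) // 2
    return (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(n_het + 1)
        - gammaln(n_bb + 1)
        + n_het * math.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_test(ds: GenotypeDataset, population: str, locus: str) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Two-sided P-value: sum of Levene probabilities of every heterozygote
    count (with the observed allele counts) whose probability does not
    exceed that of the observed count.  Monomorphic loci give P = 1.
    """
    j = ds.locus_index(locus)
    g = ds.genotypes[ds.pop_indices(population), j]
    g = g[g != MISSING]
    n = int(g.size)
    if n < 2:
        raise ValueError(f"<2 usable genotypes for {population} at {locus}")
    n_het = int(np.sum(g == 1))
    n_alt = int(g.sum())
    return hwe_exact_p(n_het, n, n_alt)


def hwe_exact_p(n_het: int, n: int, n_alt: int) -> float:
    """Exact HWE P-value from counts (n diploids, n_alt alt copies)."""
    n_a = min(n_alt, 2 * n - n_alt)  # rarer allele count
    if n_a == 0:
        return 1.0
    hets = range(n_a % 2, n_a + 1, 2)  # feasible heterozygote counts
    logp = {k: _levene_log_prob(k, n, n_a) for k in hets}
    obs = logp[n_het]
    p = sum(math.exp(lp) for lp in logp.values() if lp <= obs + 1e-12)
    return min(p, 1.0)


def hwe_summary(
    ds: GenotypeDataset, alpha: float = 0.05
) -> tuple[int, int, int]:
    """(n_tests, n_significant, n_expected) over every (population,
    polymorphic locus) pair with >= 2 usable genotypes;
    n_expected = round(alpha * n_tests)."""
    n_tests = 0
    n_sig = 0
    for pop in ds.populations:
        idx = ds.pop_indices(pop)
        g = ds.genotypes[idx, :]
        for j in range(ds.n_loci):
            col = g[:, j]
            col = col[col != MISSING]
            n = col.size
            if n < 2:
                continue
            n_alt = int(col.sum())
            if n_alt == 0 or n_alt == 2 * n:
                continue  # monomorphic in this population
            n_tests += 1
            if hwe_exact_p(int(np.sum(col == 1)), n, n_alt) < alpha:
                n_sig += 1
    return n_tests, n_sig, round(alpha * n_tests)


def pooled_t(group_a, group_b) -> tuple[float, int, float]:
    """Equal-variance pooled two-sample t-test.

    Returns (t, df, one-sided upper-tail P for mean(A) > mean(B));
    df = nA + nB - 2.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / a.size + 1 / b.size))
    p = float(stats.t.sf(t, df))
    return float(t), int(df), p


# ---------------------------------------------------------------------------
# mtDNA alignment statistics
# ---------------------------------------------------------------------------

def _clean_columns(seqs: list[str]) -> np.ndarray:
    """Matrix of alignment columns after complete deletion of sites with
    gaps or ambiguity codes in any included sequence."""
    m = np.array([list(s) for s in seqs])
    ok = np.all(np.isin(m, _NUCS), axis=0)
    return m[:, ok]


def haplotype_stats(aln: HaplotypeAlignment, population: str) -> HapStats:
    """S, haplotype diversity h = (n/(n-1))(1 - sum f_i^2), and nucleotide
    diversity pi (mean pairwise p-distance) for one population."""
    seqs = aln.pop_sequences(population)
    n = len(seqs)
    if n < 2:
        raise ValueError(f"population {population} has {n} sequence(s); need >= 2")
    m = _clean_columns(seqs)
    L = m.shape[1]
    S = int(np.sum([len(set(m[:, c])) > 1 for c in range(L)]))
    # haplotype diversity over the cleaned sequences
    haps: dict[str, int] = {}
    for row in m:
        key = "".join(row)
        haps[key] = haps.get(key, 0) + 1
    f = np.array(list(haps.values())) / n
    h = (n / (n - 1)) * (1 - np.sum(f**2))
    # mean pairwise p-distance
    if L == 0:
        pi = 0.0
    else:
        total = 0.0
        for i, j in itertools.combinations(range(n), 2):
            total += np.sum(m[i] != m[j]) / L
        pi = total / (n * (n - 1) / 2)
    return HapStats(S=S, h=float(h), pi=float(pi), n=n)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing sites over unambiguous columns."""
    a = np.array(list(seq_a))
    b = np.array(list(seq_b))
    ok = np.isin(a, _NUCS) & np.isin(b, _NUCS)
    if not ok.any():
        raise ValueError("no overlapping unambiguous sites")
    return float(np.sum(a[ok] != b[ok]) / ok.sum())


def estimate_base_freqs(aln: HaplotypeAlignment) -> dict[str, float]:
    m = aln.matrix()
    counts = {nuc: float(np.sum(m == nuc)) for nuc in _NUCS}
    tot = sum(counts.values())
    if tot == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return {nuc: c / tot for nuc, c in counts.items()}


def tn93_distance(seq_a: str, seq_b: str, freqs: dict[str, float]) -> float:
    """Tamura-Nei (1993) distance with distinct purine and pyrimidine
    transition rates.

    Uses the observed proportions P1 (A<->G transitions), P2 (C<->T
    transitions) and Q (transversions) with the supplied base frequencies.
    Raises on saturation (any logarithm argument <= 0).
    """
    a = np.array(list(seq_a))
    b = np.array(list(seq_b))
    ok = np.isin(a, _NUCS) & np.isin(b, _NUCS)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no overlapping unambiguous sites")
    a, b = a[ok], b[ok]
    diff = a != b
    ag = np.sum(diff & np.isin(a, ["A", "G"]) & np.isin(b, ["A", "G"]))
    ct = np.sum(diff & np.isin(a, ["C", "T"]) & np.isin(b, ["C", "T"]))
    tv = int(diff.sum()) - int(ag) - int(ct)
    P1, P2, Q = ag / n, ct / n, tv / n

    gA, gC, gG, gT = (freqs[x] for x in _NUCS)
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        raise ValueError("TN93 requires strictly positive base frequencies")
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise ValueError("TN93 distance saturated (log argument <= 0)")
    return float(-k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3))


def pair_distance(seq_a: str, seq_b: str, model: DistanceModel) -> float:
    if model.kind == "p":
        return p_distance(seq_a, seq_b)
    if model.freqs is None:
        raise ValueError("TN93 model needs base frequencies")
    return tn93_distance(seq_a, seq_b, model.freqs)


def _mean_between(seqs_x: list[str], seqs_y: list[str], model: DistanceModel) -> float:
    total, cnt = 0.0, 0
    for sx in seqs_x:
        for sy in seqs_y:
            total += pair_distance(sx, sy, model)
            cnt += 1
    return total / cnt


def _mean_within(seqs: list[str], model: DistanceModel) -> float:
    """Plug-in within-population mean distance (over all n^2 ordered pairs
    including self-pairs), the frequency-weighted form that makes Da vanish
    exactly when two populations share the same composition."""
    n = len(seqs)
    if n < 2:
        return 0.0
    total = 0.0
    for sa, sb in itertools.combinations(seqs, 2):
        total += pair_distance(sa, sb, model)
    return 2.0 * total / (n * n)


def net_divergence(
    aln: HaplotypeAlignment, pop_x: str, pop_y: str, model: DistanceModel | None = None
) -> float:
    """Net nucleotide divergence Da = dXY - (dX + dY)/2.

    Distances follow ``model`` (p-distance by default); populations with a
    single sequence contribute zero within-population diversity.
    """
    if model is None:
        model = DistanceModel(kind="p")
    if model.kind == "tn93" and model.freqs is None:
        model = DistanceModel(kind="tn93", freqs=estimate_base_freqs(aln))
    sx = aln.pop_sequences(pop_x)
    sy = aln.pop_sequences(pop_y)
    if not sx or not sy:
        raise ValueError(f"population {pop_x if not sx else pop_y} has no sequences")
    try:
        dxy = _mean_between(sx, sy, model)
        dx = _mean_within(sx, model)
        dy = _mean_within(sy, model)
    except ValueError as err:
        raise ValueError(f"distance undefined for pair ({pop_x}, {pop_y}): {err}") from err
    return dxy - (dx + dy) / 2.0


# ---------------------------------------------------------------------------
# AMOVA (fixed groups, distance-matrix based)
# ---------------------------------------------------------------------------

def _amova_components(d2: np.ndarray, pop_of: np.ndarray, grp_of_pop: dict):
    """Excoffier-style variance components from a squared-distance matrix.

    pop_of: population index per sequence; grp_of_pop maps population index
    to group label.  Returns (sigma_a, sigma_b, sigma_c).
    """
    N = d2.shape[0]
    pops = np.unique(pop_of)
    groups: dict = {}
    for p in pops:
        groups.setdefault(grp_of_pop[p], []).append(p)
    G = len(groups)
    P = len(pops)

    def ssd(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 0.0
        sub = d2[np.ix_(idx, idx)]
        return float(sub.sum() / (2 * idx.size))  # full matrix double-counts pairs

    idx_all = np.arange(N)
    ssd_total = ssd(idx_all)
    ssd_wp = 0.0
    for p in pops:
        ssd_wp += ssd(idx_all[pop_of == p])
    ssd_wg = 0.0  # within groups (pops pooled)
    for g, gpops in groups.items():
        mask = np.isin(pop_of, gpops)
        ssd_wg += ssd(idx_all[mask])
    ssd_ap = ssd_wg - ssd_wp  # among populations within groups
    ssd_ag = ssd_total - ssd_wg  # among groups

    n_p = {p: int(np.sum(pop_of == p)) for p in pops}
    n_g = {g: int(np.sum(np.isin(pop_of, gp))) for g, gp in groups.items()}

    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1

    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp

    if df_ap > 0:
        n_prime = (N - sum(sum(n_p[p] ** 2 for p in gp) / n_g[g] for g, gp in groups.items())) / df_ap
        ms_ap = ssd_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0

    if df_ag > 0:
        n_dprime = (
            sum(sum(n_p[p] ** 2 for p in gp) / n_g[g] for g, gp in groups.items())
            - sum(n_p[p] ** 2 for p in pops) / N
        ) / df_ag
        n_tprime = (N - sum(n_g[g] ** 2 for g in groups) / N) / df_ag
        ms_ag = ssd_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime if n_tprime > 0 else 0.0
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


def amova(
    dist: np.ndarray,
    popmap: list[str] | np.ndarray,
    groups: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    squared: bool = True,
) -> AmovaResult:
    """Fixed-group AMOVA from a pairwise distance matrix over sequences.

    ``dist`` holds squared distances unless ``squared=False`` (then entries
    are squared internally).  ``popmap`` gives one population label per row;
    ``groups`` maps population label to group label (one group for all if
    omitted).  Permutation schemes: Phi_SC permutes sequences among
    populations within groups; Phi_CT permutes whole populations among
    groups; Phi_ST permutes sequences among populations across groups.
    Groups holding a single population are allowed and contribute no
    within-group component.
    """
    d2 = np.asarray(dist, dtype=float)
    if not squared:
        d2 = d2**2
    labels = np.asarray(popmap)
    pop_names = list(dict.fromkeys(labels))
    if len(pop_names) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    if groups is None:
        groups = {p: "all" for p in pop_names}
    pop_of = np.array([pop_names.index(p) for p in labels])
    grp_of_pop = {pop_names.index(p): groups[p] for p in pop_names}

    if np.allclose(d2, 0):
        return AmovaResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)

    sigma_a, sigma_b, sigma_c = _amova_components(d2, pop_of, grp_of_pop)
    total = sigma_a + sigma_b + sigma_c

    def phis(sa, sb, sc):
        tot = sa + sb + sc
        phi_st = (sa + sb) / tot if tot != 0 else 0.0
        phi_ct = sa / tot if tot != 0 else 0.0
        phi_sc = sb / (sb + sc) if (sb + sc) != 0 else 0.0
        return phi_ct, phi_sc, phi_st

    phi_ct, phi_sc, phi_st = phis(sigma_a, sigma_b, sigma_c)

    p_ct = p_sc = p_st = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        grp_labels = np.array([grp_of_pop[p] for p in pop_of])
        uniq_groups = list(dict.fromkeys(grp_of_pop.values()))
        multi_group = len(uniq_groups) > 1

        ge_st = ge_sc = ge_ct = 0
        for _ in range(n_perm):
            # Phi_ST: shuffle sequences among populations (across groups)
            perm = rng.permutation(len(pop_of))
            sa, sb, sc = _amova_components(d2, pop_of[perm], grp_of_pop)
            _, _, pst = phis(sa, sb, sc)
            if pst >= phi_st - 1e-12:
                ge_st += 1
            if multi_group:
                # Phi_SC: shuffle sequences among populations within groups
                pop_perm = pop_of.copy()
                for g in uniq_groups:
                    mask = grp_labels == g
                    pop_perm[mask] = rng.permutation(pop_perm[mask])
                sa, sb, sc = _amova_components(d2, pop_perm, grp_of_pop)
                _, psc, _ = phis(sa, sb, sc)
                if psc >= phi_sc - 1e-12:
                    ge_sc += 1
                # Phi_CT: shuffle whole populations among groups
                grp_vals = [grp_of_pop[p] for p in sorted(grp_of_pop)]
                shuffled = list(rng.permutation(grp_vals))
                g_perm = {p: shuffled[i] for i, p in enumerate(sorted(grp_of_pop))}
                sa, sb, sc = _amova_components(d2, pop_of, g_perm)
                pct, _, _ = phis(sa, sb, sc)
                if pct >= phi_ct - 1e-12:
                    ge_ct += 1
        p_st = (1 + ge_st) / (1 + n_perm)
        if multi_group:
            p_sc = (1 + ge_sc) / (1 + n_perm)
            p_ct = (1 + ge_ct) / (1 + n_perm)

    return AmovaResult(
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        sigma_c=sigma_c,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_ct=p_ct,
        p_sc=p_sc,
        p_st=p_st,
        degenerate=False,
    )


def alignment_distance_matrix(
    aln: HaplotypeAlignment, model: DistanceModel | None = None
) -> np.ndarray:
    """Pairwise distance matrix over all sequences in the alignment."""
    if model is None:
        model = DistanceModel(kind="p")
    if model.kind == "tn93" and model.freqs is None:
        model = DistanceModel(kind="tn93", freqs=estimate_base_freqs(aln))
    n = len(aln.sequences)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pair_distance(aln.sequences[i], aln.sequences[j], model)
    return d
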