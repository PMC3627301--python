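"""Hierarchical island-model coalescent null and F_ST outlier classification.

The null distribution of (heterozygosity, F_ST) under neutrality is built
by simulating independent loci under a structured coalescent on a
two-level island model: demes nested in groups, with distinct scaled
within-group (M1) and among-group (M2) migration rates.  Lineages
co-located in a deme coalesce at rate k(k-1)/2; each lineage migrates to
another deme of its own group at total rate M1/2 and to a deme of another
group at total rate M2/2.  Each genealogy receives exactly one mutation on
a branch chosen proportionally to branch length, so every simulated locus
is polymorphic in the genealogy, matching how SNP loci are ascertained.

Observed loci are classified against the simulated cloud conditionally on
heterozygosity: the empirical P-value of a locus is computed from the
simulated loci nearest to it in heterozygosity.  Loci in the upper tail
(P < 0.01 by default) are candidates for directional selection, the lower
tail for balancing selection; loci with scaled heterozygosity below a
floor (0.2) are filtered as uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .differentiation import wc_theta_locus

log = logging.getLogger(__name__)

MAX_EVENTS = 50_000_000  # hard cap per genealogy; the process halts w.p. 1


@dataclass
class FdistConfig:
    """Parameters of the hierarchical coalescent null.

    sample_layout: one (group index, deme index, gene copies) triple per
    sampled deme; at most one sampled population per deme.  M1 and M2 are
    scaled migration rates (per-lineage rate x 2).  target_fst, when set,
    drives :func:`calibrate`.
    """

    sample_layout: list[tuple[int, int, int]]
    n_groups: int = 20
    demes_per_group: int = 100
    n_sims: int = 30_000
    M1: float = 10.0
    M2: float = 1.0
    target_fst: float | None = None
    het_conditioning_k: int = 1  # nearest het class; expand only below this
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.demes_per_group < 1:
            raise ValueError("counts must be positive")
        if self.M1 < 0 or self.M2 < 0:
            raise ValueError("migration rates must be >= 0")
        if sum(c for _, _, c in self.sample_layout) < 2:
            raise ValueError("need >= 2 sampled gene copies")
        seen = set()
        for g, d, c in self.sample_layout:
            if not (0 <= g < self.n_groups and 0 <= d < self.demes_per_group):
                raise ValueError(f"sampled deme ({g},{d}) outside the model")
            if (g, d) in seen:
                raise ValueError(f"deme ({g},{d}) sampled twice")
            seen.add((g, d))


@dataclass
class NullTable:
    """Simulated (heterozygosity, F_ST) pairs defining the neutral envelope."""

    het: np.ndarray
    fst: np.ndarray
    order: np.ndarray = field(default=None)  # het-sorted index, built lazily

    def __post_init__(self):
        self.het = np.asarray(self.het, dtype=float)
        self.fst = np.asarray(self.fst, dtype=float)
        if self.het.size != self.fst.size:
            raise ValueError("het and fst lengths differ")
        self.order = np.argsort(self.het, kind="stable")

    def __len__(self) -> int:
        return self.het.size

    def neighbourhood(self, het: float, k: int) -> np.ndarray:
        """F_ST values of the >= k simulated loci nearest in heterozygosity.

        Simulated heterozygosity is discrete (it is a function of the
        pooled derived-allele count), and the conditional F_ST distribution
        shifts across classes; splitting a class would bias the tail
        quantiles.  The neighbourhood therefore grows by whole
        heterozygosity classes, nearest first, until it holds at least k
        loci (or the table is exhausted).
        """
        hs = self.het[self.order]
        k = min(k, hs.size)
        # class boundaries in the sorted het vector
        starts = np.flatnonzero(np.concatenate([[True], np.diff(hs) > 1e-12]))
        ends = np.append(starts[1:], hs.size)
        classes = hs[starts]
        ci = int(np.argmin(np.abs(classes - het)))
        lo_c = hi_c = ci
        total = ends[ci] - starts[ci]
        while total < k:
            left_d = np.inf if lo_c == 0 else het - classes[lo_c - 1]
            right_d = np.inf if hi_c == classes.size - 1 else classes[hi_c + 1] - het
            if left_d <= right_d:
                lo_c -= 1
                total += ends[lo_c] - starts[lo_c]
            else:
                hi_c += 1
                total += ends[hi_c] - starts[hi_c]
        return self.fst[self.order[starts[lo_c]:ends[hi_c]]]

    def envelope(self, het_grid: np.ndarray, k: int = 1000, q=(0.01, 0.99)):
        """Quantile envelope of F_ST as a function of heterozygosity."""
        return np.array(
            [np.quantile(self.neighbourhood(h, k), q) for h in het_grid]
        )


@dataclass(frozen=True)
class OutlierCall:
    locus_id: str
    fst: float
    scaled_het: float
    p_high: float
    p_low: float
    classification: str  # high | low | neutral | filtered


# ---------------------------------------------------------------------------
# Structured-coalescent engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gillespie(leaf_deme_global, dpg, G, m1, m2, seed, max_events):
    """Event loop of the structured coalescent (compiled).

    leaf_deme_global: starting deme id (group * dpg + deme) per gene copy.
    Returns (parent, node_time, children) over 2n-1 nodes, leaves first.
    """
    np.random.seed(seed)
    n = leaf_deme_global.size
    n_demes = dpg * G
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    node_deme = np.empty(n_nodes, dtype=np.int64)
    active = np.empty(n_nodes, dtype=np.int64)
    count = np.zeros(n_demes, dtype=np.int64)
    for i in range(n):
        active[i] = i
        node_deme[i] = leaf_deme_global[i]
        count[leaf_deme_global[i]] += 1
    k = n
    coal_pairs = 0.0
    for d in range(n_demes):
        c = count[d]
        if c > 1:
            coal_pairs += c * (c - 1) * 0.5

    next_node = n
    t = 0.0
    events = 0
    while k > 1:
        events += 1
        if events > max_events:
            raise RuntimeError("genealogy exceeded the event cap")
        total = coal_pairs + k * (m1 + m2)
        if total <= 0.0:
            raise RuntimeError(
                "no possible event: isolated lineages with zero migration"
            )
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < coal_pairs:
            # coalescence: deme weighted by c(c-1)/2
            u = np.random.random() * coal_pairs
            acc = 0.0
            deme = -1
            for d in range(n_demes):
                c = count[d]
                if c > 1:
                    acc += c * (c - 1) * 0.5
                    if u < acc:
                        deme = d
                        break
            if deme == -1:  # float roundoff guard
                for d in range(n_demes):
                    if count[d] > 1:
                        deme = d
                        break
            c = count[deme]
            i1 = np.random.randint(0, c)
            i2 = np.random.randint(0, c - 1)
            if i2 >= i1:
                i2 += 1
            a1 = -1
            a2 = -1
            found = 0
            for ai in range(k):
                if node_deme[active[ai]] == deme:
                    if found == i1:
                        a1 = ai
                    if found == i2:
                        a2 = ai
                    found += 1
                    if a1 >= 0 and a2 >= 0:
                        break
            u_node = active[a1]
            v_node = active[a2]
            w = next_node
            next_node += 1
            parent[u_node] = w
            parent[v_node] = w
            children[w, 0] = u_node
            children[w, 1] = v_node
            node_time[w] = t
            node_deme[w] = deme
            lo_i = a1 if a1 < a2 else a2
            hi_i = a2 if a1 < a2 else a1
            active[lo_i] = w
            active[hi_i] = active[k - 1]
            k -= 1
            coal_pairs -= count[deme] - 1
            count[deme] -= 1
        else:
            ai = np.random.randint(0, k)
            node = active[ai]
            src = node_deme[node]
            g_src = src // dpg
            if np.random.random() * (m1 + m2) < m1:
                d_new = np.random.randint(0, dpg - 1)
                if d_new >= src % dpg:
                    d_new += 1
                dest = g_src * dpg + d_new
            else:
                g_new = np.random.randint(0, G - 1)
                if g_new >= g_src:
                    g_new += 1
                dest = g_new * dpg + np.random.randint(0, dpg)
            node_deme[node] = dest
            coal_pairs += count[dest] - (count[src] - 1)
            count[src] -= 1
            count[dest] += 1
    return parent, node_time, children


def _simulate_genealogy(cfg: FdistConfig, rng: np.random.Generator):
    """One genealogy under the two-level island model.

    Returns (parent, node_time, children, leaf_deme_index): tree arrays
    over 2n-1 nodes (leaves 0..n-1) plus, per leaf, the index of its
    sampled deme in cfg.sample_layout.  The event loop is seeded from the
    caller's generator, keeping the whole chain deterministic.
    """
    dpg = cfg.demes_per_group
    G = cfg.n_groups
    # effective per-lineage migration rates (no destination -> rate 0)
    m1 = cfg.M1 / 2.0 if dpg > 1 else 0.0
    m2 = cfg.M2 / 2.0 if G > 1 else 0.0

    leaf_deme = np.concatenate(
        [np.full(c, li, dtype=np.int64) for li, (_, _, c) in enumerate(cfg.sample_layout)]
    )
    start_deme = np.concatenate(
        [np.full(c, g * dpg + d, dtype=np.int64) for g, d, c in cfg.sample_layout]
    )
    seed = int(rng.integers(0, 2**31 - 1))
    parent, node_time, children = _gillespie(
        start_deme, dpg, G, m1, m2, seed, MAX_EVENTS
    )
    return parent, node_time, children, leaf_deme


def _place_mutation(parent, node_time, children, n_leaves, rng) -> np.ndarray:
    """Choose a branch with probability proportional to its length; return a
    boolean derived-state vector over leaves."""
    n_nodes = parent.size
    root = n_nodes - 1
    lengths = np.empty(n_nodes)
    for v in range(n_nodes):
        lengths[v] = 0.0 if v == root else node_time[parent[v]] - node_time[v]
    total = lengths.sum()
    target = rng.random() * total
    acc = 0.0
    chosen = root
    for v in range(n_nodes):
        acc += lengths[v]
        if target < acc:
            chosen = v
            break
    derived = np.zeros(n_leaves, dtype=bool)
    stack = [chosen]
    while stack:
        v = stack.pop()
        if v < n_leaves:
            derived[v] = True
        else:
            stack.append(int(children[v, 0]))
            stack.append(int(children[v, 1]))
    return derived


def coalesce_locus(cfg: FdistConfig, rng: np.random.Generator) -> np.ndarray:
    """Simulate one locus; returns derived-allele counts per sampled deme
    (in cfg.sample_layout order).  Always polymorphic in the genealogy."""
    parent, node_time, children, leaf_deme = _simulate_genealogy(cfg, rng)
    n = leaf_deme.size
    derived = _place_mutation(parent, node_time, children, n, rng)
    counts = np.zeros(len(cfg.sample_layout), dtype=np.int64)
    np.add.at(counts, leaf_deme[derived], 1)
    return counts


# ---------------------------------------------------------------------------
# Summaries of a simulated locus
# ---------------------------------------------------------------------------

def _pair_into_diploids(copies: int, derived: int, rng: np.random.Generator) -> tuple[int, int]:
    """Randomly pair gene copies within a deme; returns (n_diploids, n_het).

    An odd copy is dropped.
    """
    alleles = np.zeros(copies, dtype=np.int8)
    alleles[:derived] = 1
    rng.shuffle(alleles)
    n_dip = copies // 2
    pairs = alleles[: 2 * n_dip].reshape(n_dip, 2)
    return n_dip, int(np.sum(pairs.sum(axis=1) == 1))


def locus_summaries(
    cfg: FdistConfig, counts: np.ndarray, rng: np.random.Generator
) -> tuple[float, float]:
    """(total heterozygosity, theta) for one simulated locus.

    Heterozygosity is 2p(1-p) from the pooled derived-allele frequency;
    theta treats sampled demes as populations, with gene copies randomly
    paired into diploids.
    """
    copies = np.array([c for _, _, c in cfg.sample_layout])
    p = counts.sum() / copies.sum()
    het = 2.0 * p * (1.0 - p)
    n_ind = np.empty(len(copies), dtype=int)
    n_het = np.empty(len(copies), dtype=int)
    for i, (c, k) in enumerate(zip(copies, counts)):
        n_ind[i], n_het[i] = _pair_into_diploids(int(c), int(k), rng)
    comp = wc_theta_locus(n_ind, counts, n_het)
    theta = comp.theta
    return float(het), (float("nan") if theta is None else float(theta))


def _mean_theta(cfg: FdistConfig, n_loci: int, seed: int) -> float:
    """Multilocus (ratio-of-sums) theta over n_loci simulated loci."""
    rng = np.random.default_rng(seed)
    num = den = 0.0
    for _ in range(n_loci):
        counts = coalesce_locus(cfg, rng)
        copies = np.array([c for _, _, c in cfg.sample_layout])
        n_ind = np.empty(len(copies), dtype=int)
        n_het = np.empty(len(copies), dtype=int)
        for i, (c, k) in enumerate(zip(copies, counts)):
            n_ind[i], n_het[i] = _pair_into_diploids(int(c), int(k), rng)
        comp = wc_theta_locus(n_ind, counts, n_het)
        num += comp.a
        den += comp.a + comp.b + comp.c
    return num / den if den != 0 else float("nan")


def calibrate(
    cfg: FdistConfig,
    target_fst: float,
    tol: float = 0.01,
    probe_loci: int = 500,
    max_iter: int = 25,
    m_ratio: float = 10.0,
) -> tuple[float, float]:
    """Find (M1, M2) with M1 = m_ratio * M2 whose mean multilocus theta
    matches ``target_fst`` within ``tol``, by bisection on M2.

    Each probe uses common random numbers (the same seed), so the probed
    theta is a smooth decreasing function of M2.
    """
    from dataclasses import replace

    if not (0 < target_fst < 0.9):
        raise ValueError("target_fst must be in (0, 0.9)")

    def probe(m2: float) -> float:
        c = replace(cfg, M1=m_ratio * m2, M2=m2)
        return _mean_theta(c, probe_loci, cfg.seed)

    lo, hi = 0.02, 8.0  # theta(lo) high, theta(hi) low
    f_lo = probe(lo)
    while f_lo < target_fst and lo > 1e-8:
        lo /= 4.0
        f_lo = probe(lo)
    f_hi = probe(hi)
    while f_hi > target_fst and hi < 1e6:
        hi *= 4.0
        f_hi = probe(hi)
    if f_lo < target_fst or f_hi > target_fst:
        raise RuntimeError(
            f"cannot bracket target {target_fst}: theta({lo})={f_lo:.4f}, "
            f"theta({hi})={f_hi:.4f}"
        )
    best = None
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect on log scale
        f_mid = probe(mid)
        best = (m_ratio * mid, mid, f_mid)
        if abs(f_mid - target_fst) <= tol:
            log.info(
                "calibrate: M1=%.4g M2=%.4g achieves theta=%.4f (target %.3f)",
                best[0], best[1], f_mid, target_fst,
            )
            return best[0], best[1]
        if f_mid > target_fst:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge in {max_iter} iterations; bracket "
        f"M2 in [{lo:.4g}, {hi:.4g}], last theta {best[2]:.4f} vs target {target_fst}"
    )


def simulate_null(cfg: FdistConfig) -> NullTable:
    """n_sims independent loci -> the neutral (heterozygosity, F_ST) cloud."""
    rng = np.random.default_rng(cfg.seed)
    het = np.empty(cfg.n_sims)
    fst = np.empty(cfg.n_sims)
    for i in range(cfg.n_sims):
        counts = coalesce_locus(cfg, rng)
        het[i], fst[i] = locus_summaries(cfg, counts, rng)
    return NullTable(het=het, fst=fst)


def classify_outliers(
    observed: list[tuple[str, float, float]],
    null: NullTable,
    p_cut: float = 0.01,
    het_min: float = 0.2,
    het_conditioning_k: int = 1,
    het_scale: str = "multiply",
    seed: int = 0,
) -> list[OutlierCall]:
    """Classify observed loci against the null cloud.

    ``observed``: (locus id, theta, total heterozygosity) triples.  Scaled
    heterozygosity is het * (1 - theta) (``het_scale='divide'`` switches to
    het / (1 - theta)); loci at or below ``het_min`` scaled heterozygosity
    are 'filtered'.

    Empirical tail P-values condition on heterozygosity: each locus is
    compared with the simulated loci in its nearest heterozygosity class
    (classes grown to hold at least ``het_conditioning_k`` loci).  Because
    theta has discrete support within a class, ties between observed and
    simulated values are broken by a seeded uniform draw, giving P-values
    that are exactly uniform under the null rather than conservative:
    p_high = (#{sim > obs} + U * (1 + #{sim = obs})) / (m + 1), and p_low
    its mirror with the same U.  p_high < p_cut is the upper tail
    (directional selection), p_low < p_cut the lower tail (balancing).
    """
    if len(null) == 0:
        raise ValueError("null table is empty")
    rng = np.random.default_rng(seed)
    calls: list[OutlierCall] = []
    for locus_id, theta, het in observed:
        if theta is None or np.isnan(theta):
            log.info("classify_outliers: theta undefined at %s, skipped", locus_id)
            continue
        if het_scale == "multiply":
            scaled = het * (1.0 - theta)
        elif het_scale == "divide":
            scaled = het / (1.0 - theta) if theta < 1 else float("inf")
        else:
            raise ValueError(f"unknown het_scale {het_scale!r}")
        neigh = null.neighbourhood(het, het_conditioning_k)
        m = neigh.size
        gt = int(np.sum(neigh > theta + 1e-12))
        eq = int(np.sum(np.abs(neigh - theta) <= 1e-12))
        lt = m - gt - eq
        u = rng.random()
        p_high = (gt + u * (eq + 1)) / (m + 1)
        p_low = (lt + (1.0 - u) * (eq + 1)) / (m + 1)
        if scaled <= het_min:
            cls = "filtered"
        elif p_high < p_cut:
            cls = "high"
        elif p_low < p_cut:
            cls = "low"
        else:
            cls = "neutral"
        calls.append(OutlierCall(locus_id, float(theta), float(scaled), p_high, p_low, cls))
    return calls


# ---------------------------------------------------------------------------
# Layout helpers
# ---------------------------------------------------------------------------

def layout_from_dataset(ds, pops: list[str] | None = None) -> tuple[FdistConfig, list[str]]:
    """Build a sampled-deme layout from a dataset's popmap/groupmap.

    Each population occupies its own deme; populations sharing an
    empirical group share a simulated group.  Gene-copy counts are twice
    the per-locus mean number of usable individuals (rounded to an even
    count).  Returns a config (migration rates left at defaults) and the
    population order matching the layout.
    """
    from .popio import MISSING

    if pops is None:
        pops = ds.populations
    groupmap = ds.groupmap or {p: p for p in pops}
    groups = list(dict.fromkeys(groupmap.get(p, p) for p in pops))
    layout = []
    next_deme = {g: 0 for g in groups}
    for p in pops:
        gname = groupmap.get(p, p)
        g = groups.index(gname)
        idx = ds.pop_indices(p)
        usable = (ds.genotypes[idx, :] != MISSING).sum(axis=0)
        mean_ind = float(usable.mean()) if usable.size else float(idx.size)
        copies = max(2, 2 * int(round(mean_ind)))
        layout.append((g, next_deme[gname], copies))
        next_deme[gname] += 1
    cfg = FdistConfig(
        sample_layout=layout,
        n_groups=max(len(groups), FdistConfig.n_groups),
        demes_per_group=max(max(next_deme.values()), FdistConfig.demes_per_group),
    )
    return cfg, list(pops)
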