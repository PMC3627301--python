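"""Linkage disequilibrium from unphased diploid genotypes.

r^2 is computed from two-locus haplotype frequencies estimated by
expectation-maximisation over the double-heterozygote phase ambiguity; the
genome-wide decay of mean r^2 with distance is summarised by binned means, a
logarithmic fit y = a*ln(x) + b (x in Mb), and two characteristic
distances: the empirical half-length and the fitted distance at which r^2
reaches a threshold (0.2 by default).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .popio import MISSING, GenotypeDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDPair:
    locus_a: str
    locus_b: str
    chrom: str
    distance: int  # basepairs
    r2: float
    D: float


@dataclass
class DecayFit:
    """Binned mean r^2 versus distance, with logarithmic-fit coefficients."""

    bin_width: int
    bin_mid_bp: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    a: float  # slope on ln(distance in Mb)
    b: float  # intercept


class ExtrapolationWarning(UserWarning):
    """Characteristic distance lies outside the fitted data range."""


# ---------------------------------------------------------------------------
# Pairwise r^2 (EM over the double-heterozygote ambiguity)
# ---------------------------------------------------------------------------

def r2_pair(gA: np.ndarray, gB: np.ndarray, tol: float = 1e-11, max_iter: int = 5000):
    """(r2, D) between two genotype columns, or (None, None) if undefined.

    Haplotype frequencies are estimated by EM initialised at linkage
    equilibrium; only individuals non-missing at both loci contribute.
    Undefined when fewer than two such individuals exist or either locus is
    monomorphic in the joint sample.
    """
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    ok = (gA != MISSING) & (gB != MISSING)
    a = gA[ok].astype(float)
    b = gB[ok].astype(float)
    n = a.size
    if n < 2:
        return None, None
    pA = a.sum() / (2 * n)  # alt frequency at locus A
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None, None

    # haplotypes: AB means alt at both loci
    n_dh = int(np.sum((a == 1) & (b == 1)))  # double heterozygotes
    # known haplotype counts (each individual carries 2)
    #   contribution of alt-alleles to AB haplotypes outside double hets:
    #   individual (i, j) with i,j in {0,1,2} contributes
    #   min resolvable counts; enumerate the 8 unambiguous cells
    c_AB = c_Ab = c_aB = c_ab = 0.0
    for gi, gj, hAB, hAb, haB, hab in (
        (0, 0, 0, 0, 0, 2),
        (0, 1, 0, 0, 1, 1),
        (0, 2, 0, 0, 2, 0),
        (1, 0, 0, 1, 0, 1),
        (1, 2, 1, 0, 1, 0),
        (2, 0, 0, 2, 0, 0),
        (2, 1, 1, 1, 0, 0),
        (2, 2, 2, 0, 0, 0),
    ):
        m = int(np.sum((a == gi) & (b == gj)))
        c_AB += m * hAB
        c_Ab += m * hAb
        c_aB += m * haB
        c_ab += m * hab

    total = 2.0 * n
    lo_bound = max(0.0, pA + pB - 1.0)
    hi_bound = min(pA, pB)

    def loglik(p_ab_f):
        AB = p_ab_f
        Ab = pA - p_ab_f
        aB = pB - p_ab_f
        ab = 1 - pA - pB + p_ab_f
        if min(AB, Ab, aB, ab) < -1e-12:
            return -np.inf
        ll = 0.0
        # known-haplotype contributions plus double-het mixture term
        for cnt, f in ((c_AB, AB), (c_Ab, Ab), (c_aB, aB), (c_ab, ab)):
            if cnt:
                if f <= 0:
                    return -np.inf
                ll += cnt * math.log(f)
        if n_dh:
            mix = AB * ab + Ab * aB
            if mix <= 0:
                return -np.inf
            ll += n_dh * math.log(mix)
        return ll

    def run_em(start):
        p_AB = start
        for _ in range(max_iter):
            p_Ab = pA - p_AB
            p_aB = pB - p_AB
            p_ab = 1.0 - pA - pB + p_AB
            denom = p_AB * p_ab + p_Ab * p_aB
            frac = 0.5 if denom <= 0 else p_AB * p_ab / denom
            # a coupling-phase double het carries exactly one AB haplotype
            new = (c_AB + n_dh * frac) / total
            if abs(new - p_AB) < tol:
                return new
            p_AB = new
        return p_AB

    # the likelihood can be multimodal in p_AB when double heterozygotes
    # dominate; run EM from equilibrium and both phase extremes, keep the
    # highest-likelihood fixed point
    span = hi_bound - lo_bound
    starts = {pA * pB, lo_bound + 0.02 * span, hi_bound - 0.02 * span}
    # boundary frequencies are valid maximisers EM only approaches
    candidates = [run_em(s) for s in starts] + [lo_bound, hi_bound]
    p_AB = max(candidates, key=loglik)

    D = p_AB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return float(min(r2, 1.0)), float(D)


def syntenic_pairs(
    ds: GenotypeDataset,
    population: str | None = None,
    max_distance: int | None = None,
) -> list[LDPair]:
    """All same-chromosome polymorphic locus pairs with their r^2.

    ``population=None`` pools every sample; otherwise only that
    population's individuals are used.  Monomorphic-in-sample pairs are
    skipped.
    """
    if population is None:
        g = ds.genotypes
    else:
        g = ds.genotypes[ds.pop_indices(population), :]
    by_chrom: dict[str, list[int]] = {}
    for j, loc in enumerate(ds.loci):
        by_chrom.setdefault(loc.chrom, []).append(j)
    out: list[LDPair] = []
    for chrom in sorted(by_chrom):
        idx = sorted(by_chrom[chrom], key=lambda j: ds.loci[j].pos)
        for i, j1 in enumerate(idx):
            for j2 in idx[i + 1 :]:
                d = abs(ds.loci[j2].pos - ds.loci[j1].pos)
                if max_distance is not None and d > max_distance:
                    continue
                r2, D = r2_pair(g[:, j1], g[:, j2])
                if r2 is None:
                    continue
                out.append(
                    LDPair(ds.loci[j1].locus_id, ds.loci[j2].locus_id, chrom, d, r2, D)
                )
    return out


# ---------------------------------------------------------------------------
# Decay curve
# ---------------------------------------------------------------------------

def fit_decay(
    pairs: list[LDPair],
    bin_width: int = 5_000_000,
    truncate_at: int | None = None,
) -> DecayFit:
    """Bin pairs by distance, average r^2 per bin, and fit a*ln(x Mb) + b.

    Bins are [k*w, (k+1)*w); the fit is ordinary least squares of bin mean
    r^2 on the natural log of the bin midpoint in Mb, over nonempty bins.
    """
    if not pairs:
        raise ValueError("no pairs to fit")
    d = np.array([p.distance for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs], dtype=float)
    if truncate_at is not None:
        keep = d < truncate_at
        d, r2 = d[keep], r2[keep]
    k = (d // bin_width).astype(int)
    n_bins = int(k.max()) + 1
    sums = np.bincount(k, weights=r2, minlength=n_bins)
    counts = np.bincount(k, minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < 2:
        raise ValueError("need at least 2 nonempty distance bins")
    mids = (np.arange(n_bins) + 0.5) * bin_width
    mean_r2 = sums[nonempty] / counts[nonempty]
    mid_bp = mids[nonempty]
    x = np.log(mid_bp / 1e6)
    a, b = np.polyfit(x, mean_r2, 1)
    return DecayFit(
        bin_width=bin_width,
        bin_mid_bp=mid_bp,
        mean_r2=mean_r2,
        n_pairs=counts[nonempty],
        a=float(a),
        b=float(b),
    )


def decay_distance(fit: DecayFit, threshold: float = 0.2) -> float:
    """Distance (bp) at which the fitted curve reaches ``threshold`` r^2.

    Solves a*ln(x) + b = t for x in Mb.  Requires a decaying fit (a < 0);
    warns if the solution lies outside the fitted distance range.
    """
    if fit.a >= 0:
        raise ValueError(f"fit does not decay (a = {fit.a:.4g} >= 0)")
    x_mb = float(np.exp((threshold - fit.b) / fit.a))
    bp = x_mb * 1e6
    lo, hi = float(fit.bin_mid_bp.min()), float(fit.bin_mid_bp.max())
    if not (lo <= bp <= hi):
        warnings.warn(
            f"r2={threshold} reached at {bp/1e6:.3g} Mb, outside the fitted "
            f"range [{lo/1e6:.3g}, {hi/1e6:.3g}] Mb",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return bp


def half_length(fit: DecayFit) -> float:
    """Distance (bp) at which mean r^2 first falls to half its maximum.

    Uses linear interpolation of the empirical binned curve (not the
    logarithmic fit); the maximum is the shortest-distance bin mean.  If
    the curve never crosses half-maximum, returns the largest binned
    distance with a warning.
    """
    if fit.mean_r2.size == 0:
        raise ValueError("empty fit")
    y = fit.mean_r2
    x = fit.bin_mid_bp
    target = y[0] / 2.0
    for i in range(1, y.size):
        if y[i] <= target:
            if y[i] == y[i - 1]:
                return float(x[i])
            frac = (y[i - 1] - target) / (y[i - 1] - y[i])
            return float(x[i - 1] + frac * (x[i] - x[i - 1]))
    warnings.warn(
        "binned r2 curve never falls to half its maximum; returning the "
        "largest binned distance",
        ExtrapolationWarning,
        stacklevel=2,
    )
    return float(x[-1])
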