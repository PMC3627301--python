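"""Among-population differentiation: Weir-Cockerham theta and Jost's D_est.

theta follows the 1984 variance-component formulation for biallelic loci:
per-locus components a (among populations), b (among individuals within
populations) and c (within individuals), with the multilocus estimate the
ratio of summed components sum(a)/sum(a+b+c).  Negative per-locus values
are kept (not truncated) so the multilocus combination stays unbiased.

D_est uses the Nei-Chesser unbiased H_S/H_T with the harmonic-mean sample
size, D = [(H_T - H_S)/(1 - H_S)] * r/(r-1), averaged over loci.

Uncertainty: bootstrap over loci (theta CI), bootstrap over individuals
within populations (D_est CI), and permutation of individuals among
populations for P-values.  FDR control is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .popio import MISSING, GenotypeDataset

log = logging.getLogger(__name__)


@dataclass
class ThetaComponents:
    """Weir-Cockerham variance components for one locus."""

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float | None:
        tot = self.a + self.b + self.c
        if tot == 0:
            return None
        return self.a / tot


@dataclass
class ThetaOverall:
    theta: float
    ci_low: float | None
    ci_high: float | None
    pairwise: "np.ndarray | None" = None  # theta per population pair
    pairwise_p: "np.ndarray | None" = None
    populations: list[str] | None = None


@dataclass
class DestResult:
    per_locus: np.ndarray
    overall: float
    p_value: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


# ---------------------------------------------------------------------------
# Per-locus components
# ---------------------------------------------------------------------------

def wc_theta_locus(n_ind, alt_count, het_count) -> ThetaComponents:
    """Variance components from per-population counts at one biallelic locus.

    n_ind[i]: usable diploid individuals in population i; alt_count[i]:
    alt-allele copies; het_count[i]: heterozygous individuals.
    """
    n = np.asarray(n_ind, dtype=float)
    ok = n > 0
    n = n[ok]
    alt = np.asarray(alt_count, dtype=float)[ok]
    het = np.asarray(het_count, dtype=float)[ok]
    r = n.size
    if r < 2:
        raise ValueError("wc_theta_locus needs >= 2 populations with data")
    p = alt / (2 * n)
    h = het / n

    nbar = n.mean()
    r_nbar = r * nbar
    nc = (r_nbar - np.sum(n**2) / r_nbar) / (r - 1)
    pbar = np.sum(n * p) / r_nbar
    s2 = np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(n * h) / r_nbar

    if nbar <= 1 or nc <= 0:
        raise ValueError("sample sizes too small for the estimator")

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return ThetaComponents(a=float(a), b=float(b), c=float(c))


def _per_pop_counts(genotypes: np.ndarray, labels: np.ndarray, pops: list[str]):
    """(n_ind, alt, het) arrays of shape (n_pops, n_loci)."""
    n_pops = len(pops)
    n_loci = genotypes.shape[1]
    n_ind = np.zeros((n_pops, n_loci))
    alt = np.zeros((n_pops, n_loci))
    het = np.zeros((n_pops, n_loci))
    for i, p in enumerate(pops):
        g = genotypes[labels == p, :]
        usable = g != MISSING
        n_ind[i] = usable.sum(axis=0)
        alt[i] = np.where(usable, g, 0).sum(axis=0)
        het[i] = (g == 1).sum(axis=0)
    return n_ind, alt, het


def _wc_components_vec(n_ind, alt, het):
    """Vectorised W&C components over loci; returns (a, b, c) arrays.

    Loci where fewer than 2 populations have data get NaN components.
    """
    n_pops, n_loci = n_ind.shape
    with np.errstate(invalid="ignore", divide="ignore"):
        has = n_ind > 0
        r = has.sum(axis=0).astype(float)
        n = np.where(has, n_ind, np.nan)
        p = alt / (2 * n)
        h = het / n
        nbar = np.nanmean(n, axis=0)
        r_nbar = r * nbar
        nc = (r_nbar - np.nansum(n**2, axis=0) / r_nbar) / (r - 1)
        pbar = np.nansum(n * p, axis=0) / r_nbar
        s2 = np.nansum(n * (p - pbar) ** 2, axis=0) / ((r - 1) * nbar)
        hbar = np.nansum(n * h, axis=0) / r_nbar
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        bad = (r < 2) | (nbar <= 1) | (nc <= 0)
        a = np.where(bad, np.nan, a)
        b = np.where(bad, np.nan, b)
        c = np.where(bad, np.nan, c)
    return a, b, c


def multilocus_theta(genotypes: np.ndarray, labels: np.ndarray, pops=None) -> float:
    """Ratio-of-sums multilocus theta sum(a)/sum(a+b+c) over usable loci."""
    if pops is None:
        pops = list(dict.fromkeys(labels))
    n_ind, alt, het = _per_pop_counts(genotypes, labels, pops)
    a, b, c = _wc_components_vec(n_ind, alt, het)
    ok = ~np.isnan(a)
    denom = np.sum(a[ok] + b[ok] + c[ok])
    if denom == 0:
        return float("nan")
    return float(np.sum(a[ok]) / denom)


def per_locus_theta(ds: GenotypeDataset, pops: list[str] | None = None) -> np.ndarray:
    """theta per locus (NaN where undefined) over the given populations."""
    labels = ds.pop_labels()
    if pops is None:
        pops = ds.populations
    mask = np.isin(labels, pops)
    n_ind, alt, het = _per_pop_counts(ds.genotypes[mask], labels[mask], pops)
    a, b, c = _wc_components_vec(n_ind, alt, het)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = a + b + c
        return np.where((tot != 0) & ~np.isnan(tot), a / tot, np.nan)


def wc_theta_overall(
    ds: GenotypeDataset,
    pops: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    pairwise: bool = False,
) -> ThetaOverall:
    """Multilocus theta with a 95% bootstrap-over-loci CI; optional pairwise
    matrix with permutation P-values (individuals shuffled between the two
    populations of each pair)."""
    labels = ds.pop_labels()
    if pops is None:
        pops = ds.populations
    mask = np.isin(labels, pops)
    g = ds.genotypes[mask]
    lab = labels[mask]

    theta = multilocus_theta(g, lab, pops)
    rng = np.random.default_rng(seed)

    n_loci = g.shape[1]
    if n_loci >= 2:
        n_ind, alt, het = _per_pop_counts(g, lab, pops)
        a, b, c = _wc_components_vec(n_ind, alt, het)
        ok = ~np.isnan(a)
        a, bb, cc = a[ok], b[ok], c[ok]
        k = a.size
        boots = np.empty(n_perm)
        for it in range(n_perm):
            idx = rng.integers(0, k, size=k)
            denom = np.sum(a[idx] + bb[idx] + cc[idx])
            boots[it] = np.sum(a[idx]) / denom if denom != 0 else np.nan
        ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
    else:
        log.warning("wc_theta_overall: <2 loci, CI undefined")
        ci_low = ci_high = None

    pw = pw_p = None
    if pairwise:
        n_pops = len(pops)
        pw = np.full((n_pops, n_pops), np.nan)
        pw_p = np.full((n_pops, n_pops), np.nan)
        for i in range(n_pops):
            for j in range(i + 1, n_pops):
                sub = np.isin(lab, [pops[i], pops[j]])
                g2, lab2 = g[sub], lab[sub]
                obs = multilocus_theta(g2, lab2, [pops[i], pops[j]])
                ge = 0
                for _ in range(n_perm):
                    perm_lab = rng.permutation(lab2)
                    t = multilocus_theta(g2, perm_lab, [pops[i], pops[j]])
                    if not np.isnan(t) and t >= obs - 1e-12:
                        ge += 1
                pw[i, j] = pw[j, i] = obs
                pw_p[i, j] = pw_p[j, i] = (1 + ge) / (1 + n_perm)

    return ThetaOverall(
        theta=theta,
        ci_low=None if ci_low is None else float(ci_low),
        ci_high=None if ci_high is None else float(ci_high),
        pairwise=pw,
        pairwise_p=pw_p,
        populations=list(pops),
    )


# ---------------------------------------------------------------------------
# Jost's D_est
# ---------------------------------------------------------------------------

def _dest_per_locus(genotypes: np.ndarray, labels: np.ndarray, pops: list[str]) -> np.ndarray:
    """Per-locus D_est (Nei-Chesser estimators, harmonic-mean sample size).

    NaN where undefined (locus with <2 populations of data, or H_S = 1).
    """
    n_ind, alt, _ = _per_pop_counts(genotypes, labels, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        has = n_ind > 0
        r = has.sum(axis=0).astype(float)
        n = np.where(has, n_ind, np.nan)
        p = alt / (2 * n)
        # harmonic mean sample size over populations with data
        ntilde = r / np.nansum(1.0 / n, axis=0)
        hs_raw = np.nanmean(1 - p**2 - (1 - p) ** 2, axis=0)
        hs = (2 * ntilde / (2 * ntilde - 1)) * hs_raw
        pbar = np.nanmean(p, axis=0)  # unweighted across populations
        ht_raw = 1 - pbar**2 - (1 - pbar) ** 2
        ht = ht_raw + hs / (2 * ntilde * r)
        d = ((ht - hs) / (1 - hs)) * (r / (r - 1))
        d = np.where((r < 2) | np.isclose(hs, 1.0), np.nan, d)
    return d


def jost_dest(
    ds: GenotypeDataset,
    pops: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> DestResult:
    """Overall D_est (mean of per-locus values) with a permutation P-value
    (individuals shuffled among populations) and a 95% CI from
    bootstrapping individuals within populations."""
    labels = ds.pop_labels()
    if pops is None:
        pops = ds.populations
    if len(pops) < 2:
        raise ValueError("jost_dest needs >= 2 populations")
    mask = np.isin(labels, pops)
    g = ds.genotypes[mask]
    lab = labels[mask]

    per_locus = _dest_per_locus(g, lab, pops)
    n_skipped = int(np.isnan(per_locus).sum())
    if n_skipped:
        log.info("jost_dest: %d loci skipped (undefined D_est)", n_skipped)
    overall = float(np.nanmean(per_locus))

    rng = np.random.default_rng(seed)
    p_value = ci_low = ci_high = None
    if n_perm > 0:
        ge = 0
        for _ in range(n_perm):
            d = _dest_per_locus(g, rng.permutation(lab), pops)
            if np.nanmean(d) >= overall - 1e-12:
                ge += 1
        p_value = (1 + ge) / (1 + n_perm)

        boots = np.empty(n_perm)
        pop_idx = {p: np.flatnonzero(lab == p) for p in pops}
        for it in range(n_perm):
            rows = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in pop_idx.values()]
            )
            boots[it] = np.nanmean(_dest_per_locus(g[rows], lab[rows], pops))
        ci_low, ci_high = (float(v) for v in np.nanpercentile(boots, [2.5, 97.5]))

    return DestResult(
        per_locus=per_locus,
        overall=overall,
        p_value=p_value,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask at level alpha."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject
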