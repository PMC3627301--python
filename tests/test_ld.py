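"""r^2 estimation (EM vs direct likelihood maximisation), decay curves,
and characteristic distances."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from zfpg import ld
from zfpg.ld import (
    DecayFit,
    ExtrapolationWarning,
    LDPair,
    decay_distance,
    fit_decay,
    half_length,
    r2_pair,
    syntenic_pairs,
)

from conftest import make_dataset


def r2_grid_oracle(gA, gB, return_nll=False):
    """ML haplotype-frequency oracle: maximise the multinomial genotype
    likelihood over p_AB with allele frequencies fixed at their observed
    values (vectorised grid search + bounded continuous refinement).

    With ``return_nll`` also returns (pA, pB, nll function) so callers can
    check likelihood-equivalence when the profile is numerically flat."""
    gA = np.asarray(gA)
    gB = np.asarray(gB)
    ok = (gA >= 0) & (gB >= 0)
    a, b = gA[ok], gB[ok]
    n = a.size
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    counts = np.zeros((3, 3))
    for gi, gj in zip(a, b):
        counts[gi, gj] += 1

    def neg_loglik_vec(t):
        """-loglik for an array of candidate p_AB values."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        AB = t
        Ab = pA - t
        aB = pB - t
        ab = 1 - pA - pB + t
        bad = (AB < -1e-12) | (Ab < -1e-12) | (aB < -1e-12) | (ab < -1e-12)
        AB, Ab, aB, ab = (np.clip(x, 0, None) for x in (AB, Ab, aB, ab))
        cell = {
            (2, 2): AB * AB, (2, 1): 2 * AB * Ab, (2, 0): Ab * Ab,
            (1, 2): 2 * AB * aB, (0, 2): aB * aB, (0, 1): 2 * aB * ab,
            (0, 0): ab * ab, (1, 0): 2 * Ab * ab,
            (1, 1): 2 * AB * ab + 2 * Ab * aB,
        }
        ll = np.zeros_like(t)
        for (gi, gj), prob in cell.items():
            c = counts[gi, gj]
            if c:
                with np.errstate(divide="ignore"):
                    ll += c * np.log(prob)
        ll[bad] = -np.inf
        out = -ll
        out[np.isnan(out)] = np.inf
        return out

    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.linspace(lo, hi, 2001)
    vals = neg_loglik_vec(grid)
    i0 = int(np.argmin(vals))
    x0 = grid[i0]
    span = (hi - lo) / 2000
    res = minimize_scalar(
        lambda x: float(neg_loglik_vec(x)[0]),
        bounds=(max(lo, x0 - span), min(hi, x0 + span)),
        method="bounded", options={"xatol": 1e-12},
    )
    # best of: refined point, best grid point, and the exact bounds
    cands = [float(res.x), float(x0), lo, hi]
    pab = min(cands, key=lambda x: float(neg_loglik_vec(x)[0]))
    D = pab - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    if return_nll:
        return r2, pab, pA, pB, lambda x: float(neg_loglik_vec(x)[0])
    return r2


def assert_matches_ml_oracle(gA, gB, r2, D, tol=1e-6):
    """r2 equals the oracle's value, or the implementation's haplotype
    frequency is a likelihood-equivalent maximiser (the profile can be
    numerically flat near a boundary, where the maximiser location -- and
    hence r2 -- is not identifiable beyond the likelihood's resolution)."""
    orc, pab_orc, pA, pB, nll = r2_grid_oracle(gA, gB, return_nll=True)
    if abs(r2 - orc) <= tol:
        return
    pab_impl = D + pA * pB
    assert nll(pab_impl) <= nll(pab_orc) + 1e-8, (r2, orc)



class TestR2Pair:
    def test_perfect_coupling(self):
        g = np.array([2, 2, 2, 0, 0, 0], dtype=np.int8)
        r2, D = r2_pair(g, g.copy())
        assert r2 == pytest.approx(1.0)
        assert D == pytest.approx(0.25)

    def test_monomorphic_undefined(self):
        a = np.array([1, 1, 0, 2], dtype=np.int8)
        b = np.zeros(4, dtype=np.int8)
        assert r2_pair(a, b) == (None, None)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        n = 500
        a = np.repeat([0, 1, 2], [125, 250, 125]).astype(np.int8)
        b = rng.permutation(a)
        r2, _ = r2_pair(a, b)
        assert r2 < 0.05

    def test_symmetry_and_allele_relabeling(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.3, 50).astype(np.int8)
        b = rng.binomial(2, 0.6, 50).astype(np.int8)
        if r2_pair(a, b)[0] is None:
            pytest.fail("fixture degenerate")
        r_ab = r2_pair(a, b)[0]
        r_ba = r2_pair(b, a)[0]
        r_flip = r2_pair((2 - a).astype(np.int8), b)[0]
        assert r_ab == pytest.approx(r_ba, abs=1e-10)
        assert r_ab == pytest.approx(r_flip, abs=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_em_matches_ml_oracle(self, seed):
        # random tables including double heterozygotes
        rng = np.random.default_rng(seed)
        checked = 0
        while checked < 25:
            n = int(rng.integers(6, 30))
            pa, pb = rng.uniform(0.15, 0.85, 2)
            rho = rng.uniform(-0.5, 0.9)
            # correlated haplotypes via a Gaussian copula on 2n gametes
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2 * n)
            hA = (z[:, 0] < np.quantile(z[:, 0], pa)).astype(int)
            hB = (z[:, 1] < np.quantile(z[:, 1], pb)).astype(int)
            gA = (hA[:n] + hA[n:]).astype(np.int8)
            gB = (hB[:n] + hB[n:]).astype(np.int8)
            r2, D = r2_pair(gA, gB)
            if r2 is None:
                continue
            checked += 1
            assert_matches_ml_oracle(gA, gB, r2, D)


class TestSyntenicPairs:
    def test_cross_chromosome_excluded(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, size=(30, 2)).astype(np.int8)
        ds = make_dataset(g, positions=[("chr01", 100), ("chr02", 100)])
        assert syntenic_pairs(ds) == []

    def test_three_loci_three_pairs(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.5, size=(30, 3)).astype(np.int8)
        ds = make_dataset(g)
        pairs = syntenic_pairs(ds)
        assert len(pairs) == 3
        assert all(p.distance == abs(1000) or p.distance == 2000 for p in pairs)

    def test_count_matches_combinatorial_oracle(self, small_sim):
        ds, _ = small_sim
        pairs = syntenic_pairs(ds)
        # oracle: sum over chromosomes of C(k, 2) over polymorphic loci
        from zfpg.popio import MISSING
        per_chrom = {}
        for j, loc in enumerate(ds.loci):
            col = ds.genotypes[:, j]
            col = col[col != MISSING]
            if 0 < col.sum() < 2 * col.size:
                per_chrom[loc.chrom] = per_chrom.get(loc.chrom, 0) + 1
        expected = sum(k * (k - 1) // 2 for k in per_chrom.values())
        assert len(pairs) == expected


def pairs_from_bins(bin_means, bin_width=1_000_000, n_per_bin=1):
    out = []
    for i, m in enumerate(bin_means):
        mid = int((i + 0.5) * bin_width)
        for _ in range(n_per_bin):
            out.append(LDPair("a", "b", "chr01", mid, m, 0.0))
    return out


class TestFitDecay:
    def test_exact_log_law_recovered(self):
        w = 1_000_000
        mids_mb = (np.arange(10) + 0.5)
        means = -0.065 * np.log(mids_mb) + 0.306
        fit = fit_decay(pairs_from_bins(means, w), bin_width=w)
        assert fit.a == pytest.approx(-0.065, abs=1e-10)
        assert fit.b == pytest.approx(0.306, abs=1e-10)

    def test_constant_curve(self):
        w = 1_000_000
        fit = fit_decay(pairs_from_bins([0.3] * 5, w), bin_width=w)
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(0.3, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        w = 1_000_000
        means = np.clip(-0.05 * np.log(np.arange(1, 51)) + 0.25
                        + rng.normal(0, 0.01, 50), 0, 1)
        fit = fit_decay(pairs_from_bins(means, w), bin_width=w)
        x = np.log((np.arange(50) + 0.5))
        y = means
        sxx = np.sum((x - x.mean()) ** 2)
        a = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        b = y.mean() - a * x.mean()
        assert fit.a == pytest.approx(a, abs=1e-10)
        assert fit.b == pytest.approx(b, abs=1e-10)

    def test_single_bin_errors(self):
        with pytest.raises(ValueError):
            fit_decay(pairs_from_bins([0.3]), bin_width=1_000_000)

    def test_recovery_within_ols_error(self):
        # noisy log-law: recovered coefficients within 3 SE over replicates
        rng = np.random.default_rng(33)
        w = 1_000_000
        n_bins, sigma = 40, 0.02
        a_true, b_true = -0.06, 0.28
        x = np.log(np.arange(n_bins) + 0.5)
        sxx = np.sum((x - x.mean()) ** 2)
        se_a = sigma / math.sqrt(sxx)
        hits = 0
        for _ in range(100):
            y = a_true * x + b_true + rng.normal(0, sigma, n_bins)
            fit = fit_decay(pairs_from_bins(y, w), bin_width=w)
            if abs(fit.a - a_true) < 3 * se_a:
                hits += 1
        assert hits >= 95


class TestCharacteristicDistances:
    def test_published_style_fit_distance(self):
        fit = DecayFit(1, np.array([1e6, 2e6]), np.array([0.3, 0.25]),
                       np.array([1, 1]), a=-0.065, b=0.306)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            d = decay_distance(fit, 0.2)
        assert d / 1e6 == pytest.approx(math.exp((0.306 - 0.2) / 0.065), rel=1e-12)
        assert 5.0e6 < d < 5.2e6

    def test_threshold_at_intercept_is_one_mb(self):
        fit = DecayFit(1, np.array([0.5e6, 1.5e6]), np.array([0.3, 0.2]),
                       np.array([1, 1]), a=-0.1, b=0.25)
        assert decay_distance(fit, 0.25) == pytest.approx(1e6)

    def test_flat_wild_style_fit_warns_extrapolation(self):
        # nearly flat fit never reaches 0.2 inside the data range
        fit = DecayFit(1, np.array([1e6, 30e6]), np.array([0.018, 0.015]),
                       np.array([1, 1]), a=-0.00082, b=0.018)
        with pytest.warns(ExtrapolationWarning):
            d = decay_distance(fit, 0.2)
        assert d < 1e6  # far below the first bin: effectively instant decay

    def test_non_decaying_errors(self):
        fit = DecayFit(1, np.array([1e6, 2e6]), np.array([0.1, 0.2]),
                       np.array([1, 1]), a=0.01, b=0.1)
        with pytest.raises(ValueError):
            decay_distance(fit, 0.2)

    def test_half_length_interpolation(self):
        fit = DecayFit(1, np.array([1e6, 2e6, 3e6]),
                       np.array([0.4, 0.2, 0.1]), np.array([1, 1, 1]),
                       a=-0.1, b=0.4)
        assert half_length(fit) == pytest.approx(2e6)

    def test_half_length_flat_warns(self):
        fit = DecayFit(1, np.array([1e6, 2e6, 3e6]),
                       np.array([0.3, 0.29, 0.28]), np.array([1, 1, 1]),
                       a=-0.01, b=0.3)
        with pytest.warns(ExtrapolationWarning):
            assert half_length(fit) == pytest.approx(3e6)
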