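"""Balancing, expected signal, O/E detrending and correlation maps."""

import numpy as np
import pytest

import hicmap as hm
from hicmap.balance import correlate, detrend, expected, filter_bins
from hicmap.synthetic import SyntheticSpec

from conftest import toy_map


def sinkhorn_weights(counts, n_iter=5000, tol=1e-12):
    """Independent dense Sinkhorn iteration: rescale rows/cols toward
    uniform marginals, return the per-bin weights."""
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    w = np.ones(n)
    for _ in range(n_iter):
        m = (w[:, None] * w[None, :] * counts).sum(axis=1)
        if np.var(m / m.mean()) < tol:
            break
        w = w / np.sqrt(m / m.mean())
    m = (w[:, None] * w[None, :] * counts).sum(axis=1)
    return w / np.sqrt(m.mean())


class TestFilterBins:
    def test_zero_marginal_bin_filtered(self):
        counts = np.ones((5, 5))
        counts[2, :] = 0
        counts[:, 2] = 0
        m = filter_bins(toy_map(counts))
        assert np.isnan(m.bintable.weights[2])
        assert np.isfinite(np.delete(m.bintable.weights, 2)).all()

    def test_uniform_map_keeps_all_bins(self):
        m = filter_bins(toy_map(np.ones((6, 6))))
        assert np.isfinite(m.bintable.weights).all()

    def test_mad_outlier_filtered(self):
        """A bin whose counts are divided by 1000 fails the MAD-max test."""
        rng = np.random.default_rng(5)
        n = 60
        counts = rng.poisson(500, (n, n)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        counts[7, :] /= 50
        counts[:, 7] /= 50
        counts = np.rint(counts)
        m = filter_bins(toy_map(counts), mad_max=5)
        # independent oracle: direct MAD computation on log marginals
        marg = counts.sum(axis=1)
        logm = np.log10(marg[marg > 0])
        med, mad = np.median(logm), np.median(np.abs(logm - np.median(logm)))
        assert np.log10(marg[7]) < med - 5 * mad
        assert np.isnan(m.bintable.weights[7])


class TestBalance:
    def test_constant_matrix_gives_equal_weights_and_unit_marginals(self):
        m = toy_map(np.full((8, 8), 5))
        out, result = hm.balance(m, tol=1e-10)
        assert result.converged
        w = out.bintable.weights
        np.testing.assert_allclose(w, w[0], rtol=1e-6)
        bal = out.dense("balanced")
        np.testing.assert_allclose(np.nansum(bal, axis=1), 1.0, rtol=1e-4)

    def test_three_by_three_matches_sinkhorn_oracle(self):
        counts = np.array([[0, 4, 2], [4, 0, 6], [2, 6, 0]])
        m = toy_map(counts)
        out, result = hm.balance(m, tol=1e-26, max_iter=10_000)
        oracle = sinkhorn_weights(counts, tol=1e-26)
        np.testing.assert_allclose(out.bintable.weights, oracle, atol=1e-10)

    def test_doubling_counts_scales_weights_by_inverse_sqrt2(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, (10, 10))
        counts = np.triu(counts) + np.triu(counts, 1).T
        m1 = toy_map(counts)
        m2 = toy_map(counts * 2)
        w1 = hm.balance(m1, tol=1e-12)[0].bintable.weights
        w2 = hm.balance(m2, tol=1e-12)[0].bintable.weights
        np.testing.assert_allclose(w2, w1 / np.sqrt(2), rtol=1e-5)

    def test_row_scaling_invariance_of_balanced_matrix(self):
        """Multiplying row/column i of the counts by a positive factor leaves
        the balanced matrix unchanged (bias-removal property)."""
        rng = np.random.default_rng(3)
        counts = rng.poisson(30, (9, 9)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        # separable bias b with b[4] = 3: element (i, j) scales by b_i * b_j,
        # so the (4, 4) diagonal scales by 9
        biased = counts.copy()
        biased[4, :] *= 3.0
        biased[:, 4] *= 3.0
        b1 = hm.balance(toy_map(counts), tol=1e-13, max_iter=5000, mad_max=50)[0].dense(
            "balanced"
        )
        b2 = hm.balance(
            toy_map(np.rint(biased)), tol=1e-13, max_iter=5000, mad_max=50
        )[0].dense("balanced")
        np.testing.assert_allclose(b1, b2, rtol=2e-2)

    def test_planted_bias_recovered(self):
        """Balance weights recover the inverse of a planted separable bias."""
        layout = hm.GenomeLayout(("chrI",), (1_000_000,))
        n = 200
        rng = np.random.default_rng(8)
        bias = np.exp(rng.normal(0, 0.4, n))
        spec = SyntheticSpec(
            layout, 5000, 1_000_000, alpha=1.0, cis_fraction=1.0, bias=bias, seed=9
        )
        cmap, _ = hm.synthesize_map(spec)
        out, result = hm.balance(cmap)
        assert result.converged and result.final_variance < 1e-5
        w = out.bintable.weights
        ok = np.isfinite(w)
        r = np.corrcoef(np.log(w[ok]), -np.log(bias[ok]))[0, 1]
        assert r >= 0.99

    def test_non_convergence_is_flagged_not_raised(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, (20, 20))
        counts = np.triu(counts) + np.triu(counts, 1).T
        out, result = hm.balance(toy_map(counts), tol=1e-16, max_iter=2)
        assert not result.converged
        assert out.bintable.weights is not None


class TestExpected:
    def test_constant_diagonal_values(self):
        n = 12
        mat = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            mat[idx, idx + d] = d + 1.0
        mat = np.triu(mat) + np.triu(mat, 1).T
        m = toy_map(np.rint(mat))
        m = filter_bins(m)
        m = m.set_score("balanced", np.asarray(m.interactions.layer("count"), float))
        prof = expected(m)
        E, n_pairs = prof.cis["chrI"]
        np.testing.assert_allclose(E, np.arange(1, n + 1), rtol=1e-12)
        np.testing.assert_array_equal(n_pairs, n - np.arange(n))

    def test_mass_conservation(self, balanced_small_map):
        cmap, _ = balanced_small_map
        prof = expected(cmap)
        total = 0.0
        for chrom, (E, n_pairs) in prof.cis.items():
            ok = np.isfinite(E)
            total += (E[ok] * n_pairs[ok]).sum()
        for (c1, c2), (mean, n_pairs) in prof.trans.items():
            if np.isfinite(mean):
                total += mean * n_pairs
        w = cmap.bintable.weights
        b1, b2 = cmap.interactions.bin1_id, cmap.interactions.bin2_id
        valid = np.isfinite(w[b1]) & np.isfinite(w[b2])
        ref = np.nansum(np.asarray(cmap.interactions.layer("balanced"))[valid])
        np.testing.assert_allclose(total, ref, rtol=1e-9)

    def test_decay_recovered_within_poisson_error(self):
        layout = hm.GenomeLayout(("chrI",), (500_000,))
        spec = SyntheticSpec(layout, 5000, 2_000_000, alpha=1.0, cis_fraction=1.0, seed=13)
        cmap, _ = hm.synthesize_map(spec)
        out, _ = hm.balance(cmap)
        prof = expected(out)
        E, n_pairs = prof.cis["chrI"]
        d = np.arange(E.size)
        ok = (d >= 1) & (d <= 30)
        # E(d) ~ 1/d up to normalization: correlation in log-log near -1 slope
        slope = np.polyfit(np.log(d[ok]), np.log(E[ok]), 1)[0]
        assert abs(slope + 1.0) < 0.1


class TestDetrend:
    def test_per_diagonal_mean_oe_is_one(self, balanced_small_map):
        cmap, _ = balanced_small_map
        d = detrend(cmap)
        bt = d.bintable
        ints = d.interactions
        valid = np.isfinite(bt.weights)
        for chrom in ("chrI",):
            sl = bt.chrom_slice(chrom)
            ci = bt.layout.index(chrom)
            mask = (bt.chrom_id[ints.bin1_id] == ci) & (bt.chrom_id[ints.bin2_id] == ci)
            offs = ints.bin2_id[mask] - ints.bin1_id[mask]
            oe = np.asarray(ints.layer("oe"))[mask]
            v = valid[sl]
            n = v.size
            for dd in range(0, 20):
                pick = offs == dd
                if not pick.any():
                    continue
                n_pairs = int(v.sum()) if dd == 0 else int((v[:-dd] & v[dd:]).sum())
                mean_oe = np.nansum(oe[pick]) / n_pairs
                np.testing.assert_allclose(mean_oe, 1.0, atol=1e-9)

    def test_constant_diagonal_matrix_gives_unit_oe(self):
        n = 10
        mat = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            mat[idx, idx + d] = 8.0
        m = toy_map(np.rint(np.triu(mat) + np.triu(mat, 1).T))
        m = filter_bins(m)
        m = m.set_score("balanced", np.asarray(m.interactions.layer("count"), float))
        d = detrend(m)
        np.testing.assert_allclose(np.asarray(d.interactions.layer("oe")), 1.0, atol=1e-12)

    def test_planted_loop_bump_appears_in_oe(self):
        layout = hm.GenomeLayout(("chrI",), (400_000,))
        res = 2000
        loop = (hm.Region("chrI", 60_000, 62_000), hm.Region("chrI", 100_000, 102_000))
        spec = SyntheticSpec(
            layout, res, 2_000_000, alpha=1.0, cis_fraction=1.0,
            loops=[loop], loop_enrichment=5.0, seed=17,
        )
        cmap, _ = hm.synthesize_map(spec)
        out, _ = hm.balance(cmap)
        d = detrend(out)
        dense = d.dense("oe")
        i, j = 30, 50
        assert dense[i, j] == pytest.approx(5.0, rel=0.35)
        background = np.nanmedian(np.diagonal(dense, 20))
        assert dense[i, j] > 3 * background


class TestCorrelate:
    def test_symmetric_unit_diagonal_bounded(self, plaid_detrended):
        cmap, _ = plaid_detrended
        corr = correlate(cmap)["chrI"]
        ok = np.isfinite(corr)
        assert (corr[ok] >= -1 - 1e-12).all() and (corr[ok] <= 1 + 1e-12).all()
        np.testing.assert_allclose(corr, corr.T, equal_nan=True)
        diag = np.diagonal(corr)
        assert np.allclose(diag[np.isfinite(diag)], 1.0)

    def test_plaid_sign_structure(self, plaid_detrended):
        cmap, truth = plaid_detrended
        corr = correlate(cmap)["chrI"]
        states = truth.states
        same = np.outer(states, states) > 0
        off = ~np.eye(states.size, dtype=bool)
        within = np.nanmean(corr[same & off])
        between = np.nanmean(corr[~same])
        assert within > 0 > between

    def test_tiny_chromosome_gives_missing_block(self):
        layout = hm.GenomeLayout(("chrI",), (2000,))
        bt = hm.BinTable(layout, 1000)
        ints = hm.InteractionSet(
            np.array([0, 0]), np.array([0, 1]), {"count": np.array([3, 2])}
        )
        m = hm.ContactMap(bt, ints)
        m = filter_bins(m)
        m = m.set_score("balanced", np.asarray(m.interactions.layer("count"), float))
        d = detrend(m)
        corr = correlate(d)["chrI"]
        assert np.isnan(corr[0, 1])
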