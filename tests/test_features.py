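"""Structural annotation: compartments, insulation, loops, saddle."""

import numpy as np
import pytest

import hicmap as hm
from hicmap.balance import detrend
from hicmap.features import call_compartments, call_loops, insulation, saddle

from conftest import toy_map


def power_iteration(mat, n_iter=10_000, tol=1e-14):
    """Independent leading-eigenpair oracle by power iteration."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=mat.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    # shift to make the largest-algebraic eigenvalue dominant
    shift = np.abs(mat).sum()
    shifted = mat + shift * np.eye(mat.shape[0])
    for _ in range(n_iter):
        nv = shifted @ v
        nv /= np.linalg.norm(nv)
        if np.linalg.norm(nv - v) < tol:
            v = nv
            break
        v = nv
    lam = float(v @ mat @ v)
    return v, lam


class TestCompartments:
    def test_plaid_sign_agreement_with_planted_states(self, plaid_detrended):
        cmap, truth = plaid_detrended
        result = call_compartments(cmap, phasing_track=truth.states)
        ok = np.isfinite(result.e1)
        agree = np.mean(np.sign(result.e1[ok]) == truth.states[ok])
        assert agree >= 0.95
        assert result.phased

    def test_eigenvector_matches_power_iteration_oracle(self):
        corr = np.array(
            [
                [1.0, 0.8, -0.5, -0.4],
                [0.8, 1.0, -0.6, -0.5],
                [-0.5, -0.6, 1.0, 0.7],
                [-0.4, -0.5, 0.7, 1.0],
            ]
        )
        from hicmap.features import _power_leading_eigvec

        vec, lam = _power_leading_eigvec(corr)
        ovec, olam = power_iteration(corr)
        assert lam == pytest.approx(olam, abs=1e-8)
        sign = np.sign(vec @ ovec)
        np.testing.assert_allclose(vec, sign * ovec, atol=1e-8)

    def test_flipping_phasing_track_flips_labels(self, plaid_detrended):
        cmap, truth = plaid_detrended
        a = call_compartments(cmap, phasing_track=truth.states)
        b = call_compartments(cmap, phasing_track=-truth.states)
        ok = np.isfinite(a.e1)
        np.testing.assert_allclose(a.e1[ok], -b.e1[ok])
        assert all(
            x != y for x, y in zip(a.labels[ok], b.labels[ok]) if x and y
        )

    def test_unphased_warns_and_magnitude_is_stable(self, plaid_detrended):
        cmap, truth = plaid_detrended
        with pytest.warns(UserWarning, match="phasing"):
            raw = call_compartments(cmap)
        assert not raw.phased
        phased = call_compartments(cmap, phasing_track=truth.states)
        ok = np.isfinite(raw.e1)
        np.testing.assert_allclose(np.abs(raw.e1[ok]), np.abs(phased.e1[ok]))

    def test_small_chromosome_left_missing(self):
        m = toy_map(np.ones((5, 5)) * 4)
        out, _ = hm.balance(m)
        d = detrend(out)
        result = call_compartments(d, phasing_track=np.ones(5))
        assert np.isnan(result.e1).all()


class TestInsulation:
    def _prepare(self, cmap):
        out, _ = hm.balance(cmap)
        return out

    def test_uniform_map_has_flat_score_and_no_borders(self):
        n = 60
        mat = np.full((n, n), 20.0)
        m = self._prepare(toy_map(np.rint(np.triu(mat))))
        result = insulation(m, window=5000)
        ok = np.isfinite(result.is_track)
        assert np.nanmax(np.abs(result.is_track[ok])) < 0.05
        assert len(result.borders) == 0

    def test_two_blocks_give_minimum_at_junction(self):
        n = 40
        mat = np.zeros((n, n))
        mat[:20, :20] = 50.0
        mat[20:, 20:] = 50.0
        m = self._prepare(toy_map(np.rint(np.triu(mat))))
        result = insulation(m, window=5000, prominence=0.1)
        idx = np.nanargmin(result.is_track)
        assert idx in (19, 20)
        border_bins = [r.start // 1000 for r in result.borders.regions]
        assert any(abs(b - 20) <= 1 for b in border_bins)

    def test_planted_boundaries_recovered(self, domain_map):
        """All 8 planted boundaries found within +-1 bin, at most one
        spurious call at the default prominence."""
        cmap, truth = domain_map
        m = self._prepare(cmap)
        result = insulation(m, window=20_000)
        res = cmap.resolution
        called = np.array([r.start // res for r in result.borders.regions])
        planted = np.array([r.start // res for r in truth.boundaries.regions])
        hits = sum(np.any(np.abs(called - p) <= 1) for p in planted)
        spurious = sum(not np.any(np.abs(p - planted) <= 1) for p in called)
        assert hits == len(planted)
        assert spurious <= 1

    def test_scale_invariance_of_is(self, domain_map):
        cmap, _ = domain_map
        m = self._prepare(cmap)
        r1 = insulation(m, window=20_000)
        scaled = m.set_score(
            "balanced2", np.asarray(m.interactions.layer("balanced")) * 7.5
        )
        r2 = insulation(scaled, window=20_000, score="balanced2")
        np.testing.assert_allclose(
            r1.is_track, r2.is_track, atol=1e-9, equal_nan=True
        )

    def test_window_validation(self, domain_map):
        cmap, _ = domain_map
        m = self._prepare(cmap)
        with pytest.raises(ValueError):
            insulation(m, window=3000)  # not a multiple of 2 kb resolution
        with pytest.raises(ValueError):
            insulation(m, window=2000)  # single-bin diamond


@pytest.fixture(scope="module")
def loop_oe(loop_map):
    cmap, truth = loop_map
    out, _ = hm.balance(cmap)
    return detrend(out), truth


class TestLoops:
    def test_flat_oe_map_has_zero_loops(self):
        n = 80
        mat = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            mat[idx, idx + d] = 30.0
        m = toy_map(np.rint(np.triu(mat)))
        out, _ = hm.balance(m)
        d = detrend(out)
        loops = call_loops(d, band=(5000, 40_000))
        assert len(loops) == 0

    def test_planted_loops_recovered(self, loop_oe):
        cmap, truth = loop_oe
        res = cmap.resolution
        loops = call_loops(cmap, band=(10_000, 110_000))
        called = {
            (r1.start // res, r2.start // res)
            for r1, r2 in zip(loops.regions, loops.regions2)
        }
        planted = [
            (r1.start // res, r2.start // res)
            for r1, r2 in zip(truth.loops.regions, truth.loops.regions2)
        ]
        hits = sum(
            any(abs(i - a) <= 1 and abs(j - b) <= 1 for a, b in called)
            for i, j in planted
        )
        assert hits / len(planted) >= 0.8

    def test_detection_count_monotone_in_rho_min(self, loop_oe):
        cmap, _ = loop_oe
        counts = [
            len(call_loops(cmap, band=(10_000, 110_000), rho_min=r))
            for r in (0.2, 0.35, 0.5, 0.7)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recall_increases_with_enrichment(self):
        from hicmap.synthetic import SyntheticSpec

        layout = hm.GenomeLayout(("chrI",), (400_000,))
        res = 2000
        loops = [
            (
                hm.Region("chrI", a * res, (a + 1) * res),
                hm.Region("chrI", (a + 25) * res, (a + 26) * res),
            )
            for a in (20, 60, 100, 140)
        ]
        recalls = []
        for eta in (2.0, 5.0, 10.0):
            spec = SyntheticSpec(
                layout, res, 1_500_000, alpha=1.0, cis_fraction=1.0,
                loops=loops, loop_enrichment=eta, seed=91,
            )
            cmap, truth = hm.synthesize_map(spec)
            out, _ = hm.balance(cmap)
            d = detrend(out)
            found = call_loops(d, band=(30_000, 70_000))
            called = {
                (r1.start // res, r2.start // res)
                for r1, r2 in zip(found.regions, found.regions2)
            }
            planted = [
                (r1.start // res, r2.start // res)
                for r1, r2 in zip(truth.loops.regions, truth.loops.regions2)
            ]
            recalls.append(
                sum(
                    any(abs(i - a) <= 1 and abs(j - b) <= 1 for a, b in called)
                    for i, j in planted
                )
            )
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] >= 3


class TestSaddle:
    def test_two_group_saddle_on_plaid(self, plaid_detrended):
        cmap, truth = plaid_detrended
        comp = call_compartments(cmap, phasing_track=truth.states)
        sad = saddle(cmap, comp.e1, q=2)
        s = sad.s_matrix
        assert s[0, 0] > s[0, 1] and s[1, 1] > s[0, 1]
        assert sad.corner_summary["AA"] > sad.corner_summary["AB"]
        assert sad.corner_summary["BB"] > sad.corner_summary["AB"]

    def test_unit_oe_gives_unit_saddle(self):
        n = 50
        mat = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            mat[idx, idx + d] = 40.0
        m = toy_map(np.rint(np.triu(mat)))
        out, _ = hm.balance(m)
        d = detrend(out)
        rng = np.random.default_rng(5)
        e1 = rng.normal(size=n)
        sad = saddle(d, e1, q=4)
        ok = np.isfinite(sad.s_matrix)
        np.testing.assert_allclose(sad.s_matrix[ok], 1.0, atol=1e-9)

    def test_symmetry_and_min_s_filter(self, plaid_detrended):
        cmap, truth = plaid_detrended
        comp = call_compartments(cmap, phasing_track=truth.states)
        sad = saddle(cmap, comp.e1, q=5, min_s=500_000)
        np.testing.assert_allclose(sad.s_matrix, sad.s_matrix.T, equal_nan=True)
        # only pairs >= min_s contribute
        ints = cmap.interactions
        bt = cmap.bintable
        sep = np.abs(bt.start[ints.bin2_id] - bt.start[ints.bin1_id])
        cis = bt.chrom_id[ints.bin1_id] == bt.chrom_id[ints.bin2_id]
        n_eligible = int(
            (cis & (sep >= 500_000) & np.isfinite(np.asarray(ints.layer("oe")))).sum()
        )
        assert sad.counts.sum() <= 2 * n_eligible  # symmetrized tally

    def test_permutation_null_destroys_corner_contrast(self, plaid_detrended):
        """The AA/AB contrast exceeds the 95th percentile of 100 E1
        permutations."""
        cmap, truth = plaid_detrended
        comp = call_compartments(cmap, phasing_track=truth.states)
        observed = saddle(cmap, comp.e1, q=2)
        contrast = abs(
            observed.corner_summary["AA"] - observed.corner_summary["AB"]
        )
        rng = np.random.default_rng(101)
        e1 = comp.e1
        ok = np.isfinite(e1)
        null = []
        for _ in range(100):
            perm = e1.copy()
            perm[ok] = rng.permutation(e1[ok])
            sad = saddle(cmap, perm, q=2)
            null.append(abs(sad.corner_summary["AA"] - sad.corner_summary["AB"]))
        assert contrast > np.percentile(null, 95)

    def test_too_few_bins_rejected(self, plaid_detrended):
        cmap, _ = plaid_detrended
        with pytest.raises(ValueError):
            saddle(cmap, np.full(cmap.bintable.n_bins, np.nan), q=2)

    def test_default_quantile_count(self, plaid_detrended):
        cmap, truth = plaid_detrended
        comp = call_compartments(cmap, phasing_track=truth.states)
        sad = saddle(cmap, comp.e1)
        assert sad.q == 38
        assert sad.s_matrix.shape == (38, 38)
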