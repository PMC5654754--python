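"""Adaptive top-k combination core: scores, null resampling, MinP machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adabf.artp import (
    CorrelationMatrix,
    NullEnsemble,
    artp_pvalue,
    genotype_correlation,
    resample_null,
    sequential_test,
    summary_scores,
)
from adabf.bayes import ADABF_PRIOR, wakefield_log_bf
from adabf.pervariant import MISSING, EffectSummary


class TestGenotypeCorrelation:
    def test_identical_columns_correlate_fully(self, rng):
        g = rng.integers(0, 3, size=(50, 1))
        R = genotype_correlation(np.hstack([g, g, 2 - g]), founder_only=False)
        assert R.matrix[0, 1] == pytest.approx(1.0)
        assert R.matrix[0, 2] == pytest.approx(-1.0)

    def test_complete_data_equals_numpy_corrcoef(self, pool, rng):
        idx = rng.choice(pool.H, size=400, replace=False)
        common = np.where(pool.mafs > 0.05)[0][:6]
        G = pool.haplotypes[idx][:, common] + pool.haplotypes[rng.choice(pool.H, 400)][:, common]
        R = genotype_correlation(G, founder_only=False)
        np.testing.assert_allclose(R.matrix, np.corrcoef(G, rowvar=False), atol=1e-12)

    def test_independent_columns_nearly_uncorrelated(self, rng):
        G = rng.binomial(2, 0.3, size=(10_000, 2))
        R = genotype_correlation(G, founder_only=False)
        assert abs(R.matrix[0, 1]) < 0.05

    def test_pairwise_missing_matches_bruteforce_and_stays_psd(self, rng):
        G = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
        mask = rng.random(G.shape) < 0.25
        G[mask] = MISSING
        R = genotype_correlation(G, founder_only=False)
        # brute force pairwise-complete correlation before PSD repair
        Gnan = G.copy()
        Gnan[Gnan == MISSING] = np.nan
        for i, j in itertools.combinations(range(5), 2):
            ok = ~np.isnan(Gnan[:, i]) & ~np.isnan(Gnan[:, j])
            raw = np.corrcoef(Gnan[ok, i], Gnan[ok, j])[0, 1]
            assert R.matrix[i, j] == pytest.approx(raw, abs=0.05)  # repair may nudge
        assert np.linalg.eigvalsh(R.matrix).min() > -1e-9
        np.testing.assert_allclose(np.diag(R.matrix), 1.0)

    def test_monomorphic_column_rejected(self):
        G = np.column_stack([np.zeros(20), np.arange(20) % 3])
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_correlation(G, founder_only=False)


class TestSummaryScores:
    def test_worked_examples(self):
        curve = summary_scores(np.array([2.0, 1.0, -1.0]))
        assert curve.s_k.tolist() == [2.0, 3.0, 2.0]  # not monotone: negative scores
        equal = summary_scores(np.full(4, 0.7))
        np.testing.assert_allclose(equal.s_k, 0.7 * np.arange(1, 5))
        assert equal.order.tolist() == [0, 1, 2, 3]  # ties by ascending index

    def test_matches_exhaustive_subset_oracle(self, rng):
        scores = rng.normal(size=8)
        curve = summary_scores(scores)
        for k in range(1, 9):
            best = max(sum(c) for c in itertools.combinations(scores, k))
            assert curve.s_k[k - 1] == pytest.approx(best)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            summary_scores(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            summary_scores(np.array([]))

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False, width=32), min_size=1, max_size=30)
    )
    @settings(deadline=None, derandomize=True)
    def test_curve_invariants_hold_for_arbitrary_scores(self, scores):
        """S_1 is the max, S_L the total, and each increment S_k - S_(k-1)
        is a non-increasing sequence (scores are added in sorted order)."""
        scores = np.asarray(scores, dtype=float)
        curve = summary_scores(scores)
        assert curve.s_k[0] == max(scores)
        assert curve.s_k[-1] == pytest.approx(scores.sum(), abs=1e-6)
        increments = np.diff(np.concatenate([[0.0], curve.s_k]))
        assert np.all(np.diff(increments) <= 1e-9)
        assert sorted(curve.order.tolist()) == list(range(len(scores)))


class TestResampleNull:
    def test_marginal_variances(self):
        v = np.array([0.5, 0.01, 2.0])
        ens = resample_null(v, np.eye(3), B=100_000, seed=5)
        np.testing.assert_allclose(ens.betas.var(axis=0), v, rtol=0.03)

    def test_cross_correlation(self):
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        ens = resample_null(np.array([0.3, 0.7]), R, B=100_000, seed=6)
        assert np.corrcoef(ens.betas.T)[0, 1] == pytest.approx(0.9, abs=0.01)

    def test_single_draw_deterministic(self):
        a = resample_null(np.array([1.0]), np.eye(1), B=1, seed=9)
        b = resample_null(np.array([1.0]), np.eye(1), B=1, seed=9)
        assert a.betas.shape == (1, 1)
        np.testing.assert_array_equal(a.betas, b.betas)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            resample_null(np.array([-1.0]), np.eye(1), B=10)
        with pytest.raises(ValueError):
            resample_null(np.array([1.0]), np.eye(1), B=0)


def _oracle_artp(observed_scores, null_betas, var_hats, w):
    """Plain-loop re-implementation of the MinP adjustment (the oracle)."""
    B, L = null_betas.shape

    def top_k_sums(scores):
        s = sorted(scores, reverse=True)
        return [sum(s[: k + 1]) for k in range(L)]

    S_obs = top_k_sums(list(observed_scores))
    S_null = [
        top_k_sums([float(wakefield_log_bf(null_betas[b, l], var_hats[l], w))
                    for l in range(L)])
        for b in range(B)
    ]
    per_k = [sum(S_null[b][k] >= S_obs[k] for b in range(B)) / B for k in range(L)]
    minp = min(per_k)
    minp_b = []
    for b in range(B):
        pk = [sum(S_null[b2][k] >= S_null[b][k] for b2 in range(B)) / B for k in range(L)]
        minp_b.append(min(pk))
    count = sum(m <= minp for m in minp_b)
    return minp, max(count, 1) / B, count == 0


class TestArtpPvalue:
    @pytest.mark.parametrize("L,B,seed", [(2, 5, 0), (3, 7, 1), (3, 10, 2), (2, 10, 3)])
    def test_exact_match_with_enumeration_oracle(self, L, B, seed):
        rng = np.random.default_rng(seed)
        var = rng.uniform(0.05, 0.5, size=L)
        betas_obs = rng.normal(0, np.sqrt(var))
        obs_scores = wakefield_log_bf(betas_obs, var, 0.04)
        ens = resample_null(var, np.eye(L), B=B, seed=seed + 100)
        res = artp_pvalue(summary_scores(obs_scores), ens, prior=ADABF_PRIOR)
        minp, adj, floor = _oracle_artp(obs_scores, ens.betas, var, 0.04)
        assert res.min_p == pytest.approx(minp)
        assert res.adjusted_p == pytest.approx(adj)
        assert res.floor == floor

    def test_dominant_observation_hits_floor(self):
        var = np.array([0.1, 0.1])
        ens = resample_null(var, np.eye(2), B=50, seed=3)
        obs = summary_scores(np.array([50.0, 40.0]))
        res = artp_pvalue(obs, ens, prior=ADABF_PRIOR)
        assert res.adjusted_p == pytest.approx(1 / 50)
        assert res.floor

    def test_permuting_variants_leaves_pvalues_unchanged(self, rng):
        L = 6
        var = rng.uniform(0.05, 0.5, size=L)
        betas = rng.normal(0, np.sqrt(var))
        perm = rng.permutation(L)
        for transform in ("adabf", "ada"):
            if transform == "adabf":
                obs = wakefield_log_bf(betas, var, 0.04)
            else:
                obs = -np.log(stats.chi2.sf(betas**2 / var, 1))
            ens = resample_null(var, np.eye(L), B=200, seed=8)
            r1 = artp_pvalue(summary_scores(obs), ens, transform=transform)
            ens_p = NullEnsemble(betas=ens.betas[:, perm], var_hats=var[perm], R=np.eye(L))
            r2 = artp_pvalue(summary_scores(obs[perm]), ens_p, transform=transform)
            assert r1.min_p == r2.min_p and r1.adjusted_p == r2.adjusted_p

    def test_affine_score_transform_invariance(self, rng):
        """Order-preserving affine rescaling of all scores (observed and
        null alike) cannot change the rank-based adjusted P."""
        from adabf.artp import minp_adjust

        L, B = 5, 100
        obs = rng.normal(size=L)
        null = rng.normal(size=(B, L))
        base = minp_adjust(summary_scores(obs).s_k, null)
        scaled = minp_adjust(summary_scores(2.0 + 3.0 * obs).s_k, 2.0 + 3.0 * null)
        np.testing.assert_array_equal(base[0], scaled[0])  # per-k P-values
        assert base[1:] == scaled[1:]


def _effects(betas, var):
    betas, var = np.atleast_1d(betas), np.atleast_1d(var)
    stat = betas**2 / var
    return EffectSummary(
        variant_ids=np.array([f"v{i}" for i in range(len(betas))], dtype=object),
        beta_hat=betas, var_hat=var, statistic=stat,
        p_value=stats.chi2.sf(stat, 1),
    )


class TestSequentialTest:
    def test_null_region_stops_at_first_stage(self):
        eff = _effects(np.zeros(3), np.full(3, 0.2))
        res = sequential_test(eff, np.eye(3), seed=4)
        assert res.b_used == 100
        assert res.adjusted_p > 0.1

    def test_strong_signal_escalates_with_loop_invariant(self):
        eff = _effects(np.array([2.5, 0.1]), np.array([0.05, 0.2]))
        res = sequential_test(eff, np.eye(2), seed=4, b_max=10_000)
        assert res.b_used > 100
        assert res.adjusted_p <= 10 / res.b_used or res.b_used == 10_000

    def test_deterministic_under_fixed_seed(self):
        eff = _effects(np.array([0.9, -0.4, 0.2]), np.array([0.1, 0.2, 0.15]))
        a = sequential_test(eff, np.eye(3), seed=11, b_max=10_000)
        b = sequential_test(eff, np.eye(3), seed=11, b_max=10_000)
        assert a.adjusted_p == b.adjusted_p and a.b_used == b.b_used
        np.testing.assert_array_equal(a.per_k_p, b.per_k_p)

    def test_single_variant_reduces_to_wald_test(self):
        """With L = 1 the adjusted P is a Monte-Carlo single-variant test:
        ADA and ADABF agree exactly (both monotone in |beta|) and converge
        to the analytic chi-square P."""
        beta, var = 0.45, 0.04
        eff = _effects(np.array([beta]), np.array([var]))
        p_analytic = float(stats.chi2.sf(beta**2 / var, 1))
        B = 40_000
        r_ada = sequential_test(eff, np.eye(1), transform="ada", prior=None,
                                b_min=B, b_max=B, seed=21)
        r_bf = sequential_test(eff, np.eye(1), transform="adabf", seed=21,
                               b_min=B, b_max=B)
        assert r_ada.adjusted_p == r_bf.adjusted_p
        mc_sd = np.sqrt(p_analytic * (1 - p_analytic) / B)
        assert abs(r_ada.adjusted_p - p_analytic) < 4 * mc_sd

    def test_refuses_dropped_variants(self):
        eff = _effects(np.array([np.nan]), np.array([np.nan]))
        with pytest.raises(ValueError):
            sequential_test(eff, np.eye(1), seed=0)


def test_correlation_matrix_validation():
    with pytest.raises(ValueError):
        CorrelationMatrix(np.array([[1.0, 0.5], [0.2, 1.0]]))
    with pytest.raises(ValueError):
        CorrelationMatrix(np.array([[2.0, 0.0], [0.0, 1.0]]))
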