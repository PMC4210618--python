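"""The differential-variability test: deviations, pipeline, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diffvar import (
    DesignSpec,
    MethylMatrix,
    ModerationParams,
    SimConfig,
    compute_deviations,
    diff_methylation,
    diffvar,
    dm_dv_overlap,
    method_pvalues,
    significant_dm,
    significant_dv,
    simulate_dataset,
    two_group_design,
    variability_ratio,
)
from diffvar.core import diffvar_pvalues


def _matrix(values, scale="M"):
    values = np.atleast_2d(np.asarray(values, float))
    return MethylMatrix(
        values=values,
        probe_ids=[f"cg{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        scale=scale,
    )


class TestDeviations:
    def test_group_leverage_factor(self):
        design = two_group_design(50, 50)
        dev = compute_deviations(np.zeros((1, 100)), design)
        np.testing.assert_allclose(dev.leverage_factor, 50 / 51)

    def test_hand_computed_unequal_groups(self):
        """Groups {0,2} and {5,5,5,5}: h = 1/2 and 1/4."""
        design = two_group_design(2, 4)
        y = np.array([[0.0, 2, 5, 5, 5, 5]])
        dev = compute_deviations(y, design, method="abs")
        np.testing.assert_allclose(dev.values[0, :2], [1 * 2 / 3, 1 * 2 / 3])
        np.testing.assert_allclose(dev.values[0, 2:], 0.0, atol=1e-14)
        sq = compute_deviations(y, design, method="sq")
        np.testing.assert_allclose(sq.values[0, :2], [1 * 2 / 3, 1 * 2 / 3])

    def test_constant_feature_zero_row(self):
        dev = compute_deviations(np.full((1, 8), 3.7), two_group_design(4, 4))
        np.testing.assert_allclose(dev.values, 0.0, atol=1e-14)

    def test_singleton_group_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = 1.0
        X[1:, 1] = 1.0
        design = DesignSpec(design=X, coef=np.array([-1.0, 1.0]))
        with pytest.raises(ValueError, match="leverage"):
            compute_deviations(np.zeros((1, 4)), design)


class TestDiffVarPipeline:
    def test_group_swap_negates_effect(self, rng):
        values = rng.standard_normal((50, 10))
        values[:, 5:] *= 3.0
        m1 = _matrix(values)
        m2 = _matrix(np.hstack([values[:, 5:], values[:, :5]]))
        d = two_group_design(5, 5)
        r1 = diffvar(m1, d)
        r2 = diffvar(m2, d)
        np.testing.assert_allclose(r1["effect"], -r2["effect"], atol=1e-12)
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], atol=1e-12)

    def test_affine_invariance_of_abs_pvalues(self, rng):
        """p is unchanged under M -> aM + b (deviations scale by |a|)."""
        values = rng.standard_normal((100, 16))
        d = two_group_design(8, 8)
        p1 = diffvar_pvalues(values, d, method="abs")
        p2 = diffvar_pvalues(-1.7 * values + 0.4, d, method="abs")
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_balanced_design_leverage_constant_cancels(self, rng):
        """For balanced groups, scaling deviations by any constant leaves p fixed."""
        values = rng.standard_normal((80, 12))
        d = two_group_design(6, 6)
        dev = compute_deviations(values, d)
        assert np.ptp(dev.leverage_factor) == pytest.approx(0.0)
        from diffvar.core import _moderated_pipeline_nobh

        p_scaled = _moderated_pipeline_nobh(dev.values, d)[3]
        p_unscaled = _moderated_pipeline_nobh(dev.values / dev.leverage_factor, d)[3]
        np.testing.assert_allclose(p_scaled, p_unscaled, atol=1e-10)

    def test_single_feature_fallback_is_classical_t(self):
        """G=1 falls back to the unmoderated t on leverage-scaled deviations."""
        m = _matrix([[-1.0, 0, 1, -10, 0, 10]])
        d = two_group_design(3, 3)
        res = diffvar(m, d)
        assert res["effect"].iloc[0] > 0  # group 2 has the larger spread
        z = compute_deviations(m.values, d).values
        oracle = stats.ttest_ind(z[0, 3:], z[0, :3], equal_var=True)
        assert res["t"].iloc[0] == pytest.approx(oracle.statistic, abs=1e-10)
        assert res["p_value"].iloc[0] == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_beta_input_auto_logit(self, rng):
        beta = rng.uniform(0.05, 0.95, (20, 8))
        d = two_group_design(4, 4)
        from diffvar import beta_to_m

        res_beta = diffvar(_matrix(beta, scale="beta"), d)
        res_m = diffvar(beta_to_m(_matrix(beta, scale="beta")), d)
        np.testing.assert_allclose(res_beta["p_value"], res_m["p_value"], atol=1e-12)

    def test_null_pvalues_near_uniform(self):
        """Raw p under the hierarchical null stays close to U(0,1)."""
        for seed in range(5):
            rng = np.random.default_rng(np.random.SeedSequence(2024, spawn_key=(seed,)))
            m, d, _ = simulate_dataset(SimConfig(), rng)
            p = method_pvalues("diffvar_abs", m.values, d)
            ks = stats.kstest(p, "uniform").statistic
            assert ks < 0.02

    def test_outliers_not_preferentially_top_ranked(self):
        """Outlier-bearing nulls sit near the middle of the ranking, not the top."""
        g = 10_000
        ranks, top200 = [], []
        for seed in range(5):
            rng = np.random.default_rng(np.random.SeedSequence(11, spawn_key=(seed,)))
            m, d, truth = simulate_dataset(SimConfig(n_outliers=200), rng)
            p = method_pvalues("diffvar_abs", m.values, d)
            rank_of = np.argsort(np.argsort(p, kind="stable")) + 1
            ranks.append(rank_of[truth.has_outlier])
            order = np.argsort(p, kind="stable")
            top200.append(truth.has_outlier[order[:200]].sum())
        mean_rank = np.concatenate(ranks).mean()
        assert abs(mean_rank - g / 2) < 0.10 * g
        assert np.mean(top200) < 20


class TestVariabilityRatio:
    def test_direction_and_ratio(self):
        rng = np.random.default_rng(3)
        y = np.vstack([rng.standard_normal(8) * np.sqrt(5), rng.standard_normal(8)]).reshape(1, 16)
        masks = {"A": np.arange(16) < 8, "B": np.arange(16) >= 8}
        ratio, direction, variances = variability_ratio(y, masks)
        vA = y[0, :8].var(ddof=1)
        vB = y[0, 8:].var(ddof=1)
        assert ratio[0] == pytest.approx(max(vA, vB) / min(vA, vB))
        assert direction[0] == ("A" if vA > vB else "B")
        assert ratio[0] >= 1

    def test_equal_variances_unit_ratio(self):
        y = np.array([[0.0, 1, 2, 0, 1, 2]])
        masks = {"A": np.arange(6) < 3, "B": np.arange(6) >= 3}
        ratio, _, _ = variability_ratio(y, masks)
        assert ratio[0] == pytest.approx(1.0)

    def test_both_zero_defined_as_one(self):
        y = np.full((1, 6), 2.0)
        masks = {"A": np.arange(6) < 3, "B": np.arange(6) >= 3}
        ratio, _, _ = variability_ratio(y, masks)
        assert ratio[0] == 1.0


class TestSignificanceFilters:
    def _dv_frame(self, adj_p, var_ratio):
        return pd.DataFrame(
            {
                "adj_p_value": adj_p,
                "var_ratio": var_ratio,
                "more_variable_in": ["g2"] * len(adj_p),
            }
        )

    def test_dv_threshold_boundaries(self):
        res = self._dv_frame([0.01, 0.04, 0.06], [4.9, 6.0, 10.0])
        sig = significant_dv(res, fdr=0.05, ratio=5.0)
        assert list(sig.index) == [1]
        assert sig.attrs["direction_counts"] == {"g2": 1}

    def test_dv_empty(self):
        sig = significant_dv(self._dv_frame([], []))
        assert len(sig) == 0 and sig.attrs["direction_counts"] == {}

    def test_dm_threshold_boundaries(self):
        res = pd.DataFrame({"adj_p_value": [0.01, 0.01], "delta_beta": [0.09, -0.25]})
        sig = significant_dm(res, fdr=0.05, min_delta_beta=0.1)
        assert list(sig.index) == [1]

    def test_dm_empty(self):
        assert len(significant_dm(pd.DataFrame({"adj_p_value": [], "delta_beta": []}))) == 0


class TestDiffMethylation:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        half = rng.standard_normal((30, 5))
        m = _matrix(np.hstack([half, half]))
        res = diff_methylation(m, two_group_design(5, 5))
        np.testing.assert_allclose(res["effect"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], 1.0, atol=1e-10)

    def test_location_shift_recovered(self, rng):
        base = rng.standard_normal((40, 6)) * 0.01
        shifted = np.hstack([base[:, :3], base[:, 3:] + 1.0])
        res = diff_methylation(_matrix(shifted), two_group_design(3, 3))
        np.testing.assert_allclose(res["effect"], 1.0, atol=0.05)

    def test_unmoderated_matches_classical_t(self, rng):
        """Forcing d0=0 reproduces the ordinary pooled two-sample t."""
        values = rng.standard_normal((200, 14)) + np.linspace(-2, 2, 200)[:, None]
        m = _matrix(values)
        d = two_group_design(7, 7)
        res = diff_methylation(m, d, prior=ModerationParams(0.0, 1.0))
        oracle = stats.ttest_ind(values[:, 7:], values[:, :7], axis=1, equal_var=True)
        np.testing.assert_allclose(res["p_value"], oracle.pvalue, atol=1e-10)


class TestOverlapCurve:
    def test_identical_rankings_identity(self):
        feats = [f"f{i}" for i in range(100)]
        out = dm_dv_overlap(feats, feats, top_n=20, n_random=5, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out["overlap"], np.arange(1, 21))

    def test_disjoint_top_lists(self):
        feats = [f"f{i}" for i in range(100)]
        out = dm_dv_overlap(feats, feats[::-1], top_n=10, n_random=5, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out["overlap"], 0)

    def test_random_baseline_matches_hypergeometric_mean(self):
        """Random-pair overlap at rank k has expectation ~ k^2 / U."""
        feats = [f"f{i}" for i in range(500)]
        rng = np.random.default_rng(7)
        out = dm_dv_overlap(feats, list(rng.permutation(feats)), top_n=50, n_random=400, rng=rng)
        assert out["random_median"].iloc[-1] == pytest.approx(50 * 50 / 500, abs=2.0)

    def test_top_n_exceeding_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            dm_dv_overlap(["a", "b"], ["b", "a"], top_n=5)
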