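"""Surrogate training: ANOVA routing, EWAS ranking, penalised fits and
validation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dnamcvd.io import BetaMatrix
from dnamcvd.simulate import MarkerSpec, SimulationConfig, simulate_cohort
from dnamcvd.surrogate import (SurrogateRegression, TrainConfig, centre_anova,
                               ewas_rank, fit_lasso_surrogate,
                               fit_mixed_lasso_surrogate, lasso_kkt_violation,
                               meta_analyse_correlations, train_surrogate,
                               validate_surrogate)


def lasso_fixture(seed, n=120, p=15, noise=0.3, n_groups=None):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(0, 1, (n, p)),
                     columns=[f"cg{j:03d}" for j in range(p)])
    covars = pd.DataFrame({"age": rng.uniform(35, 75, n),
                           "sex": rng.choice(["female", "male"], n)})
    w = np.zeros(p)
    w[:min(p, 4)] = [1.2, -1.0, 0.8, -0.6][:min(p, 4)]
    y = (0.5 + X.to_numpy() @ w + 0.01 * covars["age"].to_numpy()
         + noise * rng.standard_normal(n))
    centre = pd.Series([f"C{i % n_groups}" for i in range(n)]) if n_groups else None
    return y, X, covars, centre


class TestCentreAnova:
    def test_equal_group_means_give_null_f(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        centre = np.array(["A"] * 3 + ["B"] * 3)
        f, p = centre_anova(y, centre)
        assert f == 0.0 and p == 1.0

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        y = np.concatenate([a, b])
        centre = np.array(["A"] * 20 + ["B"] * 25)
        f, p_f = centre_anova(y, centre)
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_hand_sum_of_squares_fixture(self):
        # groups {1,2,3} and {4,5,6}: SSB = 13.5 (df 1), SSW = 4 (df 4)
        f, _ = centre_anova(np.array([1, 2, 3, 4, 5, 6.0]),
                            np.array(["A"] * 3 + ["B"] * 3))
        assert f == pytest.approx(13.5, rel=1e-12)

    def test_single_centre_rejected(self):
        with pytest.raises(ValueError, match="2 centres"):
            centre_anova(np.arange(4.0), np.array(["A"] * 4))


class TestEwasRank:
    def make(self, seed=0, n=300, p=201):
        rng = np.random.default_rng(seed)
        bm = BetaMatrix(pd.DataFrame(rng.uniform(0, 1, (n, p)),
                                     index=[f"S{i}" for i in range(n)],
                                     columns=[f"cg{j:05d}" for j in range(p)]))
        covars = pd.DataFrame({"age": rng.uniform(35, 75, n),
                               "sex": rng.choice(["female", "male"], n)})
        return rng, bm, covars

    def test_planted_probe_ranks_first(self):
        rng, bm, covars = self.make()
        noise_sd = 0.2
        y = 10 * noise_sd * bm.data["cg00100"].to_numpy() \
            + noise_sd * rng.standard_normal(300)
        res = ewas_rank(bm, y, covars, top_fraction=0.01)
        assert res.ranked_probes[0] == "cg00100"
        assert "cg00100" in res.top_probes

    def test_top_fraction_one_returns_all_ranked(self):
        rng, bm, covars = self.make()
        y = rng.standard_normal(300)
        res = ewas_rank(bm, y, covars, top_fraction=1.0)
        assert len(res.top_probes) == 201
        assert sorted(res.ranked_probes) == sorted(bm.probe_ids)

    def test_ceil_arithmetic_for_top_count(self):
        rng = np.random.default_rng(1)
        bm = BetaMatrix(pd.DataFrame(rng.uniform(0, 1, (30, 1000)),
                                     columns=[f"cg{j:05d}" for j in range(1000)]))
        covars = pd.DataFrame({"age": rng.uniform(35, 75, 30),
                               "sex": rng.choice(["female", "male"], 30)})
        res = ewas_rank(bm, rng.standard_normal(30), covars, top_fraction=0.01)
        assert len(res.top_probes) == 10

    def test_invalid_fraction(self):
        _, bm, covars = self.make(n=20, p=5)
        with pytest.raises(ValueError, match="top_fraction"):
            ewas_rank(bm, np.zeros(20), covars, top_fraction=0.0)

    def test_ranking_invariant_to_affine_rescaling(self):
        rng, bm, covars = self.make(seed=2, n=100, p=50)
        y = rng.standard_normal(100)
        a = ewas_rank(bm, y, covars, top_fraction=0.1)
        b = ewas_rank(bm, 3.0 * y - 7.0, covars, top_fraction=0.1)
        assert a.ranked_probes == b.ranked_probes


class TestLassoSurrogate:
    def test_lambda_above_max_zeroes_all_weights(self):
        y, X, covars, _ = lasso_fixture(0)
        # lambda_max from the partialled-out standardised problem
        C = np.column_stack([np.ones(len(y)), covars["age"],
                             (covars["sex"] == "male").astype(float)])
        proj = C @ np.linalg.pinv(C)
        ytil = y - proj @ y
        Xtil = X.to_numpy() - proj @ X.to_numpy()
        Xs = (Xtil - Xtil.mean(0)) / Xtil.std(0)
        lam_max = np.max(np.abs(Xs.T @ ytil)) / len(y)
        m = fit_lasso_surrogate(y, X, covars, lambda_grid=[lam_max * 1.0001])
        assert (m.probe_weights == 0).all()
        m2 = fit_lasso_surrogate(y, X, covars, lambda_grid=[lam_max * 0.95])
        assert (m2.probe_weights != 0).any()

    def test_zero_penalty_matches_ols(self):
        y, X, covars, _ = lasso_fixture(1, n=20, p=3, noise=0.1)
        m = fit_lasso_surrogate(y, X, covars, lambda_grid=[0.0])
        D = np.column_stack([np.ones(20), X.to_numpy(), covars["age"],
                             (covars["sex"] == "male").astype(float)])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        np.testing.assert_allclose(m.probe_weights, beta[1:4], atol=1e-6)
        assert m.intercept == pytest.approx(beta[0], abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_conditions_hold_at_solution(self, seed):
        y, X, covars, _ = lasso_fixture(seed)
        m = fit_lasso_surrogate(y, X, covars, seed=seed)
        assert lasso_kkt_violation(m, y, X, covars) < 1e-6

    def test_active_set_shrinks_with_penalty(self):
        y, X, covars, _ = lasso_fixture(3)
        lams = np.logspace(-3, 0, 12)
        nnz = [fit_lasso_surrogate(y, X, covars, lambda_grid=[l]).n_probes_nonzero
               for l in lams]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_degenerate_inputs_rejected(self):
        y, X, covars, _ = lasso_fixture(0, n=8)
        with pytest.raises(ValueError, match="cv_folds"):
            fit_lasso_surrogate(y, X, covars, cv_folds=10)
        y2, X2, covars2, _ = lasso_fixture(0)
        with pytest.raises(ValueError, match="constant"):
            fit_lasso_surrogate(np.ones(len(y2)), X2, covars2)


class TestMixedLassoSurrogate:
    @pytest.mark.parametrize("seed", [1, 3, 4])
    def test_reduces_to_lasso_without_centre_variance(self, seed):
        """With no planted centre effect and the variance estimate on the
        boundary, the mixed fit must coincide with the plain LASSO."""
        y, X, covars, centre = lasso_fixture(seed, n=240, p=30, n_groups=6)
        plain = fit_lasso_surrogate(y, X, covars, seed=0)
        mixed = fit_mixed_lasso_surrogate(y, X, covars, centre, seed=0)
        assert mixed.sigma2_between == 0.0  # premise: ML estimate on boundary
        assert set(plain.probe_weights[plain.probe_weights != 0].index) \
            == set(mixed.probe_weights[mixed.probe_weights != 0].index)
        np.testing.assert_allclose(mixed.probe_weights, plain.probe_weights,
                                   atol=1e-4)

    def test_objective_non_increasing(self):
        y, X, covars, centre = lasso_fixture(2, n=240, p=30, n_groups=6)
        rng = np.random.default_rng(2)
        offs = {f"C{g}": o for g, o in enumerate(rng.normal(0, 0.5, 6))}
        y = y + centre.map(offs).to_numpy()
        m = fit_mixed_lasso_surrogate(y, X, covars, centre, seed=0)
        obj = np.array(m.objective_path)
        assert np.all(np.diff(obj) <= 1e-10)

    def test_recovers_planted_centre_variance(self):
        rng = np.random.default_rng(0)
        n, p = 1200, 20
        X = pd.DataFrame(rng.uniform(0, 1, (n, p)),
                         columns=[f"cg{j:03d}" for j in range(p)])
        covars = pd.DataFrame({"age": rng.uniform(35, 75, n),
                               "sex": rng.choice(["female", "male"], n)})
        centre = pd.Series(rng.choice(["A", "B", "C"], n))
        w = np.zeros(p); w[:3] = [1.0, -0.8, 0.6]
        y = (X.to_numpy() @ w + centre.map({"A": -1.0, "B": 0.0, "C": 1.0}).to_numpy()
             + 0.4 * rng.standard_normal(n))
        m = fit_mixed_lasso_surrogate(y, X, covars, centre, seed=0)
        planted = np.var([-1.0, 0.0, 1.0])
        assert abs(m.sigma2_between - planted) < 0.3 * planted

    def test_single_centre_rejected(self):
        y, X, covars, _ = lasso_fixture(0)
        with pytest.raises(ValueError, match="2 centres"):
            fit_mixed_lasso_surrogate(y, X, covars, pd.Series(["C"] * len(y)))


class TestThreeStepTraining:
    def test_routes_to_mixed_with_planted_centre_offsets(self, planted_cohort):
        bm, pheno, _ = planted_cohort
        model = train_surrogate("glucose", bm, pheno,
                                TrainConfig(top_fraction=0.05, seed=0))
        assert model.model_type == "mixed_lasso"
        assert model.anova_p < 0.05
        assert model.sigma2_between is not None and model.sigma2_between >= 0

    def test_routes_to_fixed_without_centre_effect(self):
        cfg = SimulationConfig(n_samples=400, n_probes=100, seed=13,
                               markers={"crp": MarkerSpec(n_causal_cpgs=5,
                                                          intercept=0.5)},
                               hazard_weights={})
        bm, pheno, _ = simulate_cohort(cfg)
        model = train_surrogate("crp", bm, pheno,
                                TrainConfig(top_fraction=0.1, seed=0))
        assert model.model_type == "fixed_lasso"

    def test_non_positive_marker_rejected(self, planted_cohort):
        bm, pheno, _ = planted_cohort
        bad = pheno.copy()
        bad.loc[bad.index[0], "glucose"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            train_surrogate("glucose", bm, bad)

    def test_model_results_wrapper_summary(self, planted_cohort):
        bm, pheno, _ = planted_cohort
        res = SurrogateRegression("glucose", bm, pheno, top_fraction=0.05,
                                  seed=0).fit()
        text = res.summary()
        assert "glucose" in text and "lambda" in text
        assert res.model.n_probes_nonzero == (res.model.probe_weights != 0).sum()


class TestValidation:
    def test_perfect_prediction_gives_unit_correlation(self, planted_cohort):
        bm, pheno, _ = planted_cohort
        model = train_surrogate("glucose", bm, pheno,
                                TrainConfig(top_fraction=0.05, seed=0))
        from dnamcvd.scoring import compute_surrogate
        pred = compute_surrogate(bm, pheno, model.to_weight_table())
        perfect = pheno.copy()
        perfect["glucose"] = np.exp(pred.to_numpy())
        r, p, n = validate_surrogate(model, bm, perfect)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_pairs(self):
        # pairs (1,2),(2,1),(3,4),(4,3),(5,5): r = 8/sqrt(10*10) = 0.8
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        r, p = stats.pearsonr(x, y)
        assert r == pytest.approx(0.8, rel=1e-12)

    def test_null_predictions_give_near_zero_correlation(self):
        rng = np.random.default_rng(42)
        a, b = rng.standard_normal(1000), rng.standard_normal(1000)
        r, _ = stats.pearsonr(a, b)
        assert abs(r) < 0.08

    def test_too_few_samples_rejected(self, planted_cohort):
        bm, pheno, _ = planted_cohort
        model = train_surrogate("glucose", bm, pheno,
                                TrainConfig(top_fraction=0.05, seed=0))
        tiny = pheno.iloc[:2]
        tiny_bm = BetaMatrix(bm.data.loc[tiny["sample_id"]])
        with pytest.raises(ValueError, match="3 test samples"):
            validate_surrogate(model, tiny_bm, tiny)


class TestMetaAnalysis:
    def test_identical_studies_pool_to_same_r(self):
        r, p = meta_analyse_correlations([(0.3, 103), (0.3, 103)])
        assert r == pytest.approx(0.3, rel=1e-12)

    def test_single_study_passthrough(self):
        r, _ = meta_analyse_correlations([(0.45, 60)])
        assert r == pytest.approx(0.45, rel=1e-12)

    def test_hand_computed_inverse_variance_pooling(self):
        # independent hand computation of the weighted Fisher-z mean
        z = np.arctanh(np.array([0.2, 0.6]))
        w = np.array([47.0, 197.0])
        zbar = (w * z).sum() / w.sum()
        expected_r = np.tanh(zbar)
        expected_p = 2 * stats.norm.sf(abs(zbar) * np.sqrt(w.sum()))
        r, p = meta_analyse_correlations([(0.2, 50), (0.6, 200)])
        assert r == pytest.approx(expected_r, rel=1e-12)
        assert p == pytest.approx(expected_p, rel=1e-9)

    def test_random_effects_shrinks_towards_equal_weights(self):
        fixed, _ = meta_analyse_correlations([(0.1, 1000), (0.7, 50)])
        random_, _ = meta_analyse_correlations([(0.1, 1000), (0.7, 50)],
                                               method="random")
        naive = np.tanh(np.mean(np.arctanh([0.1, 0.7])))
        assert abs(random_ - naive) < abs(fixed - naive)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            meta_analyse_correlations([(1.0, 50)])
        with pytest.raises(ValueError, match="n >= 4"):
            meta_analyse_correlations([(0.3, 3)])
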