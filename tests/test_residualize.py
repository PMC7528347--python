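import numpy as np
import pytest

from resadj import (
    AdjustmentMap,
    adjust_for_split,
    fit_residual_model,
    residuals,
)
from resadj.residualize import ResidualError

from conftest import brute_force_residuals


class TestContinuousFits:
    def test_intercept_only_model_predicts_the_mean(self):
        v = np.array([1.0, 2.0, 3.0])
        C = np.empty((3, 0))
        model = fit_residual_model(v, C, [0, 1, 2], "continuous")
        np.testing.assert_allclose(model.predict(C), [2.0, 2.0, 2.0])
        np.testing.assert_allclose(
            residuals(model, v, C, [0, 1, 2]), [-1.0, 0.0, 1.0]
        )

    def test_perfect_fit_recovers_slope_one_intercept_zero(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=10)
        model = fit_residual_model(c, c.reshape(-1, 1), np.arange(10), "continuous")
        np.testing.assert_allclose(model.coef, [0.0, 1.0], atol=1e-10)

    def test_variable_equal_to_covariate_has_zero_residuals(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=20)
        C = c.reshape(-1, 1)
        model = fit_residual_model(c, C, np.arange(20), "continuous")
        np.testing.assert_allclose(residuals(model, c, C, np.arange(20)), 0.0, atol=1e-8)

    def test_rank_deficient_design_is_solved_not_raised(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=15)
        C = np.column_stack([c, c, 2 * c])  # collinear encoded covariates
        v = 3 * c + rng.normal(size=15, scale=0.1)
        model = fit_residual_model(v, C, np.arange(15), "continuous")
        assert np.all(np.isfinite(model.coef))


class TestCategoricalFits:
    def test_saturated_logistic_matches_cell_proportions(self):
        """With one binary covariate the fitted P(v=1|c) equals the empirical
        cell proportion (up to the small ridge used for convergence)."""
        c = np.array([0, 0, 0, 1, 1, 1], dtype=float).reshape(-1, 1)
        v = np.array([0, 0, 1, 1, 1, 0], dtype=float)
        model = fit_residual_model(v, c, np.arange(6), "binary")
        probs = model.classifier.predict_proba(np.array([[0.0], [1.0]]))[:, 1]
        np.testing.assert_allclose(probs, [1 / 3, 2 / 3], atol=1e-3)

    def test_expected_value_residual_on_test_row(self):
        # oracle: residual = v - P(v=1 | c) with class values {0, 1}
        c = np.array([0, 0, 0, 1, 1, 1, 0], dtype=float).reshape(-1, 1)
        v = np.array([0, 0, 1, 1, 1, 0, 1], dtype=float)
        model = fit_residual_model(v, c, np.arange(6), "binary")
        r = residuals(model, v, c, [6])
        np.testing.assert_allclose(r, [1 - 1 / 3], atol=1e-3)

    def test_single_class_fold_gives_constant_probability_one(self):
        v = np.full(5, 3.0)
        C = np.random.default_rng(3).normal(size=(5, 2))
        model = fit_residual_model(v, C, np.arange(5), "ordinal")
        np.testing.assert_allclose(residuals(model, v, C, np.arange(5)), 0.0)

    def test_binary_with_three_levels_rejected(self):
        v = np.array([0.0, 1.0, 2.0, 1.0])
        with pytest.raises(ResidualError, match="levels"):
            fit_residual_model(v, np.empty((4, 0)), np.arange(4), "binary")

    def test_ordinal_expected_value_uses_class_codes(self):
        """Residual = observed code minus probability-weighted class codes."""
        rng = np.random.default_rng(4)
        c = rng.normal(size=60)
        v = np.clip(np.round(2 + c + rng.normal(size=60, scale=0.3)), 1, 4)
        model = fit_residual_model(v, c.reshape(-1, 1), np.arange(60), "ordinal")
        probs = model.classifier.predict_proba(c.reshape(-1, 1))
        expected = probs @ model.class_values
        np.testing.assert_allclose(
            residuals(model, v, c.reshape(-1, 1), np.arange(60)), v - expected
        )


class TestAdjustForSplit:
    def test_empty_map_returns_nothing_adjusted(self, six_row_table):
        adjusted, models = adjust_for_split(
            six_row_table, AdjustmentMap(), [0, 1, 2, 3], [4, 5]
        )
        assert adjusted == {} and models == {}

    def test_matches_hand_ols_on_training_rows(self, six_row_table):
        """Oracle: closed-form slope/intercept from the 4 training points,
        applied to all 6 rows."""
        amap = AdjustmentMap(entries=[("geneA", ["c1"])])
        train, test = np.arange(4), np.array([4, 5])
        adjusted, _ = adjust_for_split(six_row_table, amap, train, test)
        v = six_row_table.values("geneA")
        c = six_row_table.values("c1")
        slope = np.cov(c[:4], v[:4], bias=True)[0, 1] / np.var(c[:4])
        intercept = v[:4].mean() - slope * c[:4].mean()
        oracle = v - (intercept + slope * c)
        np.testing.assert_allclose(adjusted["geneA"], oracle[np.r_[train, test]], atol=1e-8)

    def test_train_residuals_bit_invariant_to_test_perturbation(self, random_table, random_map):
        train, test = np.arange(150), np.arange(150, 200)
        adjusted, _ = adjust_for_split(random_table, random_map, train, test, include_target=True)
        perturbed = random_table.copy()
        perturbed.df.iloc[150:, :] += 1000.0
        adjusted2, _ = adjust_for_split(perturbed, random_map, train, test, include_target=True)
        for name in adjusted:
            # bit-identical, not merely close
            assert np.array_equal(adjusted[name][:150], adjusted2[name][:150])

    def test_oracle_equivalence_on_random_table(self, random_table, random_map):
        from resadj import make_split_plan

        plan = make_split_plan(200, 5, "shuffle", 0.75, seed=5)
        covs = [f"c{j}" for j in range(3)]
        C = random_table.df[covs].to_numpy()
        for train, test in plan.splits:
            adjusted, _ = adjust_for_split(random_table, random_map, train, test, include_target=True)
            rows = np.r_[train, test]
            for name in [f"g{j}" for j in range(5)] + ["y"]:
                oracle = brute_force_residuals(random_table.values(name), C, train, rows)
                np.testing.assert_allclose(adjusted[name], oracle, atol=1e-8)

    def test_whole_data_fit_differs_on_test_rows(self, random_table, random_map):
        """The leakage signature: full-data residuals disagree with
        split-fit residuals on test rows for generic data."""
        train, test = np.arange(150), np.arange(150, 200)
        split_adj, _ = adjust_for_split(random_table, random_map, train, test)
        full_adj, _ = adjust_for_split(
            random_table, random_map, np.arange(200), np.array([], dtype=int)
        )
        g0_split_test = split_adj["g0"][150:]
        g0_full_test = full_adj["g0"][150:200]
        assert not np.allclose(g0_split_test, g0_full_test, atol=1e-6)


def test_orthogonality_of_training_residuals(random_table, random_map):
    """Over training rows, continuous residuals have mean 0 and zero sample
    covariance with every covariate column."""
    train, test = np.arange(150), np.arange(150, 200)
    adjusted, _ = adjust_for_split(random_table, random_map, train, test, include_target=True)
    C = random_table.df[[f"c{j}" for j in range(3)]].to_numpy()
    for name, vals in adjusted.items():
        r_train = vals[:150]
        assert abs(r_train.mean()) < 1e-8
        for j in range(3):
            cov = np.mean(r_train * (C[:150, j] - C[:150, j].mean()))
            assert abs(cov) < 1e-8
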