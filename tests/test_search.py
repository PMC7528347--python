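import numpy as np
import pandas as pd
import pytest

from resadj import (
    AdjustedTable,
    AdjustmentMap,
    ClassicDataset,
    FeatureSetCollection,
    PipelineIndividual,
    Template,
    adjust_for_split,
    build_resadj_dataset,
    default_pool,
    evolve,
    feature_set_select,
    holdout_score,
    make_split_plan,
    residual_scorer,
)
from resadj.search import (
    SEARCH_END,
    OperatorSpec,
    ResAdjTransformerStep,
    SearchFailure,
    score_predictions,
)
from resadj.table import TableError


class TestTemplate:
    @pytest.mark.parametrize(
        "text",
        [
            "FeatureSetSelector-resAdjTransformer-Transformer-Regressor",
            "FeatureSetSelector-Transformer-Classifier",
            "resAdjTransformer-Selector-Regressor",
            "Regressor",
        ],
    )
    def test_valid_templates_parse(self, text):
        assert str(Template.parse(text)) == text

    @pytest.mark.parametrize(
        "text",
        [
            "FeatureSetSelector-Transformer",  # no estimator
            "Transformer-resAdjTransformer-Regressor",  # resAdj not first
            "FeatureSetSelector-Transformer-resAdjTransformer-Regressor",
            "Regressor-FeatureSetSelector",
        ],
    )
    def test_invalid_templates_rejected(self, text):
        with pytest.raises(TableError):
            Template.parse(text)


@pytest.fixture
def linear_setup():
    """Three feature sets; set S_true linearly determines the target."""
    rng = np.random.default_rng(8)
    m = 90
    names = [f"g{s}_{j}" for s in range(3) for j in range(4)]
    X = rng.normal(size=(m, 12))
    y = X[:, 0:4].sum(axis=1) + rng.normal(scale=0.05, size=m)
    df = pd.DataFrame(X, columns=names)
    df["y"] = y
    df.index = pd.Index([f"s{i}" for i in range(m)], name="sample_id")
    roles = {c: "feature" for c in names} | {"y": "target"}
    kinds = {c: "continuous" for c in names} | {"y": "continuous"}
    table = AdjustedTable(df, roles, kinds)
    coll = FeatureSetCollection(
        {f"S{s}": (f"set {s}", names[s * 4 : (s + 1) * 4]) for s in range(3)}
    )
    return table, coll


class TestFeatureSetSelect:
    def test_intersection_and_passthrough(self, random_table):
        coll = FeatureSetCollection({"A": ("d", ["g1", "g2", "g9"])})
        out = feature_set_select(random_table, coll, "A")
        assert out.feature_names == ["g1", "g2"]
        assert out.covariate_names == ["c0", "c1", "c2"]  # untouched

    def test_disjoint_set_is_error(self, random_table):
        coll = FeatureSetCollection({"A": ("d", ["nope"])})
        with pytest.raises(TableError, match="no members"):
            feature_set_select(random_table, coll, "A")

    def test_unknown_set_is_error(self, random_table):
        coll = FeatureSetCollection({"A": ("d", ["g1"])})
        with pytest.raises(TableError, match="unknown"):
            feature_set_select(random_table, coll, "B")


class TestResAdjTransformerStep:
    def test_fit_then_transform_equals_adjust_for_split(self, random_table, random_map):
        train, test = np.arange(150), np.arange(150, 200)
        cols = random_table.feature_names + random_table.covariate_names
        df = random_table.df[cols]
        step = ResAdjTransformerStep(random_map, random_table.covariate_names)
        step.fit(df, train, random_table.kinds)
        out_train = step.transform(df, train)
        out_test = step.transform(df, test)
        oracle, _ = adjust_for_split(random_table, random_map, train, test)
        for j in range(5):
            np.testing.assert_allclose(out_train[f"g{j}"], oracle[f"g{j}"][:150], atol=1e-10)
            np.testing.assert_allclose(out_test[f"g{j}"], oracle[f"g{j}"][150:], atol=1e-10)

    def test_covariates_dropped_even_with_empty_map(self, random_table):
        df = random_table.df[random_table.feature_names + random_table.covariate_names]
        step = ResAdjTransformerStep(AdjustmentMap(), random_table.covariate_names)
        step.fit(df, np.arange(200), random_table.kinds)
        out = step.transform(df, np.arange(200))
        assert list(out.columns) == random_table.feature_names
        np.testing.assert_array_equal(out.to_numpy(), df[random_table.feature_names].to_numpy())

    def test_transform_before_fit_is_error(self, random_table):
        step = ResAdjTransformerStep(AdjustmentMap(), [])
        with pytest.raises(SearchFailure):
            step.transform(random_table.df, np.arange(5))


class TestResidualScorer:
    @pytest.fixture
    def ds(self, random_table, random_map):
        plan = make_split_plan(200, 5, "shuffle", 0.75, seed=2)
        return build_resadj_dataset(random_table, random_map, plan)

    def test_exact_predictions_score_one(self, ds):
        _, test = ds.plan.splits[1]
        y = ds.adjusted_target(1, test)
        assert residual_scorer(ds, y, test, "r2") == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, ds):
        _, test = ds.plan.splits[0]
        y = ds.adjusted_target(0, test)
        preds = np.full(len(test), y.mean())
        assert residual_scorer(ds, preds, test, "r2") == pytest.approx(0.0)

    def test_hand_sized_r2_against_brute_force(self):
        y = np.array([1.0, -1.0, 2.0, -2.0])
        p = np.array([0.5, -0.5, 1.0, -1.0])
        ss_res = np.sum((y - p) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert score_predictions(y, p, "r2") == pytest.approx(1 - ss_res / ss_tot)

    def test_balanced_accuracy_is_mean_per_class_recall(self):
        # 3-class confusion: A 2/3 right, B 1/2 right, C 1/1 right
        y = np.array([1, 1, 1, 2, 2, 3])
        p = np.array([1, 1, 2, 2, 3, 3])
        expected = (2 / 3 + 1 / 2 + 1 / 1) / 3
        assert score_predictions(y, p, "balanced_accuracy") == pytest.approx(expected)


class TestEvolve:
    def _classic(self, table, seed=0):
        plan = make_split_plan(table.m, 5, "shuffle", 0.75, seed=seed)
        return ClassicDataset(table, plan)

    def test_degenerate_search_returns_the_single_pipeline(self, linear_setup):
        table, coll = linear_setup
        pool = default_pool(coll.names())
        pool.by_role["Regressor"] = [pool.by_role["Regressor"][1]]  # LinearRegression
        pool.by_role["FeatureSetSelector"] = [
            OperatorSpec("FeatureSetSelector", "FeatureSetSelector", (("set_name", ("S0",)),))
        ]
        data = self._classic(table)
        best, log, fitted = evolve(
            data, "FeatureSetSelector-Regressor", pool, coll,
            population=1, generations=0, metric="r2", seed=0,
        )
        assert best.selected_set == "S0"
        assert np.isfinite(best.cv_score)
        assert len(log) == 1

    def test_same_seed_identical_generation_log(self, linear_setup):
        table, coll = linear_setup
        kw = dict(population=8, generations=3, metric="r2", seed=5)
        _, log1, _ = evolve(self._classic(table), "FeatureSetSelector-Transformer-Regressor", None, coll, **kw)
        _, log2, _ = evolve(self._classic(table), "FeatureSetSelector-Transformer-Regressor", None, coll, **kw)
        assert log1 == log2

    def test_best_score_is_monotone_under_elitism(self, linear_setup):
        table, coll = linear_setup
        _, log, _ = evolve(
            self._classic(table), "FeatureSetSelector-Transformer-Regressor", None, coll,
            population=10, generations=4, metric="r2", seed=7,
        )
        best_scores = [g["best_score"] for g in log]
        assert all(b2 >= b1 for b1, b2 in zip(best_scores, best_scores[1:]))

    def test_search_finds_the_determining_feature_set(self, linear_setup):
        """Oracle: S0 linearly determines y, so exhaustive evaluation of all
        sets under a linear model ranks S0 first; the GP should agree in
        most seeded runs."""
        table, coll = linear_setup
        hits = 0
        for seed in range(5):
            data = self._classic(table, seed=seed)
            best, _, _ = evolve(
                data, "FeatureSetSelector-Transformer-Regressor", None, coll,
                population=20, generations=5, metric="r2", seed=seed,
            )
            hits += best.selected_set == "S0"
        assert hits >= 4

    def test_no_full_lookup_before_search_end(self, random_table, random_map):
        plan = make_split_plan(160, 4, "shuffle", 0.75, seed=1)
        ds = build_resadj_dataset(random_table, random_map, plan, 0.2, seed=1)
        coll = FeatureSetCollection({"A": ("d", [f"g{j}" for j in range(5)])})
        evolve(
            ds, "FeatureSetSelector-resAdjTransformer-Transformer-Regressor",
            None, coll, population=4, generations=2, metric="r2", seed=3,
        )
        from resadj import FULL

        end = ds.call_log.index((SEARCH_END, None))
        before = ds.call_log[:end]
        after = ds.call_log[end + 1 :]
        assert all(split != FULL for split, _ in before)
        assert any(split == FULL for split, _ in after)


class TestHoldout:
    def test_perfect_and_mean_predictions(self, linear_setup):
        from resadj import split_holdout

        table, coll = linear_setup
        work, hold = split_holdout(table, 0.25, seed=0)
        plan = make_split_plan(work.m, 4, "shuffle", 0.75, seed=0)
        data = ClassicDataset(work, plan, hold)
        best, _, fitted = evolve(
            data, "FeatureSetSelector-Transformer-Regressor", None, coll,
            population=10, generations=3, metric="r2", seed=1,
        )
        score = holdout_score(fitted, data, "r2")
        assert best.holdout_score == score
        assert score > 0.5  # S_true signal dominates

    def test_missing_holdout_is_error(self, linear_setup):
        table, coll = linear_setup
        plan = make_split_plan(table.m, 4, "shuffle", 0.75, seed=0)
        data = ClassicDataset(table, plan)
        best, _, fitted = evolve(
            data, "FeatureSetSelector-Transformer-Regressor", None, coll,
            population=2, generations=0, metric="r2", seed=1,
        )
        with pytest.raises(TableError, match="holdout"):
            holdout_score(fitted, data, "r2")
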