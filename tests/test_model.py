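"""Modeling stage: level merging, balanced splits, SMOTE, Gain ranking,
LOOCV without leakage, selection rules, refits and the LASSO subscale."""

import numpy as np
import pandas as pd
import pytest

from gaitbench import metrics as _metrics
from gaitbench.model import (
    GBT,
    GBT_GRID,
    K_GRID,
    RBF,
    SVM_GRID,
    CVResult,
    MergeMap,
    SplitError,
    TrainedItemModel,
    expand_grid,
    fit_final,
    fit_subscale,
    loocv_evaluate,
    merge_levels,
    rank_features_by_gain,
    select_best,
    sensor_contribution,
    smote_balance,
    split_cohort,
)
from gaitbench.synth import ITEMS, simulate_cohort


def scores_from_counts(counts: dict[int, int]) -> np.ndarray:
    return np.concatenate([np.full(n, s) for s, n in counts.items()])


class TestMergeLevels:
    def test_sparse_top_levels_cascade_down(self):
        scores = scores_from_counts({0: 150, 1: 60, 2: 20, 3: 4, 4: 2})
        assert merge_levels(scores).mapping == (0, 1, 2, 2, 2)

    def test_three_level_map_like_freezing_item(self):
        scores = scores_from_counts({0: 146, 1: 6, 2: 22, 3: 4, 4: 2})
        mm = merge_levels(scores, item="item_3_11")
        assert mm.mapping == (0, 1, 2, 2, 2)
        assert mm.m == 3
        assert mm.level_labels() == ["0", "1", "2/3/4"]

    def test_four_level_map_like_posture_item(self):
        scores = scores_from_counts({0: 49, 1: 80, 2: 33, 3: 14, 4: 4})
        mm = merge_levels(scores, item="item_3_13")
        assert mm.mapping == (0, 1, 2, 3, 3)
        assert mm.level_labels() == ["0", "1", "2", "3/4"]

    def test_sparse_lowest_level_folds_upward(self):
        scores = scores_from_counts({0: 3, 1: 100, 2: 50})
        assert merge_levels(scores).mapping == (0, 0, 1, 1, 1)

    def test_single_class_not_modelable(self):
        with pytest.raises(ValueError, match="not modelable"):
            merge_levels(np.full(80, 2))

    def test_same_map_applied_verbatim_to_test(self):
        mm = merge_levels(scores_from_counts({0: 100, 1: 50, 2: 30, 3: 3, 4: 1}))
        test_scores = np.array([0, 1, 2, 3, 4])
        np.testing.assert_array_equal(mm.apply(test_scores), [0, 1, 2, 2, 2])

    def test_mapping_validation(self):
        with pytest.raises(ValueError):
            MergeMap("x", (0, 2, 1, 2, 2))  # not monotone
        with pytest.raises(ValueError):
            MergeMap("x", (0, 2, 2, 2, 2))  # not surjective

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            merge_levels(np.array([0, 1, 5]))


@pytest.fixture(scope="module")
def labels():
    return simulate_cohort(225, seed=5).labels


class TestSplitCohort:
    def test_sizes_180_45(self, labels):
        train, test = split_cohort(labels, seed=0)
        assert len(train) == 180 and len(test) == 45
        assert not set(train) & set(test)

    def test_deterministic(self, labels):
        assert split_cohort(labels, seed=3) == split_cohort(labels, seed=3)

    def test_all_levels_present_in_training(self, labels):
        train, _ = split_cohort(labels, seed=1)
        tr = labels[labels["participant"].isin(train)]
        for item in ITEMS:
            assert set(labels[item]) == set(tr[item])

    def test_singleton_level_forced_into_training(self, labels):
        mod = labels.copy()
        # exactly one participant carries score 4 on the first item
        mod.loc[:, ITEMS[0]] = np.clip(mod[ITEMS[0]], 0, 3)
        lucky = mod.index[7]
        mod.loc[lucky, ITEMS[0]] = 4
        train, _ = split_cohort(mod, seed=2)
        assert mod.loc[lucky, "participant"] in train

    def test_exhaustion_reports_failing_constraint(self, labels):
        with pytest.raises(SplitError, match="last failure"):
            split_cohort(labels, seed=0, max_tries=0)

    def test_tiny_cohort_rejected(self, labels):
        with pytest.raises(ValueError):
            split_cohort(labels.head(5))


class TestSmote:
    def test_balances_all_classes(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = np.array([0] * 40 + [1] * 15 + [2] * 5)
        Xa, ya = smote_balance(X, y, rng)
        _, counts = np.unique(ya, return_counts=True)
        assert counts.tolist() == [40, 40, 40]
        assert len(Xa) == 120

    def test_synthetic_points_interpolate_within_class_box(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 25 + [1] * 5)
        Xa, ya = smote_balance(X, y, rng)
        new = Xa[30:]
        box_lo, box_hi = X[y == 1].min(0), X[y == 1].max(0)
        assert np.all(new >= box_lo - 1e-12) and np.all(new <= box_hi + 1e-12)

    def test_singleton_class_duplicated(self):
        rng = np.random.default_rng(2)
        X = np.vstack([np.zeros((9, 2)), [[5.0, 5.0]]])
        y = np.array([0] * 9 + [1])
        Xa, ya = smote_balance(X, y, rng)
        np.testing.assert_array_equal(Xa[ya == 1], np.tile([5.0, 5.0], (9, 1)))

    def test_small_class_reduces_neighbour_count(self):
        rng = np.random.default_rng(3)
        X = np.vstack([np.zeros((20, 2)), [[1, 1], [2, 2], [3, 3]]])
        y = np.array([0] * 20 + [1] * 3)
        Xa, ya = smote_balance(X, y, rng, k=5)  # k must fall back to 2
        assert (ya == 1).sum() == 20


class TestGainRanking:
    def test_signal_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 31)), columns=[f"f{i:02d}" for i in range(31)])
        y = (X["f07"] > 0).astype(int)
        ranked = rank_features_by_gain(X, y, seed=0)
        assert ranked[0][0] == "f07"

    def test_all_noise_returns_full_ranking_nonnegative(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(80, 10)), columns=[f"n{i}" for i in range(10)])
        y = rng.integers(0, 2, 80)
        ranked = rank_features_by_gain(X, y, seed=0)
        assert len(ranked) == 10
        assert all(g >= 0 for _, g in ranked)

    def test_deterministic_with_name_tie_break(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            {"b_const": np.ones(60), "a_const": np.ones(60), "sig": rng.normal(size=60)}
        )
        y = (X["sig"] > 0).astype(int)
        r1 = rank_features_by_gain(X, y, seed=0)
        r2 = rank_features_by_gain(X, y, seed=0)
        assert r1 == r2
        zero_named = [name for name, g in r1 if g == 0]
        assert zero_named == sorted(zero_named)


class TestGrids:
    def test_grid_sizes_match_protocol(self):
        assert len(expand_grid(GBT_GRID)) == 24
        assert len(expand_grid(SVM_GRID)) == 16
        assert K_GRID == tuple(range(5, 55, 5))
        # 24 hyperparameter combos x 10 feature counts = 240 boosted configs
        assert len(expand_grid(GBT_GRID)) * len(K_GRID) == 240


def separable_problem(n=30, n_feat=8, seed=0):
    """Binary target that is a deterministic function of a two-cluster f0.

    f0 takes only the values -1 and +1, so every leave-one-out training
    fold brackets the held-out point and any sane split separates the
    classes exactly.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, n_feat)), columns=[f"f{i}" for i in range(n_feat)])
    X["f0"] = rng.choice([-1.0, 1.0], size=n)
    y = (X["f0"] > 0).astype(int).to_numpy()
    return X, y


class TestLoocv:
    def test_left_out_row_never_used_for_fitting_or_smote(self):
        X, y = separable_problem()
        audit: list = []
        loocv_evaluate(
            X, y, list(X.columns), GBT, [dict(learning_rate=0.1, max_depth=3, gamma=0.1, reg_lambda=3)],
            k_grid=(5,), seed=0, audit=audit,
        )
        assert len(audit) == len(X)
        for left_out, train_idx in audit:
            assert left_out not in train_idx
            assert len(train_idx) == len(X) - 1

    def test_perfectly_separable_reaches_full_accuracy(self):
        X, y = separable_problem(n=40)
        results = loocv_evaluate(
            X, y, list(X.columns), GBT,
            [dict(learning_rate=0.1, max_depth=3, gamma=0.1, reg_lambda=3)],
            k_grid=(5,), seed=0,
        )
        assert results[0].report.acc_exact == 100.0

    def test_one_result_per_configuration(self):
        X, y = separable_problem(n=25)
        grid = [dict(gamma=0.01, C=1), dict(gamma=0.1, C=1)]
        results = loocv_evaluate(X, y, list(X.columns), RBF, grid, k_grid=(5, 8), seed=0)
        assert len(results) == 4
        assert {r.k for r in results} == {5, 8}


def _fake_result(algorithm, k, wf1, acc=50.0):
    cm = np.array([[1, 0], [0, 1]])
    rep = _metrics.item_report(cm)
    rep.weighted_f1 = wf1
    rep.acc_exact = acc
    return CVResult(algorithm, {}, k, rep, 0)


class TestSelectBest:
    def test_single_result_returned(self):
        r = _fake_result(GBT, 10, 0.8)
        assert select_best([r]) is r

    def test_tie_broken_by_smaller_k(self):
        a = _fake_result(GBT, 30, 0.7)
        b = _fake_result(GBT, 10, 0.7)
        assert select_best([a, b]).k == 10

    def test_tie_broken_by_algorithm_order(self):
        a = _fake_result(RBF, 10, 0.7)
        b = _fake_result(GBT, 10, 0.7)
        assert select_best([a, b]).algorithm == GBT

    def test_higher_weighted_f1_wins(self):
        a = _fake_result(RBF, 50, 0.9)
        b = _fake_result(GBT, 5, 0.7)
        assert select_best([a, b]).algorithm == RBF

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestFitFinal:
    def make_fitted(self, seed=0, tmp=None):
        X, y = separable_problem(n=60, seed=4)
        ranked = rank_features_by_gain(X, y, seed=seed)
        best = _fake_result(GBT, 5, 0.9)
        best.params = dict(learning_rate=0.1, max_depth=3, gamma=0.1, reg_lambda=3)
        mm = MergeMap("item_3_9", (0, 1, 1, 1, 1))
        return X, y, fit_final(X, y, "item_3_9", best, ranked, mm, seed=seed)

    def test_refit_deterministic(self):
        X, _, m1 = self.make_fitted()
        _, _, m2 = self.make_fitted()
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_round_trip_identical_predictions(self, tmp_path):
        X, _, model = self.make_fitted()
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedItemModel.load(path)
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
        assert loaded.features == model.features

    def test_evaluate_uses_merge_map(self):
        X, y, model = self.make_fitted()
        raw_scores = np.where(y == 1, 3, 0)  # scores 0/3 merge onto levels 0/1
        rep = model.evaluate(X, raw_scores)
        assert rep.n == len(X)
        assert rep.acc_exact > 90.0


class TestSensorContribution:
    def _model_with(self, features):
        return TrainedItemModel(
            item="item_3_9", algorithm=GBT, params={}, k=len(features),
            features=features, gain_scores=[1.0] * len(features),
            merge_map=MergeMap("item_3_9", (0, 1, 1, 1, 1)),
            medians=np.zeros(len(features)), estimator=None,
        )

    def test_share_arithmetic(self):
        feats = ["Shank—Swing RoM—mean (max)"] * 0 + [
            "Shank—Swing RoM—mean (max)",
            "Shank—Swing RoM—min (diff)",
            "Cadence—mean",
            "Trunk—Max Sagittal Angular Velocity—max",
            "180° Turn—Duration—mean",
        ]
        contrib = sensor_contribution(self._model_with(feats))
        assert contrib["shank"] == pytest.approx(3 / 5)
        assert contrib["chest"] == pytest.approx(1 / 5)
        assert contrib["waist"] == pytest.approx(1 / 5)

    def test_single_sensor_features_sum_to_one(self):
        feats = ["Cadence—mean", "Gait Speed—max", "180° Turn—Duration—mean"]
        contrib = sensor_contribution(self._model_with(feats))
        assert sum(contrib.values()) == pytest.approx(1.0)

    def test_multi_sensor_feature_counted_once_per_group(self):
        feats = ["Effective Trial Duration", "Cadence—mean"]
        contrib = sensor_contribution(self._model_with(feats))
        assert contrib["shank"] == 1.0  # both features touch the shank group
        assert contrib["waist"] == 0.5
        assert sum(contrib.values()) > 1.0

    def test_unregistered_feature_raises(self):
        with pytest.raises(KeyError):
            sensor_contribution(self._model_with(["Mystery—mean (max)"]))


class TestSubscale:
    def test_recovers_single_informative_feature(self):
        rng = np.random.default_rng(0)
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 51)), columns=["f1"] + [f"n{i}" for i in range(50)])
        y = 3.0 * X["f1"].to_numpy() + rng.normal(0, 0.5, n)
        model = fit_subscale(X, y, seed=0)
        assert "f1" in model.coefficients
        assert model.coefficients["f1"] == pytest.approx(3.0, abs=0.5)
        # min-CV lambda keeps a handful of tiny noise coefficients; most of
        # the 50 distractors must be zeroed and all must stay small
        noise_betas = [v for k, v in model.coefficients.items() if k.startswith("n")]
        assert len(noise_betas) <= 20
        assert max(map(abs, noise_betas), default=0.0) < 0.2

    def test_infinite_penalty_collapses_to_mean(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        y = rng.normal(10, 2, 50)
        model = fit_subscale(X, y, alpha=1e6)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(np.mean(y))
        np.testing.assert_allclose(model.predict(X), np.mean(y))

    def test_constant_target_rejected(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(30, 3)))
        with pytest.raises(ValueError, match="constant"):
            fit_subscale(X, np.full(30, 7.0))

    def test_holdout_spearman_on_predictable_target(self):
        rng = np.random.default_rng(3)
        n = 240
        X = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"f{i}" for i in range(20)])
        y = X["f0"] * 2 + X["f1"] + rng.normal(0, 0.3, n)
        model = fit_subscale(X.iloc[:200], y[:200], seed=0)
        rep = model.evaluate(X.iloc[200:], y[200:])
        assert rep.spearman_r >= 0.7
        assert rep.rmse >= rep.mae >= 0
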