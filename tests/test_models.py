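"""Supervised models: regressor tuning/exclusion, balanced sampling,
classifier recovery, probability contracts, persistence."""

import numpy as np
import pandas as pd
import pytest

import ecostatus as es
from ecostatus.constants import FACTORS
from ecostatus.models import (balanced_sample, load_bundle, save_bundle,
                              tune_classifier, tune_regressor)
from conftest import toy_env_grid


@pytest.fixture(scope="module")
def env_samples():
    return es.gen_env_samples(600, seed=10)


class TestTuneRegressor:
    def test_perfectly_learnable_target(self, env_samples):
        y = env_samples["temperature"]
        res = tune_regressor(env_samples, y, families=("linear",), seed=0)
        assert res.r2_test >= 0.99
        assert not res.excluded

    def test_noise_target_excluded(self, env_samples):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(env_samples))
        res = tune_regressor(env_samples, y, families=("linear", "knn"), seed=0)
        assert res.excluded
        assert "R^2" in res.reason

    def test_constant_target_excluded_with_reason(self, env_samples):
        res = tune_regressor(env_samples, np.ones(len(env_samples)), seed=0)
        assert res.excluded and res.reason == "constant target"

    def test_importance_normalized(self, env_samples):
        res = tune_regressor(env_samples, env_samples["phosphate"] * 2,
                             families=("random_forest",), seed=0)
        assert res.importance.sum() == pytest.approx(1.0)
        assert (res.importance >= 0).all()
        assert res.importance.idxmax() == "phosphate"

    def test_nonlinear_target_prefers_trees(self):
        env = es.gen_env_samples(1000, seed=42)
        rng = np.random.default_rng(42)
        y = 2 * env["phosphate"] + env["oxygen"] ** 2
        y = y + rng.normal(0, 0.05 * y.std(), size=len(y))
        tree = tune_regressor(env, y, families=("random_forest",), seed=42)
        lin = tune_regressor(env, y, families=("linear",), seed=42)
        assert tree.cv_r2 > lin.cv_r2

    def test_too_few_samples_rejected(self):
        env = es.gen_env_samples(20, seed=0)
        with pytest.raises(ValueError):
            tune_regressor(env, np.arange(20.0), seed=0)


class TestPredictIndices:
    def test_mask_propagation_and_consistency(self, env_samples):
        bundle = es.fit_index_regressors(
            env_samples, pd.DataFrame({"idx": env_samples["temperature"] * 3}),
            families=("linear",), seed=0)
        lats, lons = [0.0, 10.0], [0.0, 10.0, 20.0]
        temp = np.array([[5.0, 10.0, np.nan], [15.0, 20.0, 25.0]])
        env = toy_env_grid({"temperature": temp}, lats, lons)
        for f in FACTORS:  # propagate the mask to every factor
            env[f] = env[f].where(~np.isnan(temp))
        pred = es.predict_indices(bundle, env)
        assert np.isnan(pred["idx"].values[0, 2])
        assert pred["idx"].values[1, 0] == pytest.approx(45.0, rel=1e-6)

    def test_missing_factor_rejected(self, env_samples):
        bundle = es.fit_index_regressors(
            env_samples, pd.DataFrame({"idx": env_samples["temperature"]}),
            families=("linear",), seed=0)
        with pytest.raises(ValueError, match="missing factor"):
            es.predict_indices(bundle, env_samples.drop(columns=["iron"]))


class TestBalancedSample:
    def test_count_arithmetic(self):
        labels = pd.Series(["A"] * 5000 + ["B"] * 4000)
        train, test = balanced_sample(labels, 3000, seed=1)
        assert len(train) == 6000 and len(test) == 3000
        assert labels.loc[train].value_counts().to_dict() == {"A": 3000, "B": 3000}

    def test_strict_mode_rejects_small_class(self):
        labels = pd.Series(["A"] * 100 + ["B"] * 10)
        with pytest.raises(ValueError, match="class B"):
            balanced_sample(labels, 50, seed=0)

    def test_oversample_mode(self):
        labels = pd.Series(["A"] * 100 + ["B"] * 10)
        train, _ = balanced_sample(labels, 50, seed=0, oversample=True)
        assert labels.loc[train].value_counts()["B"] == 50

    def test_sampled_class_matches_full_distribution(self):
        # the balanced subsample should not distort per-factor distributions:
        # 3000 drawn from a ~10000-member class look like the whole class
        env = es.gen_env_samples(20000, seed=1)
        truth = es.make_truth_mapping(env, n_status=2, seed=1)
        labels = pd.Series(truth.status(env), index=env.index)
        train, _ = balanced_sample(labels, 3000, seed=1)
        from scipy.stats import ks_2samp
        biggest = labels.value_counts().idxmax()
        sampled = env.loc[train[(labels.loc[train] == biggest).to_numpy()]]
        full = env.loc[labels[labels == biggest].index]
        for f in FACTORS:
            assert ks_2samp(sampled[f], full[f]).pvalue > 0.01


class TestTuneClassifier:
    def test_separable_toy_perfect(self):
        env = es.gen_env_samples(400, seed=3)
        y = pd.Series(np.where(env["temperature"] < 5, 1,
                               np.where(env["temperature"] < 18, 2, 3)),
                      index=env.index)
        # margin around the cuts so the boundary is learnable exactly
        keep = (abs(env["temperature"] - 5) > 1) & (abs(env["temperature"] - 18) > 1)
        env, y = env[keep], y[keep]
        tr, te = balanced_sample(y, 60, seed=3)
        clf = tune_classifier(env.loc[tr], y.loc[tr], env.loc[te], y.loc[te],
                              families=("xgboost",), seed=3, cv=5)
        assert clf.test_accuracy == 1.0

    def test_shuffled_labels_chance_level(self):
        env = es.gen_env_samples(500, seed=4)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.integers(1, 5, len(env)), index=env.index)
        tr, te = balanced_sample(y, 80, seed=4)
        clf = tune_classifier(env.loc[tr], y.loc[tr], env.loc[te], y.loc[te],
                              families=("logistic",), seed=4, cv=5)
        assert clf.cv_accuracy < 0.40  # 4 classes -> chance 0.25

    def test_single_class_rejected(self):
        env = es.gen_env_samples(100, seed=5)
        with pytest.raises(ValueError):
            tune_classifier(env, np.ones(100), seed=5)

    def test_importance_normalized(self, ocean_system):
        truth = ocean_system["truth"]
        env, y = es.gen_labeled_env_samples(truth, 1500, seed=6, margin=0.1)
        tr, te = balanced_sample(y, 100, seed=6)
        clf = tune_classifier(env.loc[tr], y.loc[tr], env.loc[te], y.loc[te],
                              families=("xgboost",), seed=6, cv=5)
        assert clf.importance.sum() == pytest.approx(1.0)
        assert clf.importance.idxmax() == "phosphate"


@pytest.fixture(scope="module")
def fitted(ocean_system):
    truth = ocean_system["truth"]
    env, y = es.gen_labeled_env_samples(truth, 2000, seed=7, margin=0.15)
    tr, te = balanced_sample(y, 150, seed=7)
    return tune_classifier(env.loc[tr], y.loc[tr], env.loc[te], y.loc[te],
                           families=("xgboost",), seed=7, cv=5), env


class TestPredictProba:
    def test_probabilities_sum_to_one(self, fitted):
        clf, env = fitted
        probs, labels = es.predict_status_proba(clf, env)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (labels == probs.idxmax(axis=1)).all()

    def test_deep_interior_point_confident(self, fitted, ocean_system):
        clf, env = fitted
        truth = ocean_system["truth"]
        s = truth.score(env[list(FACTORS)].to_numpy())
        edges = np.concatenate([[s.min()], truth.thresholds, [s.max()]])
        dist = np.min(np.abs(s[:, None] - truth.thresholds[None, :]), axis=1)
        deep = np.argsort(dist)[-20:]
        probs, _ = es.predict_status_proba(clf, env.iloc[deep])
        assert (probs.max(axis=1) > 0.9).all()

    def test_masked_cells_masked(self, fitted, ocean_system):
        clf, _ = fitted
        env = ocean_system["env"]
        probs, status = es.predict_status_proba(clf, env)
        land = ~ocean_system["spec"].mask()
        assert np.isnan(status.values[land]).all()
        first = list(probs.data_vars)[0]
        assert np.isnan(probs[first].values[land]).all()


class TestPersistence:
    def test_round_trip(self, tmp_path, ocean_system):
        truth = ocean_system["truth"]
        env, y = es.gen_labeled_env_samples(truth, 1200, seed=8, margin=0.1)
        tr, te = balanced_sample(y, 80, seed=8)
        clf = tune_classifier(env.loc[tr], y.loc[tr], env.loc[te], y.loc[te],
                              families=("logistic",), seed=8, cv=5)
        path = tmp_path / "clf.joblib"
        save_bundle(clf, path)
        loaded = load_bundle(path)
        probs_a, _ = es.predict_status_proba(clf, env.iloc[:10])
        probs_b, _ = es.predict_status_proba(loaded, env.iloc[:10])
        pd.testing.assert_frame_equal(probs_a, probs_b)

    def test_schema_mismatch_fails_loudly(self, tmp_path):
        import joblib
        path = tmp_path / "bad.joblib"
        joblib.dump({"schema_version": 999, "payload": None}, path)
        with pytest.raises(ValueError, match="schema"):
            load_bundle(path)
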