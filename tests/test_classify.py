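import numpy as np
import pandas as pd
import pytest

from senodetect.classify import (
    ClassifierModel,
    ConsensusEnsemble,
    LabelingPolicy,
    SchemaMismatchError,
    SizingError,
    TrainingSet,
    build_training_set,
    fit_pruned_tree,
    load_model,
    predict,
    predict_proba,
    save_model,
    summarize_wells,
    train_forest,
    train_tree,
)
from senodetect.featuresets import CORE7, FeatureSet
from senodetect.synthdata import default_population_spec, generate_population_table

ONE_D = FeatureSet("one_d", ("X",), {"X": 0})


def _tables(n=3000, seed=0):
    normal = generate_population_table(
        default_population_spec(n, 0.0, seed=seed)
    ).drop(columns="true_label")
    senescent = generate_population_table(
        default_population_spec(n, 1.0, seed=seed + 1)
    ).drop(columns="true_label")
    return normal, senescent


class TestBuildTrainingSet:
    def test_exact_per_class_counts(self):
        normal, senescent = _tables()
        ts = build_training_set(normal, senescent, n_per_class=1000, seed=0)
        assert ts.class_counts == {0: 1000, 1: 1000}
        assert len(ts.X) == 2000

    def test_same_seed_identical_selection(self):
        normal, senescent = _tables()
        a = build_training_set(normal, senescent, n_per_class=500, seed=3)
        b = build_training_set(normal, senescent, n_per_class=500, seed=3)
        pd.testing.assert_frame_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)

    def test_pool_deficit_reports_counts(self):
        normal, senescent = _tables(n=100)
        with pytest.raises(SizingError, match="100 rows"):
            build_training_set(normal, senescent, n_per_class=500, seed=0)
        ts = build_training_set(
            normal, senescent, n_per_class=500, seed=0, allow_smaller=True
        )
        assert ts.class_counts == {0: 100, 1: 100}

    def test_marker_mode_restricts_pools(self, rng):
        normal, senescent = _tables(n=1000)
        # 40% of treated cells are marker-positive
        marker = np.where(rng.random(1000) < 0.4, 2.0, 0.1)
        senescent = senescent.assign(c12fdg_mean=marker)
        normal = normal.assign(c12fdg_mean=rng.normal(0.1, 0.02, 1000))
        policy = LabelingPolicy(mode="marker", marker_channel="c12fdg_mean", threshold=1.0)
        n_eligible = int((marker > 1.0).sum())
        ts = build_training_set(
            normal, senescent, policy, n_per_class=n_eligible, seed=0
        )
        assert ts.class_counts[1] == n_eligible
        with pytest.raises(SizingError):
            build_training_set(normal, senescent, policy, n_per_class=n_eligible + 1, seed=0)

    def test_marker_mode_percentile_threshold(self, rng):
        normal, senescent = _tables(n=500)
        normal = normal.assign(c12fdg_mean=rng.normal(1.0, 0.1, 500))
        senescent = senescent.assign(c12fdg_mean=rng.normal(3.0, 0.1, 500))
        policy = LabelingPolicy(mode="marker", marker_channel="c12fdg_mean")
        ts = build_training_set(normal, senescent, policy, n_per_class=400, seed=0)
        assert ts.class_counts == {0: 400, 1: 400}

    def test_marker_mode_requires_rule(self):
        with pytest.raises(ValueError, match="marker_channel"):
            LabelingPolicy(mode="marker")

    def test_multi_condition_equal_sampling(self):
        normal, senescent = _tables(n=2000)
        ts = build_training_set(
            {"a": normal, "b": normal.copy()},
            {"c": senescent, "d": senescent.copy(), "e": senescent.copy()},
            n_per_class=900,
            seed=0,
        )
        prov = ts.provenance["condition"].value_counts()
        assert prov["a"] == prov["b"] == 450
        assert prov["c"] == prov["d"] == prov["e"] == 300


class TestTrainTree:
    def _one_d_training_set(self, rng, separable=True, n=200):
        if separable:
            x0 = rng.uniform(0.0, 4.8, n)
            x1 = rng.uniform(5.2, 10.0, n)
        else:
            x0 = rng.uniform(0.0, 10.0, n)
            x1 = rng.uniform(0.0, 10.0, n)
        X = pd.DataFrame({"X": np.concatenate([x0, x1])})
        y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
        return TrainingSet(X=X, y=y, feature_set=ONE_D, provenance=pd.DataFrame({"condition": ["s"] * 2 * n, "labeling_mode": "assumption"}), seed=0)

    def test_separable_1d_gives_depth_one_tree_in_gap(self, rng):
        ts = self._one_d_training_set(rng)
        model = train_tree(ts, seed=0)
        tree = model.estimator.tree_
        assert model.estimator.get_depth() == 1
        threshold = tree.threshold[0]
        assert 4.8 < threshold < 5.2  # exhaustive split-point oracle: gap midzone
        assert model.metadata["holdout_accuracy"] == 1.0

    def test_independent_labels_collapse_to_prior(self):
        accs, leaves = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ts = self._one_d_training_set(rng, separable=False, n=300)
            model = train_tree(ts, seed=seed)
            accs.append(model.metadata["holdout_accuracy"])
            leaves.append(model.metadata["n_leaves"])
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)
        assert np.median(leaves) <= 3  # pruned toward the root

    def test_row_duplication_invariance(self, rng):
        ts = self._one_d_training_set(rng)
        t1 = fit_pruned_tree(ts.X, ts.y, alpha=0.0)
        t2 = fit_pruned_tree(
            pd.concat([ts.X, ts.X], ignore_index=True), np.tile(ts.y, 2), alpha=0.0
        )
        assert np.array_equal(t1.tree_.feature, t2.tree_.feature)
        assert np.allclose(t1.tree_.threshold, t2.tree_.threshold)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame({"X": rng.random(50)})
        ts = TrainingSet(X=X, y=np.zeros(50, int), feature_set=ONE_D,
                         provenance=pd.DataFrame({"condition": ["s"] * 50, "labeling_mode": "assumption"}), seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_tree(ts)
        with pytest.raises(ValueError, match="single class"):
            train_forest(ts)


class _StubTree:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)


def _stub_forest(labels, cutoff=0.5):
    est = type("E", (), {})()
    est.estimators_ = [_StubTree(v) for v in labels]
    return ClassifierModel(kind="forest", feature_set=ONE_D, estimator=est, cutoff=cutoff)


def _stub_tree_model(label):
    est = type("E", (), {})()
    est.predict = lambda X: np.full(len(X), label)
    return ClassifierModel(kind="tree", feature_set=ONE_D, estimator=est)


class TestForestAndPredict:
    def test_well_separated_gaussians(self):
        # 4-sigma class shift: Bayes accuracy ~0.977, forest should exceed 0.95
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"X": np.concatenate([rng.normal(0, 1, 400), rng.normal(4, 1, 400)])})
            y = np.concatenate([np.zeros(400, int), np.ones(400, int)])
            ts = TrainingSet(X=X, y=y, feature_set=ONE_D,
                             provenance=pd.DataFrame({"condition": ["s"] * 800, "labeling_mode": "assumption"}), seed=seed)
            model = train_forest(ts, n_estimators=50, seed=seed)
            accs.append(model.metadata["holdout_accuracy"])
        assert min(accs) >= 0.90
        assert np.mean(accs) >= 0.93

    def test_probability_at_cutoff_votes_zero(self):
        # 2-of-4 trees vote senescent: probability exactly 0.5, strict '>'
        model = _stub_forest([1, 1, 0, 0])
        table = pd.DataFrame({"X": [0.0, 1.0]})
        assert predict_proba(model, table).tolist() == [0.5, 0.5]
        assert predict(model, table).tolist() == [0, 0]

    def test_probability_above_cutoff_votes_one(self):
        model = _stub_forest([1, 1, 1, 0])
        assert predict(model, pd.DataFrame({"X": [0.0]})).tolist() == [1]

    def test_forest_determinism(self):
        normal, senescent = _tables(n=800)
        ts = build_training_set(normal, senescent, n_per_class=400, seed=1)
        m1 = train_forest(ts, n_estimators=30, seed=5)
        m2 = train_forest(ts, n_estimators=30, seed=5)
        table = normal.head(100)
        assert np.array_equal(predict(m1, table), predict(m2, table))

    def test_schema_mismatch_lists_missing(self):
        normal, senescent = _tables(n=500)
        ts = build_training_set(normal, senescent, n_per_class=200, seed=0)
        model = train_tree(ts, seed=0)
        with pytest.raises(SchemaMismatchError, match="GyrationRadius"):
            predict(model, normal.drop(columns=["GyrationRadius"]))


class TestEnsemble:
    def test_unanimous_vote(self):
        ens = ConsensusEnsemble([_stub_tree_model(1) for _ in range(8)])
        assert predict(ens, pd.DataFrame({"X": [0.0]})).tolist() == [1]

    def test_tie_votes_non_senescent(self):
        ens = ConsensusEnsemble([_stub_tree_model(1)] * 4 + [_stub_tree_model(0)] * 4)
        assert predict(ens, pd.DataFrame({"X": [0.0]})).tolist() == [0]

    def test_majority_five_of_eight(self):
        ens = ConsensusEnsemble([_stub_tree_model(1)] * 5 + [_stub_tree_model(0)] * 3)
        assert predict(ens, pd.DataFrame({"X": [0.0]})).tolist() == [1]

    def test_requires_two_members(self):
        with pytest.raises(ValueError, match="at least 2"):
            ConsensusEnsemble([_stub_tree_model(1)])


class TestWellSummary:
    def test_percentage(self):
        labels = np.array([1] * 30 + [0] * 70)
        wells = np.array(["A1"] * 100)
        out = summarize_wells(labels, wells)
        assert out.loc[0, "pct_senescent"] == 30.0

    def test_empty_well_flagged_not_zero(self):
        out = summarize_wells(np.array([1, 0]), np.array(["A1", "A1"]), all_wells=["A1", "B1"])
        b1 = out[out["well"] == "B1"].iloc[0]
        assert bool(b1["empty"])
        assert np.isnan(b1["pct_senescent"])

    def test_count_conservation(self, rng):
        labels = rng.integers(0, 2, 500)
        wells = rng.choice(["A1", "A2", "B3"], 500)
        out = summarize_wells(labels, wells)
        assert out["n_cells"].sum() == 500


class TestSerialization:
    def test_round_trip_identical_predictions(self, tmp_path):
        normal, senescent = _tables(n=600)
        ts = build_training_set(normal, senescent, n_per_class=300, seed=0)
        for trainer in (lambda: train_tree(ts, seed=0),
                        lambda: train_forest(ts, n_estimators=20, seed=0)):
            model = trainer()
            path = tmp_path / "model.joblib"
            save_model(model, path)
            loaded = load_model(path)
            table = normal.head(200)
            assert np.array_equal(predict(model, table), predict(loaded, table))
            assert loaded.feature_set.name == CORE7.name
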