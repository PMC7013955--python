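"""Policy set-algebra, SVM training, hierarchical routing, persistence."""

import numpy as np
import pytest

from kelpcover.annotations import AnnotationTable, PointAnnotation
from kelpcover.errors import (
    CompatibilityError,
    PolicyError,
    StratificationError,
    TrainingError,
)
from kelpcover.features import FeatureMatrix
from kelpcover.hierclf import (
    NodeModel,
    TrainConfig,
    TrainingPolicy,
    build_node_training_set,
    load_model,
    predict_flat,
    predict_hierarchical,
    predict_node,
    save_model,
    train_flat,
    train_hierarchical,
    train_linear_svm,
)

FAST_CFG = TrainConfig(C_grid=(0.1, 1.0), seed=0)


class TestNodeTrainingSets:
    def test_sibling_at_kelp(self, toy_table, toy_tree):
        idx, y, info = build_node_training_set(
            toy_table, toy_tree, TrainingPolicy("sibling", "1.1.1")
        )
        assert (info["n_pos"], info["n_neg"]) == (4, 3)
        assert set(toy_table.labels[idx[y == 1]]) == {"kelp"}
        assert set(toy_table.labels[idx[y == 0]]) == {"scytothalia"}

    def test_inclusive_at_kelp(self, toy_table, toy_tree):
        idx, y, info = build_node_training_set(
            toy_table, toy_tree, TrainingPolicy("inclusive", "1.1.1")
        )
        assert (info["n_pos"], info["n_neg"]) == (4, 8)
        assert set(toy_table.labels[idx[y == 0]]) == {"scytothalia", "coral", "sand"}

    def test_sibling_equals_inclusive_when_parent_is_root(self, toy_table, toy_tree):
        sib = build_node_training_set(toy_table, toy_tree, TrainingPolicy("sibling", "1.1"))
        inc = build_node_training_set(toy_table, toy_tree, TrainingPolicy("inclusive", "1.1"))
        np.testing.assert_array_equal(sib[0], inc[0])
        np.testing.assert_array_equal(sib[1], inc[1])

    def test_root_target_rejected(self, toy_table, toy_tree):
        with pytest.raises(PolicyError):
            build_node_training_set(toy_table, toy_tree, TrainingPolicy("sibling", "1"))

    def test_unassigned_labels_excluded_and_counted(self, toy_tree):
        points = [
            PointAnnotation("im0", x=i, y=0, label=lab)
            for i, lab in enumerate(["kelp", "kelp", "mystery-taxon", "sand"])
        ]
        table = AnnotationTable.from_points(points)
        idx, y, info = build_node_training_set(
            table, toy_tree, TrainingPolicy("inclusive", "1.1.1")
        )
        assert info["n_unassigned"] == 1
        assert len(idx) == 3  # the mystery taxon row is excluded

    def test_sibling_subset_of_inclusive_on_random_trees(self):
        from conftest import random_tree_and_table

        rng = np.random.default_rng(1234)
        checked = 0
        for _ in range(100):
            tree, table = random_tree_and_table(rng)
            for node_id in tree.iter_nonroot():
                sib_idx, sib_y, _ = build_node_training_set(
                    table, tree, TrainingPolicy("sibling", node_id)
                )
                inc_idx, inc_y, _ = build_node_training_set(
                    table, tree, TrainingPolicy("inclusive", node_id)
                )
                assert set(sib_idx) <= set(inc_idx)
                # positives agree exactly between the policies
                np.testing.assert_array_equal(sib_idx[sib_y == 1], inc_idx[inc_y == 1])
                assert len(sib_idx) <= len(inc_idx)
                checked += 1
        assert checked > 100


def _blobs(rng, n=60, d=2, sep=6.0):
    X = np.vstack(
        [rng.standard_normal((n, d)), rng.standard_normal((n, d)) + sep]
    )
    y = np.repeat([0, 1], n)
    return X, y


class TestLinearSVM:
    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng)
        model = train_linear_svm(X, y, FAST_CFG)
        pred, _ = predict_node(model, X)
        assert np.mean(pred == y) == 1.0
        cv_means = [np.mean(s) for s in model.fold_scores.values()]
        assert max(cv_means) >= 0.95

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(TrainingError):
            train_linear_svm(X, np.zeros(10, dtype=int), FAST_CFG)

    def test_tiny_class_stratification_error_names_class(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(StratificationError, match="1"):
            train_linear_svm(X, y, TrainConfig(n_folds=3))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        X, y = _blobs(rng, sep=2.0)
        m1 = train_linear_svm(X, y, TrainConfig(seed=11))
        m2 = train_linear_svm(X, y, TrainConfig(seed=11))
        assert m1.best_C == m2.best_C
        np.testing.assert_array_equal(m1.coef, m2.coef)
        np.testing.assert_array_equal(m1.intercept, m2.intercept)

    def test_tie_breaks_toward_smallest_C(self):
        # perfectly separable data: every C scores 1.0, so the smallest wins
        rng = np.random.default_rng(7)
        X, y = _blobs(rng, sep=20.0)
        model = train_linear_svm(X, y, TrainConfig(C_grid=(0.01, 1.0, 100.0)))
        means = {C: np.mean(s) for C, s in model.fold_scores.items()}
        assert len(set(means.values())) == 1
        assert model.best_C == 0.01


class TestPredictNode:
    @staticmethod
    def _manual_model(w, b):
        return NodeModel(
            node_id="n", policy_kind="sibling", classes_=[0, 1],
            coef=np.atleast_2d(np.asarray(w, float)),
            intercept=np.atleast_1d(float(b)),
            best_C=1.0, fold_scores={}, extractor_id="",
        )

    def test_zero_score_counts_positive(self):
        model = self._manual_model([1.0, 0.0], 0.0)
        labels, scores = predict_node(model, np.array([[0.0, 5.0]]))
        assert scores[0] == 0.0 and labels[0] == 1

    def test_empty_input(self):
        model = self._manual_model([1.0], 0.0)
        labels, scores = predict_node(model, np.empty((0, 1)))
        assert labels.size == 0 and scores.size == 0

    def test_dim_mismatch_rejected(self):
        model = self._manual_model([1.0, 2.0], 0.0)
        with pytest.raises(CompatibilityError):
            predict_node(model, np.zeros((3, 5)))


def _toy_features(table, rng, centers):
    """2-D features: one Gaussian blob per label, from a center map."""
    X = np.stack([centers[lab] for lab in table.labels]) + 0.3 * rng.standard_normal(
        (len(table), 2)
    )
    return FeatureMatrix(X, "toy")


def _big_toy_table(rng, counts):
    points = []
    k = 0
    for lab, n in counts.items():
        for _ in range(n):
            points.append(PointAnnotation(f"im{k % 5}", x=k, y=0, label=lab))
            k += 1
    return AnnotationTable.from_points(points)


CENTERS = {
    "kelp": np.array([0.0, 0.0]),
    "scytothalia": np.array([6.0, 0.0]),
    "turf": np.array([0.0, 6.0]),
    "coral": np.array([6.0, 6.0]),
    "sand": np.array([-6.0, 6.0]),
}


class TestHierarchicalTraining:
    def test_models_for_every_populated_node(self, toy_tree):
        rng = np.random.default_rng(0)
        table = _big_toy_table(rng, {"kelp": 12, "scytothalia": 9, "coral": 6, "sand": 9})
        features = _toy_features(table, rng, CENTERS)
        hm = train_hierarchical(table, features, toy_tree, "sibling", FAST_CFG)
        assert {"1.1", "1.1.1", "1.1.2", "1.2"} <= set(hm.node_models)
        assert hm.skipped == {}

    def test_empty_node_skipped_with_reason(self, toy_tree):
        rng = np.random.default_rng(1)
        # no macroalgae other than kelp: the kelp node has no sibling negatives
        table = _big_toy_table(rng, {"kelp": 12, "coral": 6, "sand": 9})
        features = _toy_features(table, rng, CENTERS)
        hm = train_hierarchical(table, features, toy_tree, "sibling", FAST_CFG)
        assert "1.1.1" in hm.skipped
        assert "negatives" in hm.skipped["1.1.1"]

    def test_sibling_sets_never_larger_than_inclusive(self, toy_tree):
        rng = np.random.default_rng(2)
        table = _big_toy_table(
            rng, {"kelp": 12, "scytothalia": 9, "turf": 6, "coral": 6, "sand": 9}
        )
        for node_id in toy_tree.iter_nonroot():
            sib = build_node_training_set(table, toy_tree, TrainingPolicy("sibling", node_id))
            inc = build_node_training_set(table, toy_tree, TrainingPolicy("inclusive", node_id))
            assert len(sib[0]) <= len(inc[0])


class TestFlat:
    def test_three_class_blobs_high_accuracy(self):
        rng = np.random.default_rng(3)
        table = _big_toy_table(rng, {"kelp": 30, "scytothalia": 30, "sand": 30})
        features = _toy_features(table, rng, CENTERS)
        model = train_flat(table, features, FAST_CFG)
        labels, _ = predict_flat(model, features.values)
        assert np.mean(labels == table.labels) >= 0.95

    def test_exact_tie_goes_to_lexicographically_first(self):
        model = NodeModel(
            node_id="__flat__", policy_kind="flat", classes_=["algae", "sand"],
            coef=np.zeros((2, 2)), intercept=np.zeros(2),
            best_C=1.0, fold_scores={}, extractor_id="",
        )
        labels, scores = predict_flat(model, np.array([[1.0, 1.0]]))
        assert scores[0, 0] == scores[0, 1]
        assert labels[0] == "algae"


class TestHierarchicalPrediction:
    @pytest.fixture()
    def trained(self, toy_tree):
        rng = np.random.default_rng(4)
        table = _big_toy_table(
            rng, {"kelp": 15, "scytothalia": 12, "turf": 9, "coral": 9, "sand": 12}
        )
        features = _toy_features(table, rng, CENTERS)
        hm = train_hierarchical(table, features, toy_tree, "sibling", FAST_CFG)
        return hm, table, features

    def test_node_only_equals_predict_node(self, trained):
        hm, table, features = trained
        records = predict_hierarchical(hm, features.values, mode="node_only", target_node="1.1.1")
        y01, _ = predict_node(hm.node_models["1.1.1"], features.values)
        got = np.array(["1.1.1" in r.node_path for r in records], dtype=int)
        np.testing.assert_array_equal(got, y01)

    def test_top_down_is_hierarchy_consistent(self, trained):
        hm, table, features = trained
        for rec in predict_hierarchical(hm, features.values, mode="top_down"):
            path = rec.node_path
            assert path[0] == hm.tree.root_id
            for parent, child in zip(path, path[1:]):
                assert child in hm.tree.node(parent).children
                assert rec.node_scores[child] >= 0.0

    def test_top_down_matches_brute_force_routing(self, trained):
        hm, table, features = trained
        X = features.values

        def brute_route(x):
            cur = hm.tree.root_id
            while True:
                best, best_score = None, None
                for child in hm.tree.node(cur).children:
                    if child not in hm.node_models:
                        continue
                    score = float(
                        hm.node_models[child].decision_scores(x[None, :])[0, 0]
                    )
                    if score >= 0.0 and (best is None or score > best_score):
                        best, best_score = child, score
                if best is None:
                    return cur
                cur = best

        records = predict_hierarchical(hm, X, mode="top_down")
        for i, rec in enumerate(records):
            assert rec.node_path[-1] == brute_route(X[i])

    def test_rejected_at_macroalgae_never_labeled_kelp(self, trained):
        hm, table, features = trained
        for rec in predict_hierarchical(hm, features.values, mode="top_down"):
            if "1.1" not in rec.node_path:
                assert "1.1.1" not in rec.node_path


class TestPersistence:
    def test_hier_model_round_trip(self, toy_tree, tmp_path):
        rng = np.random.default_rng(6)
        table = _big_toy_table(rng, {"kelp": 12, "scytothalia": 9, "coral": 6, "sand": 9})
        features = _toy_features(table, rng, CENTERS)
        hm = train_hierarchical(table, features, toy_tree, "inclusive", FAST_CFG)
        path = tmp_path / "model.zip"
        save_model(hm, path)
        loaded = load_model(path)
        assert loaded.policy_kind == "inclusive"
        assert set(loaded.node_models) == set(hm.node_models)
        for nid in hm.node_models:
            np.testing.assert_array_equal(loaded.node_models[nid].coef, hm.node_models[nid].coef)
            assert loaded.node_models[nid].best_C == hm.node_models[nid].best_C
        r1 = predict_hierarchical(hm, features.values, mode="top_down")
        r2 = predict_hierarchical(loaded, features.values, mode="top_down")
        assert [r.node_path for r in r1] == [r.node_path for r in r2]

    def test_flat_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        table = _big_toy_table(rng, {"kelp": 15, "sand": 15})
        features = _toy_features(table, rng, CENTERS)
        model = train_flat(table, features, FAST_CFG)
        save_model(model, tmp_path / "flat.zip")
        loaded = load_model(tmp_path / "flat.zip")
        l1, _ = predict_flat(model, features.values)
        l2, _ = predict_flat(loaded, features.values)
        np.testing.assert_array_equal(l1, l2)
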