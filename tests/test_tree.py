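"""CART with Gini splitting: oracle agreement, invariants, posture tree."""

import numpy as np
import pandas as pd
import pytest

from sedmet.synth import GeneratorConfig, ParticipantProfile, generate_study, simulate_accel
from sedmet.tree import (
    GiniTreeClassifier,
    PostureThresholds,
    PostureTreeClassifier,
    gini_impurity,
    posture_tree,
)


def brute_force_best_split(X, y):
    """Independent exhaustive enumerator of every (feature, midpoint) split.

    Returns (feature, threshold, decrease) with ties broken toward lower
    feature index then lower threshold, or None if no split improves Gini.
    """
    n = len(y)
    classes = np.unique(y)

    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = np.array([np.mean(labels == c) for c in classes])
        return 1.0 - np.sum(p * p)

    parent = gini(y)
    best = None
    for j in range(X.shape[1]):
        for v in np.unique(X[:, j])[:-1]:
            uniq = np.unique(X[:, j])
            t = 0.5 * (v + uniq[uniq > v][0])
            left = X[:, j] < t
            nl, nr = left.sum(), n - left.sum()
            if nl == 0 or nr == 0:
                continue
            dec = parent - (nl * gini(y[left]) + nr * gini(y[~left])) / n
            if best is None or dec > best[2]:
                best = (j, t, dec)
    if best is None or best[2] <= 0:
        return None
    return best


class TestGini:
    def test_balanced_binary_node_is_half(self):
        assert gini_impurity([50, 50]) == pytest.approx(0.5)

    def test_pure_node_is_zero(self):
        assert gini_impurity([10, 0]) == 0.0

    def test_three_class_uniform(self):
        assert gini_impurity([5, 5, 5]) == pytest.approx(1 - 3 * (1 / 3) ** 2)


class TestFit:
    def test_one_dimensional_split_at_midpoint(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["A", "A", "B", "B"])
        est = GiniTreeClassifier(max_depth=5, min_leaf=1).fit(X, y)
        assert est.tree_.threshold == pytest.approx(1.5)
        assert np.all(est.predict(X) == y)

    def test_root_split_matches_brute_force_on_100_random_datasets(self):
        rng = np.random.default_rng(2024)
        for rep in range(100):
            n = int(rng.integers(8, 30))
            X = rng.normal(size=(n, 3)).round(2)  # rounding forces ties
            y = rng.choice(["active", "inactive"], size=n)
            oracle = brute_force_best_split(X, y)
            est = GiniTreeClassifier(max_depth=1, min_leaf=1).fit(X, y)
            if oracle is None:
                assert est.tree_.is_leaf
            else:
                assert not est.tree_.is_leaf, f"rep {rep}"
                assert est.tree_.feature == oracle[0], f"rep {rep}"
                assert est.tree_.threshold == pytest.approx(oracle[1]), f"rep {rep}"

    def test_perfect_training_fit_without_conflicts(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 1] + 0.3 * X[:, 2] > 0).astype(str)
        est = GiniTreeClassifier(max_depth=100, min_leaf=1).fit(X, y)
        assert np.mean(est.predict(X) == y) == 1.0

    def test_monotone_feature_transform_preserves_predictions(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.choice(["a", "b"], size=40)
        Xt = X.copy()
        Xt[:, 1] = np.exp(X[:, 1])  # strictly monotone
        a = GiniTreeClassifier(max_depth=3, min_leaf=2).fit(X, y)
        b = GiniTreeClassifier(max_depth=3, min_leaf=2).fit(Xt, y)
        Xnew = rng.normal(size=(30, 3))
        Xnew_t = Xnew.copy()
        Xnew_t[:, 1] = np.exp(Xnew[:, 1])
        assert np.all(a.predict(Xnew) == b.predict(Xnew_t))

    def test_empty_and_single_class_rejected(self):
        with pytest.raises(ValueError):
            GiniTreeClassifier().fit(np.empty((0, 2)), np.array([]))
        with pytest.raises(ValueError):
            GiniTreeClassifier().fit(np.zeros((5, 2)), np.array(["a"] * 5))

    def test_every_accepted_split_decreases_gini(self, rng):
        X = rng.normal(size=(80, 4))
        y = rng.choice(["a", "b"], size=80)
        est = GiniTreeClassifier(max_depth=6, min_leaf=2).fit(X, y)

        def walk(node, Xn, yn):
            if node.is_leaf:
                return
            left = Xn[:, node.feature] < node.threshold
            parent = gini_impurity([np.sum(yn == c) for c in est.classes_])
            child = (
                left.sum() * gini_impurity([np.sum(yn[left] == c) for c in est.classes_])
                + (~left).sum() * gini_impurity([np.sum(yn[~left] == c) for c in est.classes_])
            ) / len(yn)
            assert parent - child > 0
            walk(node.left, Xn[left], yn[left])
            walk(node.right, Xn[~left], yn[~left])

        walk(est.tree_, X, y)


class TestPredictScore:
    def test_leaf_fractions(self):
        X = np.array([[0.0], [0.2], [2.0], [2.1], [2.2], [2.3]])
        y = np.array(["active", "active", "inactive", "inactive", "inactive", "active"])
        est = GiniTreeClassifier(max_depth=1, min_leaf=2).fit(X, y)
        scores = est.predict_score(X, positive_class="inactive")
        assert set(np.round(scores, 3)) == {0.0, 0.75}

    def test_predict_agrees_with_argmax_score(self, rng):
        for _ in range(20):
            X = rng.normal(size=(50, 3))
            y = rng.choice(["x", "y"], size=50)
            est = GiniTreeClassifier(max_depth=4, min_leaf=2).fit(X, y)
            Xn = rng.normal(size=(20, 3))
            s = est.predict_score(Xn, positive_class="y")
            pred = est.predict(Xn)
            # at exact 0.5 the argmax tie-break decides; exclude those
            decisive = s != 0.5
            assert np.all((s[decisive] > 0.5) == (pred[decisive] == "y"))

    def test_missing_split_feature_raises(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0], "f2": [1, 1, 1, 1]})
        y = np.array(["a", "a", "b", "b"])
        est = GiniTreeClassifier(min_leaf=1).fit(X, y)
        assert est.used_features_ == ("f1",)
        with pytest.raises(ValueError, match="split feature"):
            est.predict(pd.DataFrame({"f2": [1.0]}))


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        y = rng.choice(["active", "inactive"], size=60)
        est = GiniTreeClassifier(max_depth=3, min_leaf=2).fit(X, y)
        est.save(tmp_path / "tree.json")
        back = GiniTreeClassifier.load(tmp_path / "tree.json")
        Xn = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        assert np.all(est.predict(Xn) == back.predict(Xn))
        np.testing.assert_allclose(
            est.predict_score(Xn, "inactive"), back.predict_score(Xn, "inactive")
        )


class TestPostureTree:
    def test_horizontal_thigh_is_sitting(self):
        clf = posture_tree()
        assert clf.classify_minute(np.zeros(1800)) == "sitting"

    def test_quiet_vertical_thigh_is_standing(self):
        clf = posture_tree()
        assert clf.classify_minute(np.full(1800, -1.0)) == "standing"

    def test_sitting_rule_boundary(self):
        clf = posture_tree()
        assert clf.classify_minute(np.full(1800, -0.774)) == "sitting"
        assert clf.classify_minute(np.full(1800, -0.9)) == "standing"

    def test_walking_minutes_from_generator_all_classified_walking(self):
        config = GeneratorConfig(seed=5)
        profile = ParticipantProfile("P01", 1.4, (1.0,) * 8, 1.8)
        clf = posture_tree()
        rng = np.random.default_rng(42)
        for _ in range(100):
            rec = simulate_accel("walking", 60.0, profile, config, rng)
            assert clf.classify_minute(rec.y) == "walking"

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            PostureThresholds(sit_threshold=-1.5, walk_accel_threshold=-1.35)

    def test_deceleration_branch_catches_slow_walking(self):
        # 5th percentile inside the standing band but 95th above the band:
        # node 3 must still call it walking
        clf = PostureTreeClassifier(
            sit_threshold=-0.774, walk_accel_threshold=-1.35, walk_decel_threshold=-0.85
        )
        pred = clf.predict(pd.DataFrame({"accel.y.p5": [-1.2], "accel.y.p95": [-0.5]}))
        assert pred[0] == "walking"
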