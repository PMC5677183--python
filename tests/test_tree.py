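"""Gini impurity, exhaustive splitting, stopping rules, fixed reference tree."""

import numpy as np
import pandas as pd
import pytest

from edaflow.tree import (TreeModel, best_split, gini, grow, predict,
                          reference_tree, tree_cv)


def labelled_table(rng, n=40, informative_shift=2.0):
    y = np.where(rng.random(n) < 0.5, "distress", "calm")
    shift = np.where(y == "distress", informative_shift, 0.0)
    return pd.DataFrame({
        "SDSC": rng.normal(size=n) + shift,
        "SKSC": rng.normal(size=n),
        "condition": y,
    })


class TestGini:
    def test_pure_node_is_zero_exactly(self):
        assert gini(["distress"] * 7) == 0.0
        assert gini(["calm"]) == 0.0
        assert gini(["calm"] * 3, method="lorenz") == 0.0

    def test_balanced_node_is_half(self):
        assert gini(["calm", "distress"] * 4) == pytest.approx(0.5)

    def test_lorenz_variant_reaches_one(self):
        assert gini(["calm", "distress"] * 4, method="lorenz") == pytest.approx(1.0)

    def test_symmetry_and_maximum_at_equal_proportions(self):
        for k in range(1, 10):
            labels = ["distress"] * k + ["calm"] * (10 - k)
            flipped = ["calm"] * k + ["distress"] * (10 - k)
            assert gini(labels) == pytest.approx(gini(flipped))
            assert gini(labels) <= 0.5 + 1e-12

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini([])


def brute_force_split(X, y):
    """Naive enumeration of every (feature, midpoint) split."""

    def impurity(lbls):
        if len(lbls) == 0:
            return 0.0
        p = np.mean(lbls == "distress")
        return 1.0 - p ** 2 - (1 - p) ** 2

    n = len(y)
    parent = impurity(y)
    best = None
    for feat in sorted(X.columns):
        v = X[feat].to_numpy(float)
        for thr in (np.unique(v)[:-1] + np.unique(v)[1:]) / 2:
            left = v <= thr
            dec = parent - (left.sum() * impurity(y[left])
                            + (~left).sum() * impurity(y[~left])) / n
            if best is None or dec > best[2] + 1e-12:
                best = (feat, thr, dec)
    return best


class TestBestSplit:
    def test_perfect_separator_chosen_with_full_decrease(self, rng):
        X = pd.DataFrame({"SDSC": [1.0, 2.0, 10.0, 11.0], "SKSC": [5.0, 1.0, 4.0, 2.0]})
        y = np.array(["calm", "calm", "distress", "distress"])
        feat, thr, dec = best_split(X, y)
        assert feat == "SDSC"
        assert 2.0 < thr < 10.0
        assert dec == pytest.approx(0.5)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 16))
            X = pd.DataFrame({
                "A": rng.integers(0, 6, size=n).astype(float),
                "B": rng.integers(0, 6, size=n).astype(float),
                "C": rng.integers(0, 6, size=n).astype(float),
            })
            y = np.where(rng.random(n) < 0.5, "distress", "calm")
            got = best_split(X, y)
            want = brute_force_split(X, y)
            if want is None or want[2] <= 0:
                assert got is None or got[2] <= max(w[2] for w in [want] if w) + 1e-12
                continue
            assert got[2] == pytest.approx(want[2], abs=1e-12)
            assert (got[0], got[1]) == (want[0], pytest.approx(want[1]))

    def test_duplicate_columns_resolved_by_name_order(self, rng):
        v = rng.normal(size=12)
        y = np.where(v > 0, "distress", "calm")
        X = pd.DataFrame({"B": v, "A": v})
        feat, _, _ = best_split(X, y)
        assert feat == "A"

    def test_constant_features_give_no_split(self):
        X = pd.DataFrame({"A": np.ones(8)})
        y = np.array(["calm", "distress"] * 4)
        assert best_split(X, y) is None


class TestGrow:
    def test_pure_input_rejected_at_root(self, rng):
        table = labelled_table(rng)
        table["condition"] = "calm"
        with pytest.raises(ValueError):
            grow(table)

    def test_stopping_rules_never_violated(self, rng):
        for _ in range(25):
            table = labelled_table(rng, n=int(rng.integers(20, 120)),
                                   informative_shift=float(rng.uniform(0, 3)))
            model = grow(table)
            bound = 0.20 * len(table)

            def check(node):
                if node.is_leaf:
                    return
                assert node.gini > 0.0
                assert node.n_samples >= bound
                assert node.left.n_samples + node.right.n_samples == node.n_samples
                assert node.left.n_samples >= 1 and node.right.n_samples >= 1
                check(node.left)
                check(node.right)

            check(model.root)

    def test_twenty_percent_rule_on_n100(self, rng):
        table = labelled_table(rng, n=100, informative_shift=0.5)
        model = grow(table)

        def smallest_split_node(node):
            if node.is_leaf:
                return np.inf
            return min(node.n_samples,
                       smallest_split_node(node.left), smallest_split_node(node.right))

        assert smallest_split_node(model.root) >= 20

    def test_split_decreases_weighted_child_impurity(self, rng):
        table = labelled_table(rng, n=60)
        model = grow(table)

        def check(node):
            if node.is_leaf:
                return
            n = node.n_samples
            w = (node.left.n_samples * node.left.gini
                 + node.right.n_samples * node.right.gini) / n
            assert w < node.gini + 1e-12
            check(node.left)
            check(node.right)

        check(model.root)

    def test_single_informative_feature_recovered_at_root(self, rng):
        table = labelled_table(rng, n=80, informative_shift=4.0)
        model = grow(table)
        assert model.root.feature == "SDSC"
        assert abs(model.root.threshold - 2.0) < 1.5

    def test_training_accuracy_at_least_majority(self, rng):
        table = labelled_table(rng, n=50, informative_shift=1.0)
        model = grow(table)
        labels, _ = predict(model, table)
        acc = np.mean(labels == table["condition"].to_numpy())
        majority = max((table["condition"] == "calm").mean(),
                       (table["condition"] == "distress").mean())
        assert acc >= majority

    def test_agrees_with_sklearn_root_split(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        table = labelled_table(rng, n=60, informative_shift=2.5)
        model = grow(table)
        clf = DecisionTreeClassifier(max_depth=1, random_state=0)
        clf.fit(table[["SDSC", "SKSC"]], table["condition"])
        sk_feature = ["SDSC", "SKSC"][clf.tree_.feature[0]]
        assert model.root.feature == sk_feature
        assert model.root.threshold == pytest.approx(clf.tree_.threshold[0], abs=1e-6)


class TestReferenceTree:
    def test_distress_typical_values_classified_distress(self):
        model = reference_tree()
        rows = pd.DataFrame([{"SDSC": 12.52, "SKSC": 3.11}])
        labels, _ = predict(model, rows)
        assert labels[0] == "distress"

    def test_boundary_value_routes_left(self):
        model = reference_tree()
        # exactly at the root threshold: <= goes to the SKSC subtree
        low_sksc = pd.DataFrame([{"SDSC": 4.4830, "SKSC": 0.0}])
        high_sksc = pd.DataFrame([{"SDSC": 4.4830, "SKSC": 5.0}])
        assert predict(model, low_sksc)[0][0] == "calm"
        assert predict(model, high_sksc)[0][0] == "distress"

    def test_flip_inverts_every_prediction(self, rng):
        rows = pd.DataFrame({"SDSC": rng.normal(5, 4, 30), "SKSC": rng.normal(3, 1, 30)})
        a, _ = predict(reference_tree(), rows)
        b, _ = predict(reference_tree(flip=True), rows)
        assert np.all(a != b)

    def test_structure(self):
        model = reference_tree()
        assert model.root.feature == "SDSC"
        assert model.root.threshold == pytest.approx(4.4830)
        assert model.root.left.feature == "SKSC"
        assert model.root.left.threshold == pytest.approx(3.1102)
        assert model.root.right.is_leaf


class TestPredictAndSerialize:
    def test_single_leaf_model_constant(self, rng):
        from edaflow.tree import TreeNode

        model = TreeModel(root=TreeNode(n_samples=10, gini=0.0, klass="calm"))
        rows = pd.DataFrame({"SDSC": rng.normal(size=5)})
        labels, paths = predict(model, rows)
        assert set(labels) == {"calm"}
        assert all(p == ["calm"] for p in paths)

    def test_hand_traced_paths(self):
        model = reference_tree()
        rows = pd.DataFrame([{"SDSC": 2.0, "SKSC": 4.0}, {"SDSC": 9.0, "SKSC": 0.0}])
        labels, paths = predict(model, rows)
        assert paths[0] == ["SDSC<=4.483", "SKSC>3.1102", "distress"]
        assert paths[1] == ["SDSC>4.483", "distress"]

    def test_missing_feature_is_schema_error(self):
        with pytest.raises(KeyError):
            predict(reference_tree(), pd.DataFrame([{"SDSC": 1.0}]))

    def test_json_round_trip(self, rng):
        table = labelled_table(rng, n=40)
        model = grow(table, seed=3)
        clone = TreeModel.from_json(model.to_json())
        rows = labelled_table(rng, n=20)
        a, _ = predict(model, rows)
        b, _ = predict(clone, rows)
        assert np.array_equal(a, b)


def test_tree_cv_reports_both_phases(rng):
    table = labelled_table(rng, n=60, informative_shift=2.0)
    table["subject_id"] = [f"S{i}" for i in range(len(table))]
    res = tree_cv(table[["SDSC", "SKSC", "condition", "subject_id"]], k=5, repeats=1, seed=2)
    assert set(res) == {"learn_se", "learn_sp", "learn_acc", "test_se", "test_sp", "test_acc"}
    assert res["learn_acc"] >= res["test_acc"] - 5.0
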