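"""CART tree: Gini math, split search, one-use rule, prediction, LOSO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from tcmdetect import (
    DecisionTreeModel,
    EvaluationReport,
    GiniTreeClassifier,
    best_split,
    fit_cart,
    gini_index,
    loso_evaluate,
    predict,
)
from tcmdetect.selection import _ArrayMatrix


def labels(*xs):
    return np.array(["CPE" if x == 0 else "TCM" for x in xs], dtype=object)


def naive_best_split(values, y):
    """Transparent reference: try every midpoint with explicit loops."""
    values = np.asarray(values, dtype=float)
    distinct = sorted(set(values))
    if len(distinct) < 2:
        return None
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2.0
        out = []
        for side in (values < thr, values >= thr):
            sub = y[side]
            n = len(sub)
            p = np.mean(sub == "TCM") if n else 0.0
            out.append((n, 1.0 - p**2 - (1 - p) ** 2))
        (nl, gl), (nr, gr) = out
        wg = (nl * gl + nr * gr) / (nl + nr)
        if best is None or wg < best[1] - 1e-12:
            best = (thr, wg)
    return best


class TestGiniIndex:
    @pytest.mark.parametrize(
        "props,expected",
        [((0.5, 0.5), 0.5), ((1.0, 0.0), 0.0), ((0.75, 0.25), 0.375)],
    )
    def test_values(self, props, expected):
        assert gini_index(props) == pytest.approx(expected)

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            gini_index([0.7, 0.7])
        with pytest.raises(ValueError):
            gini_index([1.5, -0.5])
        with pytest.raises(ValueError):
            gini_index([])

    @settings(max_examples=50, deadline=None)
    @given(p=st.floats(0.0, 1.0))
    def test_binary_bounds(self, p):
        g = gini_index([p, 1.0 - p])
        assert 0.0 <= g <= 0.5 + 1e-12


class TestBestSplit:
    def test_clean_separation(self):
        thr, wg = best_split(np.array([1.0, 2.0, 3.0, 4.0]), labels(0, 0, 1, 1))
        assert thr == pytest.approx(2.5)
        assert wg == pytest.approx(0.0)

    def test_pure_node_has_no_split(self):
        assert best_split(np.array([1.0, 2.0]), labels(0, 0)) is not None  # split exists
        assert best_split(np.array([1.0, 1.0]), labels(0, 1)) is None  # constant feature

    def test_alternating_labels_match_bruteforce(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        y = labels(0, 1, 0, 1)
        thr, wg = best_split(v, y)
        ref_thr, ref_wg = naive_best_split(v, y)
        assert wg == pytest.approx(ref_wg)
        assert thr == pytest.approx(ref_thr)
        assert wg > 0.0

    def test_tie_breaks_to_smallest_threshold(self):
        # symmetric data: thresholds 1.5 and 2.5 give equal weighted Gini
        v = np.array([1.0, 2.0, 3.0])
        y = labels(0, 1, 0)
        thr, _ = best_split(v, y)
        assert thr == pytest.approx(1.5)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_naive_reference_on_random_data(self, data):
        n = data.draw(st.integers(2, 12))
        v = np.array(data.draw(st.lists(st.integers(0, 4), min_size=n, max_size=n)), dtype=float)
        y = np.array(data.draw(st.lists(st.sampled_from(["CPE", "TCM"]), min_size=n, max_size=n)), dtype=object)
        res = best_split(v, y)
        ref = naive_best_split(v, y)
        if ref is None:
            assert res is None
        else:
            assert res[1] == pytest.approx(ref[1])
            assert res[0] == pytest.approx(ref[0])


class TestFitCart:
    def test_separable_single_feature_gives_depth_one(self):
        X = pd.DataFrame({"f": [0.0, 0.1, 1.0, 1.1]})
        model = fit_cart(X, labels(0, 0, 1, 1), ["f"])
        assert not model.root.is_leaf
        assert model.root.left.is_leaf and model.root.right.is_leaf
        assert np.all(predict(model, X) == labels(0, 0, 1, 1))

    def test_and_truth_table_needs_two_features(self):
        X = pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0], "b": [0.0, 1.0, 0.0, 1.0]})
        y = labels(0, 0, 0, 1)  # TCM only when a AND b
        model = fit_cart(X, y, ["a", "b"])
        assert sorted(model.feature_order) == ["a", "b"]
        assert np.all(predict(model, X) == y)

    def test_pure_input_gives_single_leaf(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        model = fit_cart(X, labels(1, 1, 1), ["f"])
        assert model.root.is_leaf and model.root.leaf_class == "TCM"

    def test_empty_feature_set_gives_majority_leaf(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        model = fit_cart(X, labels(0, 1, 1), [])
        assert model.root.is_leaf and model.root.leaf_class == "TCM"

    def test_leaf_majority_tie_goes_to_cpe(self):
        X = pd.DataFrame({"f": [1.0, 1.0]})
        model = fit_cart(X, labels(0, 1), ["f"])  # constant feature: no split
        assert model.root.is_leaf and model.root.leaf_class == "CPE"

    def test_global_one_use_consumes_features_across_subtrees(self):
        # XOR labels: under the global rule, at most 2 internal nodes exist
        X = pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0], "b": [0.0, 1.0, 0.0, 1.0]})
        y = labels(0, 1, 1, 0)
        model = fit_cart(X, y, ["a", "b"])
        assert len(model.feature_order) == len(set(model.feature_order))

    def test_per_path_mode_may_reuse_across_branches(self):
        X = pd.DataFrame(
            {"a": [0.0, 0.0, 1.0, 1.0, 2.0, 2.0], "b": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]}
        )
        y = labels(0, 1, 1, 0, 0, 1)
        clf = GiniTreeClassifier(one_use="path").fit(X, y)
        counts: dict[str, int] = {}
        for name in clf.model_.feature_order:
            counts[name] = counts.get(name, 0) + 1
        assert max(counts.values()) >= 1  # b may appear in both branches

    def test_split_never_increases_impurity(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = np.where(rng.random(40) < 0.5, "CPE", "TCM").astype(object)
        model = fit_cart(X, y, ["a", "b", "c"])

        def walk(node):
            if node.is_leaf:
                return
            nl, nr = sum(node.left.class_counts), sum(node.right.class_counts)
            wg = (nl * node.left.gini + nr * node.right.gini) / (nl + nr)
            assert wg <= node.gini + 1e-12
            walk(node.left)
            walk(node.right)

        walk(model.root)


class TestPredict:
    def test_value_at_split_goes_right(self):
        X = pd.DataFrame({"f": [0.0, 1.0]})
        model = fit_cart(X, labels(0, 1), ["f"])
        thr = model.root.split_value
        assert predict(model, {"f": thr})[0] == model.root.right.leaf_class

    def test_training_rows_of_zero_error_tree_get_own_labels(self):
        X = pd.DataFrame({"f": [0.0, 0.2, 0.9, 1.0]})
        y = labels(0, 0, 1, 1)
        model = fit_cart(X, y, ["f"])
        assert np.all(predict(model, X) == y)

    def test_missing_feature_rejected(self):
        X = pd.DataFrame({"f": [0.0, 1.0]})
        model = fit_cart(X, labels(0, 1), ["f"])
        with pytest.raises(ValueError):
            predict(model, pd.DataFrame({"g": [0.5]}))

    def test_json_round_trip_preserves_predictions(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        y = np.where(X["a"] + 0.3 * X["b"] > 0, "TCM", "CPE").astype(object)
        model = fit_cart(X, y, ["a", "b"])
        back = DecisionTreeModel.from_json(model.to_json())
        assert np.all(predict(back, X) == predict(model, X))


class TestSklearnEstimator:
    def test_clone_and_params(self):
        clf = GiniTreeClassifier(one_use="path")
        assert clone(clf).get_params()["one_use"] == "path"

    def test_fit_predict_on_arrays(self, rng):
        X = rng.normal(size=(50, 2))
        y = np.where(X[:, 0] > 0, "TCM", "CPE").astype(object)
        clf = GiniTreeClassifier().fit(X, y)
        assert clf.n_features_in_ == 2
        assert (clf.predict(X) == y).mean() == 1.0

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            GiniTreeClassifier().fit(np.zeros((2, 1)), np.array(["a", "b"]))


class TestEvaluation:
    def test_report_identities(self):
        rep = EvaluationReport(tp=30, tn=25, fp=5, fn=10)
        assert rep.accuracy == pytest.approx((30 + 25) / 70)
        assert rep.sensitivity == pytest.approx(30 / 40)
        assert rep.specificity == pytest.approx(25 / 30)
        assert rep.n == 70

    def test_two_subjects_give_two_folds_covering_all_rows(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": np.r_[rng.normal(0, 1, 6), rng.normal(4, 1, 6)]})
        meta = pd.DataFrame(
            {
                "subject_id": ["A"] * 3 + ["B"] * 3 + ["A"] * 3 + ["B"] * 3,
                "category": ["CPE"] * 6 + ["TCM"] * 6,
                "set_index": list(range(1, 4)) * 4,
            }
        )
        matrix = _ArrayMatrix(X, meta)
        rep = loso_evaluate(matrix, ["f"])
        assert rep.n == 12  # every row predicted exactly once
        assert rep.accuracy > 0.9

    def test_single_subject_rejected(self):
        X = pd.DataFrame({"f": [0.0, 1.0]})
        meta = pd.DataFrame(
            {"subject_id": ["A", "A"], "category": ["CPE", "TCM"], "set_index": [1, 1]}
        )
        with pytest.raises(ValueError):
            loso_evaluate(_ArrayMatrix(X, meta), ["f"])

    def test_subject_with_single_category_is_still_evaluated(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": np.r_[rng.normal(0, 0.1, 4), rng.normal(4, 0.1, 3)]})
        meta = pd.DataFrame(
            {
                "subject_id": ["A", "A", "B", "B", "A", "B", "C"],
                "category": ["CPE"] * 4 + ["TCM"] * 3,
                "set_index": [1, 2, 1, 2, 3, 3, 1],
            }
        )
        rep = loso_evaluate(_ArrayMatrix(X, meta), ["f"])  # C has only TCM rows
        assert rep.n == 7
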