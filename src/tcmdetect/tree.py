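"""Binary CART decision tree with Gini impurity and a one-use-per-feature rule.

The classifier distinguishes clinically prescribed execution (CPE) from a
typical compensatory movement (TCM) of a rehabilitation exercise, from a
handful of z-scored accelerometer-derived features.  It is a standard CART
tree (recursive binary splitting, Gini impurity) with one deliberate
restriction used as the stopping rule: each feature may be used at most once
in the whole tree, which bounds depth by the size of the feature subset and
acts as the overfitting guard instead of pruning.

``GiniTreeClassifier`` is a scikit-learn style estimator; the module-level
functions (:func:`fit_cart`, :func:`predict`, :func:`loso_evaluate`) are thin
wrappers kept for pipeline scripting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "gini_index",
    "best_split",
    "SplitNode",
    "DecisionTreeModel",
    "GiniTreeClassifier",
    "EvaluationReport",
    "fit_cart",
    "predict",
    "loso_evaluate",
    "plot_feature_scatter",
]

#: class label order; ties in leaf majority go to the first entry (CPE),
#: i.e. compensation is not flagged without evidence.
CLASS_ORDER = ("CPE", "TCM")
POSITIVE_CLASS = "TCM"

_EPS = 1e-12


def gini_index(class_proportions: Sequence[float]) -> float:
    """Gini impurity ``G = 1 - sum(p_k^2)`` of a node.

    For a binary node G is 0 for a pure node and 0.5 for an equal class
    split.

    Parameters
    ----------
    class_proportions : sequence of float
        Non-negative class proportions summing to 1.
    """
    p = np.asarray(class_proportions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("class proportions must be a non-empty 1-D sequence")
    if np.any(p < -_EPS):
        raise ValueError("class proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {p.sum()!r}")
    return float(1.0 - np.sum(p**2))


def _counts_gini(counts: np.ndarray) -> float:
    """Gini impurity from raw class counts (0 for an empty node)."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p**2))


def best_split(values: np.ndarray, labels: np.ndarray):
    """Best threshold for one feature, minimising child-weighted Gini.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; rows with ``value < threshold`` go left.  Ties in weighted Gini
    resolve to the smallest threshold.

    Returns
    -------
    (threshold, weighted_gini) or ``None``
        ``None`` signals no admissible split (fewer than two distinct
        values).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    order = np.argsort(values, kind="stable")
    v = values[order]
    # boolean encoding: 1 where label is the positive class
    y = (labels[order] == POSITIVE_CLASS).astype(np.int64)
    n = v.size
    if n < 2:
        return None
    boundary = np.nonzero(np.diff(v) > 0)[0]  # split after index i
    if boundary.size == 0:
        return None
    cum_pos = np.cumsum(y)
    n_left = boundary + 1
    n_right = n - n_left
    pos_left = cum_pos[boundary]
    pos_right = cum_pos[-1] - pos_left
    gl = 1.0 - ((pos_left / n_left) ** 2 + ((n_left - pos_left) / n_left) ** 2)
    gr = 1.0 - ((pos_right / n_right) ** 2 + ((n_right - pos_right) / n_right) ** 2)
    weighted = (n_left * gl + n_right * gr) / n
    # ties (within float tolerance) resolve to the smallest threshold
    best = int(np.flatnonzero(weighted <= weighted.min() + _EPS)[0])
    thr = 0.5 * (v[boundary[best]] + v[boundary[best] + 1])
    return float(thr), float(weighted[best])


@dataclass
class SplitNode:
    """One node of the fitted tree.

    Internal nodes carry ``feature_name`` and ``split_value`` (rows with
    ``value < split_value`` descend left); leaves carry ``leaf_class``.
    ``class_counts`` is ``(n_CPE, n_TCM)`` of the training rows reaching the
    node and ``gini`` its impurity.
    """

    class_counts: tuple[int, int]
    gini: float
    feature_name: str | None = None
    split_value: float | None = None
    left: "SplitNode | None" = None
    right: "SplitNode | None" = None
    leaf_class: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class is not None

    def to_dict(self) -> dict:
        d: dict = {"class_counts": list(self.class_counts), "gini": self.gini}
        if self.is_leaf:
            d["leaf_class"] = self.leaf_class
        else:
            d.update(
                feature=self.feature_name,
                split=self.split_value,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SplitNode":
        node = cls(class_counts=tuple(d["class_counts"]), gini=d["gini"])
        if "leaf_class" in d:
            node.leaf_class = d["leaf_class"]
        else:
            node.feature_name = d["feature"]
            node.split_value = d["split"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class DecisionTreeModel:
    """Fitted tree plus the order in which features were consumed."""

    root: SplitNode
    feature_order: list[str] = field(default_factory=list)

    def predict_row(self, row) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.left if row[node.feature_name] < node.split_value else node.right
        return node.leaf_class

    def split_values(self) -> dict[str, float]:
        """Mapping feature -> split value, walking the tree."""
        out: dict[str, float] = {}

        def walk(node: SplitNode) -> None:
            if not node.is_leaf:
                out[node.feature_name] = node.split_value
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"feature_order": self.feature_order, "root": self.root.to_dict()},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str) -> "DecisionTreeModel":
        d = json.loads(source)
        return cls(root=SplitNode.from_dict(d["root"]), feature_order=d["feature_order"])


def _node_counts(y: np.ndarray) -> np.ndarray:
    return np.array([int(np.sum(y == c)) for c in CLASS_ORDER], dtype=np.int64)


def _majority(counts: np.ndarray) -> str:
    # tie -> CPE (first class)
    return CLASS_ORDER[int(np.argmax(counts))]


class GiniTreeClassifier(BaseEstimator, ClassifierMixin):
    """CART tree with Gini impurity and each feature used at most once.

    Parameters
    ----------
    one_use : {"global", "path"}, default="global"
        Scope of the one-use-per-feature rule.  ``"global"`` (default)
        forbids reuse anywhere in the tree; ``"path"`` only along a
        root-to-leaf path.
    min_gini_decrease : float, default=0.0
        A split is accepted only if the child-weighted Gini is below the
        parent Gini by more than this margin.

    Attributes
    ----------
    model_ : DecisionTreeModel
        The fitted tree.
    classes_ : ndarray of str
    feature_names_in_ : ndarray of str
    """

    def __init__(self, one_use: str = "global", min_gini_decrease: float = 0.0):
        self.one_use = one_use
        self.min_gini_decrease = min_gini_decrease

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_frame(X, feature_names=None) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X, columns=list(feature_names))

    def fit(self, X, y, feature_names=None):
        if self.one_use not in ("global", "path"):
            raise ValueError("one_use must be 'global' or 'path'")
        frame = self._as_frame(X, feature_names)
        y = np.asarray(y, dtype=object)
        if len(frame) != len(y):
            raise ValueError("X and y length mismatch")
        if len(frame) == 0:
            raise ValueError("cannot fit on an empty dataset")
        unknown = set(np.unique(y)) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        self.classes_ = np.array(CLASS_ORDER, dtype=object)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]

        cols = {name: frame[name].to_numpy(dtype=float) for name in frame.columns}
        order: list[str] = []
        available = list(frame.columns)
        root = self._grow(cols, y, np.arange(len(y)), available, order)
        self.model_ = DecisionTreeModel(root=root, feature_order=order)
        return self

    def _grow(self, cols, y, idx, available, order) -> SplitNode:
        counts = _node_counts(y[idx])
        node = SplitNode(class_counts=tuple(int(c) for c in counts), gini=_counts_gini(counts))
        if node.gini == 0.0 or not available:
            node.leaf_class = _majority(counts)
            return node
        best = None  # (weighted_gini, feature, threshold)
        for name in available:
            res = best_split(cols[name][idx], y[idx])
            if res is None:
                continue
            thr, wg = res
            if best is None or wg < best[0] - _EPS:
                best = (wg, name, thr)
            # exact ties resolve to the lexicographically smallest feature
            # name; within a feature best_split already took the smallest
            # threshold
            elif abs(wg - best[0]) <= _EPS and name < best[1]:
                best = (wg, name, thr)
        if best is None or best[0] >= node.gini - self.min_gini_decrease - _EPS:
            node.leaf_class = _majority(counts)
            return node
        wg, name, thr = best
        node.feature_name = name
        node.split_value = thr
        order.append(name)
        mask = cols[name][idx] < thr
        if self.one_use == "global":
            # the remaining budget is shared: the left subtree consumes
            # features first, the right subtree sees what is left
            remaining = [f for f in available if f != name]
            node.left = self._grow(cols, y, idx[mask], remaining, order)
            used = set(order)
            node.right = self._grow(
                cols, y, idx[~mask], [f for f in remaining if f not in used], order
            )
        else:
            remaining = [f for f in available if f != name]
            node.left = self._grow(cols, y, idx[mask], list(remaining), order)
            node.right = self._grow(cols, y, idx[~mask], list(remaining), order)
        return node

    def predict(self, X):
        check_is_fitted(self, "model_")
        frame = self._as_frame(X, list(self.feature_names_in_))
        missing = [f for f in self.model_.split_values() if f not in frame.columns]
        if missing:
            raise ValueError(f"rows are missing tree features: {missing}")
        rows = frame.to_dict("records")
        return np.array([self.model_.predict_row(r) for r in rows], dtype=object)

    def get_depth(self) -> int:
        check_is_fitted(self, "model_")

        def depth(node: SplitNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        return depth(self.model_.root)


def fit_cart(X, y, features: Sequence[str] | None = None, one_use: str = "global") -> DecisionTreeModel:
    """Fit a CART tree on ``X`` (DataFrame) restricted to ``features``."""
    frame = GiniTreeClassifier._as_frame(X)
    if features is not None:
        # a duplicated feature adds nothing: the tree uses each at most once
        features = list(dict.fromkeys(features))
        if len(features) == 0:
            # empty feature set: single majority leaf
            counts = _node_counts(np.asarray(y, dtype=object))
            leaf = SplitNode(
                class_counts=tuple(int(c) for c in counts),
                gini=_counts_gini(counts),
                leaf_class=_majority(counts),
            )
            return DecisionTreeModel(root=leaf, feature_order=[])
        missing = [f for f in features if f not in frame.columns]
        if missing:
            raise ValueError(f"features not in matrix: {missing}")
        frame = frame.loc[:, list(features)]
    clf = GiniTreeClassifier(one_use=one_use).fit(frame, y)
    return clf.model_


def predict(model: DecisionTreeModel, rows) -> np.ndarray:
    """Predict class labels for rows (DataFrame, dict, or sequence of dicts)."""
    if isinstance(rows, dict):
        return np.array([model.predict_row(rows)], dtype=object)
    if isinstance(rows, pd.DataFrame):
        needed = model.split_values()
        missing = [f for f in needed if f not in rows.columns]
        if missing:
            raise ValueError(f"rows are missing tree features: {missing}")
        rows = rows.to_dict("records")
    return np.array([model.predict_row(r) for r in rows], dtype=object)


@dataclass
class EvaluationReport:
    """Pooled confusion counts with TCM as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    scheme: str = "loso"
    split_values: dict[str, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "n": self.n,
            "confusion": {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "split_values": self.split_values,
        }


def _tally(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos = POSITIVE_CLASS
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    return tp, tn, fp, fn


def loso_evaluate(matrix, features: Sequence[str], scaling: str = "full") -> EvaluationReport:
    """Leave-one-subject-out evaluation of a CART tree on a feature matrix.

    Every subject is held out in turn; a tree is fitted on all other
    subjects' rows (restricted to ``features``) and evaluated on the held-out
    subject, so test data always comes from an unseen individual.  Confusion
    counts are pooled over folds.

    Parameters
    ----------
    matrix : FeatureMatrix
    features : ordered feature names to use.
    scaling : {"full", "train_only"}
        ``"full"`` evaluates on the matrix z-scored over all rows (the study
        convention); ``"train_only"`` re-scales each fold with the training
        rows' statistics only.
    """
    subjects = matrix.meta["subject_id"].to_numpy()
    uniq = pd.unique(subjects)
    if uniq.size < 2:
        raise ValueError("LOSO requires at least 2 subjects")
    y = matrix.y
    tp = tn = fp = fn = 0
    for subj in uniq:
        test = subjects == subj
        train = ~test
        if scaling == "train_only":
            X_tr, X_te = matrix.rescaled(train_mask=train)
            X_tr = X_tr.loc[:, list(features)]
            X_te = X_te.loc[:, list(features)]
        else:
            X_tr = matrix.X.loc[train, list(features)]
            X_te = matrix.X.loc[test, list(features)]
        model = fit_cart(X_tr, y[train], list(features))
        pred = predict(model, X_te)
        t = _tally(y[test], pred)
        tp, tn, fp, fn = tp + t[0], tn + t[1], fp + t[2], fn + t[3]
    # a model on the full matrix provides the reported split values
    full_model = fit_cart(matrix.X, y, list(features))
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn, scheme="loso", split_values=full_model.split_values()
    )


def plot_feature_scatter(matrix, features: Sequence[str], model: DecisionTreeModel | None, path):
    """Scatter of sets in 1-2 feature dimensions with dashed split lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    features = list(features)[:2]
    y = matrix.y
    fig, ax = plt.subplots(figsize=(6, 5))
    splits = model.split_values() if model is not None else {}
    for cls, marker, color in (("CPE", "o", "tab:blue"), ("TCM", "^", "tab:red")):
        sel = y == cls
        xs = matrix.X.loc[sel, features[0]]
        ys = matrix.X.loc[sel, features[1]] if len(features) == 2 else np.zeros(int(sel.sum()))
        ax.scatter(xs, ys, marker=marker, s=24, alpha=0.75, label=cls, color=color)
    if features[0] in splits:
        ax.axvline(splits[features[0]], linestyle="--", color="k")
    if len(features) == 2 and features[1] in splits:
        ax.axhline(splits[features[1]], linestyle="--", color="k")
    ax.set_xlabel(f"{features[0]} (z-score)")
    ax.set_ylabel(f"{features[1]} (z-score)" if len(features) == 2 else "")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
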