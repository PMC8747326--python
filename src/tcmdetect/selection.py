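"""Wrapper forward feature selection driven by cross-validated tree loss.

Starting from an empty subset, the selector repeatedly tries every
not-yet-accepted feature appended to the current subset, scores each
candidate subset by the misclassification rate of a CART tree under
stratified 5-fold cross-validation, and accepts the best candidate.  It
stops when no candidate improves on the current loss or when the subset cap
is reached.  The cap defaults to 5 features, the largest subset size not
exceeding half the training-observation count the study worked with
(N = 36, so at most 5 features per subset).

The loss of the empty subset — the baseline the first acceptance decision
is made against — is the minority-class proportion (the error of always
predicting the majority class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, MetaEstimatorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .tree import GiniTreeClassifier, fit_cart, predict

__all__ = [
    "count_subsets",
    "SelectionConfig",
    "SelectionResult",
    "cv_loss",
    "forward_select",
    "ForwardTreeSelector",
]


def count_subsets(n_features: int, max_size: int) -> int:
    """Number of non-empty feature subsets of size <= max_size (exact).

    ``sum_{k=1..max_size} C(n_features, k)``: 2,369,935 for 50 features and
    subsets of up to 5, and 6,884 for the 16-feature single-sensor case.
    """
    if max_size < 1 or max_size > n_features:
        raise ValueError("require 1 <= max_size <= n_features")
    return sum(comb(n_features, k) for k in range(1, max_size + 1))


@dataclass
class SelectionConfig:
    """Knobs of the wrapper selection (defaults follow the study set-up)."""

    max_subset_size: int = 5
    cv_folds: int = 5
    rng_seed: int = 0
    mode: str = "all"
    scaling: str = "full"  # z-score convention handed down to cv_loss

    def __post_init__(self):
        if self.max_subset_size < 1:
            raise ValueError("max_subset_size must be at least 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass
class SelectionResult:
    """Outcome of a forward-selection run."""

    accepted_features: list[str]
    step_losses: list[float]
    baseline_loss: float
    candidate_evaluations: int
    stopped_reason: str  # no_improvement | cap_reached
    mode: str = "all"

    def to_dict(self) -> dict:
        return {
            "accepted_features": self.accepted_features,
            "step_losses": self.step_losses,
            "baseline_loss": self.baseline_loss,
            "candidate_evaluations": self.candidate_evaluations,
            "stopped_reason": self.stopped_reason,
            "mode": self.mode,
        }


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified fold test-index arrays; re-drawn (next seed, max 10
    attempts) in the degenerate case of a training fold with one class."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = [test for _, test in skf.split(np.zeros_like(y, dtype=float), y)]
        ok = True
        for test in folds:
            train_labels = np.delete(y, test)
            if np.unique(train_labels).size < 2:
                ok = False
                break
        if ok:
            return folds
    raise ValueError("could not draw folds with both classes in every training split")


def cv_loss(
    matrix,
    features: Sequence[str],
    config: SelectionConfig | None = None,
    folds: list[np.ndarray] | None = None,
) -> float:
    """Pooled misclassification rate of a CART tree under stratified k-fold CV.

    Per fold a tree is fitted on the training rows restricted to
    ``features`` and evaluated on the held-out rows; the loss pools the
    misclassifications over folds (accuracy = 1 - loss).
    """
    config = config or SelectionConfig()
    features = list(dict.fromkeys(features))  # duplicates add nothing to a tree
    if not features:
        raise ValueError("feature subset must not be empty")
    missing = [f for f in features if f not in matrix.X.columns]
    if missing:
        raise ValueError(f"features not in matrix: {missing}")
    y = matrix.y
    if folds is None:
        folds = _stratified_folds(y, config.cv_folds, config.rng_seed)
    errors = 0
    total = 0
    for test_idx in folds:
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        if config.scaling == "train_only":
            X_tr, X_te = matrix.rescaled(train_mask=~mask)
            X_tr, X_te = X_tr.loc[:, features], X_te.loc[:, features]
        else:
            X_tr = matrix.X.loc[~mask, features]
            X_te = matrix.X.loc[mask, features]
        model = fit_cart(X_tr, y[~mask], features)
        pred = predict(model, X_te)
        errors += int(np.sum(pred != y[mask]))
        total += int(mask.sum())
    return errors / total


def forward_select(matrix, config: SelectionConfig | None = None) -> SelectionResult:
    """Greedy forward selection over the matrix's feature columns.

    Deterministic given the seed and matrix: candidate ties resolve to the
    lexicographically smallest feature name, and one seeded fold partition
    is reused for every candidate evaluation.
    """
    config = config or SelectionConfig()
    y = matrix.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("selection requires at least 2 rows per category")
    folds = _stratified_folds(y, config.cv_folds, config.rng_seed)

    baseline = float(counts.min() / counts.sum())  # minority-class rate
    current_loss = baseline
    accepted: list[str] = []
    step_losses: list[float] = []
    evaluations = 0
    remaining = sorted(matrix.X.columns)
    stopped = "cap_reached"
    while len(accepted) < config.max_subset_size:
        best_feature = None
        best_loss = np.inf
        for name in remaining:
            loss = cv_loss(matrix, accepted + [name], config, folds=folds)
            evaluations += 1
            if loss < best_loss:  # remaining is sorted: ties keep the smaller name
                best_loss, best_feature = loss, name
        if best_feature is None or best_loss >= current_loss:
            stopped = "no_improvement"
            break
        accepted.append(best_feature)
        remaining.remove(best_feature)
        step_losses.append(best_loss)
        current_loss = best_loss
        if current_loss == 0.0:
            stopped = "no_improvement"  # nothing left to improve
            break
    return SelectionResult(
        accepted_features=accepted,
        step_losses=step_losses,
        baseline_loss=baseline,
        candidate_evaluations=evaluations,
        stopped_reason=stopped,
        mode=config.mode,
    )


class ForwardTreeSelector(BaseEstimator, MetaEstimatorMixin):
    """Scikit-learn style transformer wrapping :func:`forward_select`.

    Operates on an already z-scored DataFrame (or array) and selects
    columns by cross-validated CART loss.

    Attributes
    ----------
    selected_features_ : list of str
    step_losses_ : list of float
    n_candidates_evaluated_ : int
    stopped_reason_ : str
    support_ : boolean mask over input columns
    """

    def __init__(self, max_features: int = 5, cv: int = 5, random_state: int = 0):
        self.max_features = max_features
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        frame = GiniTreeClassifier._as_frame(X)
        y = np.asarray(y, dtype=object)
        # package the inputs as a minimal matrix-like for forward_select
        meta = pd.DataFrame({"subject_id": "", "category": y, "set_index": 0})
        matrix = _ArrayMatrix(frame, meta)
        config = SelectionConfig(
            max_subset_size=self.max_features, cv_folds=self.cv, rng_seed=self.random_state
        )
        result = forward_select(matrix, config)
        self.result_ = result
        self.selected_features_ = result.accepted_features
        self.step_losses_ = result.step_losses
        self.n_candidates_evaluated_ = result.candidate_evaluations
        self.stopped_reason_ = result.stopped_reason
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.support_ = np.isin(self.feature_names_in_, result.accepted_features)
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        frame = GiniTreeClassifier._as_frame(X, list(self.feature_names_in_))
        return frame.loc[:, self.selected_features_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return np.nonzero(self.support_)[0] if indices else self.support_


class _ArrayMatrix:
    """Duck-typed stand-in for FeatureMatrix over a plain scaled frame."""

    def __init__(self, X: pd.DataFrame, meta: pd.DataFrame):
        self.X = X.reset_index(drop=True)
        self.raw = self.X
        self.meta = meta.reset_index(drop=True)

    @property
    def y(self) -> np.ndarray:
        return self.meta["category"].to_numpy(dtype=object)

    def rescaled(self, train_mask):
        train_mask = np.asarray(train_mask, dtype=bool)
        tr = self.raw.loc[train_mask]
        mean = tr.mean(axis=0)
        sd = tr.std(axis=0, ddof=0).replace(0.0, 1.0)
        return (self.raw.loc[train_mask] - mean) / sd, (self.raw.loc[~train_mask] - mean) / sd
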