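"""Two-state classification with cross-validated error reporting.

Discrimination quality of the intragene feature tables is estimated
with two model families:

* L1-regularized logistic regression, whose regularization strength is
  tuned by an inner stratified cross-validation loop inside each outer
  fold (nested CV), with features z-scored on the training part of each
  fold;
* random forests of shallow trees (1000 trees of depth 3 by default),
  which need no hyperparameter tuning and therefore skip the inner
  loop.

Errors follow the stem-cell study convention: with an "induced" class
(the iPSC analogue) designated, the type I error is the fraction of
induced-class samples called non-induced, the type II error the
fraction of non-induced samples called induced, and the
misclassification error the total fraction wrong.  All three are
reported as mean +/- sd over the outer folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

#: inverse-regularization grid for the L1 logistic model
DEFAULT_C_GRID = np.logspace(-3, 3, 20)

FAMILIES = ("l1_logistic", "random_forest", "stump")


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameters and seed."""

    family: str = "l1_logistic"
    c_grid: tuple[float, ...] = tuple(DEFAULT_C_GRID)
    n_trees: int = 1000
    max_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.family == "l1_logistic" and len(self.c_grid) == 0:
            raise ValueError("regularization grid must be non-empty")
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


@dataclass
class CVErrorReport:
    """Outer-fold error summary (type I, type II, misclassification)."""

    type1_mean: float
    type1_sd: float
    type2_mean: float
    type2_sd: float
    misclassification_mean: float
    misclassification_sd: float
    per_fold: pd.DataFrame
    n_folds: int

    def as_dict(self) -> dict[str, Any]:
        return {
            "type1_mean": self.type1_mean,
            "type1_sd": self.type1_sd,
            "type2_mean": self.type2_mean,
            "type2_sd": self.type2_sd,
            "misclassification_mean": self.misclassification_mean,
            "misclassification_sd": self.misclassification_sd,
            "n_folds": self.n_folds,
        }


class _L1Logistic(LogisticRegression):
    """L1 logistic regression that degrades to the majority class.

    liblinear penalizes the intercept along with the coefficients, so
    under extreme regularization the decision function collapses to a
    tie at zero.  The sensible limit of an L1 model is intercept-only,
    i.e. the training majority class; predict that when every
    coefficient is zeroed out.
    """

    def fit(self, X, y, sample_weight=None):
        super().fit(X, y, sample_weight=sample_weight)
        values, counts = np.unique(np.asarray(y), return_counts=True)
        self.majority_class_ = values[np.argmax(counts)]
        return self

    def predict(self, X):
        if not np.any(self.coef_):
            return np.full(len(X), self.majority_class_, dtype=object)
        return super().predict(X)


def _build_estimator(spec: ModelSpec, seed: int, inner_folds: int = 5):
    """Estimator for one training fold; tunes C for the linear family."""
    if spec.family == "l1_logistic":
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "model",
                    _L1Logistic(
                        l1_ratio=1,
                        solver="liblinear",
                        max_iter=2000,
                        random_state=seed % (2**31),
                    ),
                ),
            ]
        )
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=seed % (2**31)
        )
        return GridSearchCV(
            pipe,
            param_grid={"model__C": list(spec.c_grid)},
            scoring="accuracy",
            cv=inner,
            refit=_smallest_c_among_ties,
            n_jobs=1,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            random_state=seed % (2**31),
            n_jobs=1,
        )
    return DecisionTreeClassifier(max_depth=1, random_state=seed % (2**31))


def _smallest_c_among_ties(cv_results: dict) -> int:
    """Pick the strongest regularization among accuracy-tied grid points."""
    scores = np.asarray(cv_results["mean_test_score"])
    cs = np.asarray([p["model__C"] for p in cv_results["params"]], dtype=float)
    best = np.max(scores)
    tied = np.flatnonzero(scores >= best - 1e-12)
    return int(tied[np.argmin(cs[tied])])


def _resolve_induced(classes: list[str], induced_class: str | None) -> str:
    if induced_class is None:
        return classes[-1]  # lexicographically last, e.g. iPSC over ESC
    if induced_class not in classes:
        raise ValueError(f"induced_class {induced_class!r} not among labels {classes}")
    return induced_class


def _fold_errors(
    y_true: np.ndarray, y_pred: np.ndarray, induced: str
) -> dict[str, float]:
    is_induced = y_true == induced
    wrong = y_true != y_pred
    n_ind = int(is_induced.sum())
    n_base = int((~is_induced).sum())
    return {
        "type1": float(wrong[is_induced].sum() / n_ind) if n_ind else np.nan,
        "type2": float(wrong[~is_induced].sum() / n_base) if n_base else np.nan,
        "misclassification": float(wrong.mean()),
        "n_induced": n_ind,
        "n_base": n_base,
    }


def nested_cv_evaluate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec,
    n_outer: int = 5,
    n_inner: int = 5,
    seed: int = 0,
    induced_class: str | None = None,
) -> CVErrorReport:
    """Outer stratified k-fold error estimate with inner-loop tuning.

    The inner loop runs only for the L1 logistic family (the forest is
    used with fixed hyperparameters).  Fold assignment and model seeds
    derive deterministically from ``seed``.
    """
    X = matrix.to_numpy(dtype=float)
    y = labels.loc[matrix.index].to_numpy(dtype=object).astype(str)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < n_outer:
        raise ValueError(
            f"minority class has {min(counts.values())} samples; "
            f"cannot stratify into {n_outer} folds"
        )
    induced = _resolve_induced(classes, induced_class)

    outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed % (2**31))
    rows = []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        est = _build_estimator(spec, seed=seed + 1 + fold, inner_folds=n_inner)
        est.fit(X[tr], y[tr])
        pred = est.predict(X[te])
        rec = _fold_errors(y[te], pred, induced)
        rec["fold"] = fold
        if spec.family == "l1_logistic":
            rec["selected_C"] = float(est.best_params_["model__C"])
        rows.append(rec)
    per_fold = pd.DataFrame(rows).set_index("fold")
    return CVErrorReport(
        type1_mean=float(per_fold["type1"].mean()),
        type1_sd=float(per_fold["type1"].std(ddof=1)),
        type2_mean=float(per_fold["type2"].mean()),
        type2_sd=float(per_fold["type2"].std(ddof=1)),
        misclassification_mean=float(per_fold["misclassification"].mean()),
        misclassification_sd=float(per_fold["misclassification"].std(ddof=1)),
        per_fold=per_fold,
        n_folds=n_outer,
    )


def fit_predict(
    matrix_train: pd.DataFrame,
    labels_train: pd.Series,
    matrix_test: pd.DataFrame,
    spec: ModelSpec,
    n_inner: int = 5,
) -> tuple[pd.Series, pd.Series]:
    """Train on one table, predict another; return per-feature scores.

    For the linear family the score is the absolute coefficient on the
    z-scored features at the inner-loop-selected regularization; for
    trees it is the impurity-based importance.
    """
    if list(matrix_train.columns) != list(matrix_test.columns):
        raise ValueError("train and test feature columns differ")
    X_tr = matrix_train.to_numpy(dtype=float)
    y_tr = labels_train.loc[matrix_train.index].to_numpy(dtype=object).astype(str)
    est = _build_estimator(spec, seed=spec.seed, inner_folds=n_inner)
    est.fit(X_tr, y_tr)
    pred = pd.Series(
        est.predict(matrix_test.to_numpy(dtype=float)), index=matrix_test.index
    )
    scores = pd.Series(feature_scores(est, spec), index=matrix_train.columns)
    return pred, scores


def feature_scores(fitted_estimator, spec: ModelSpec) -> np.ndarray:
    """Extract |coefficient| or impurity importance from a fitted model."""
    if spec.family == "l1_logistic":
        model = fitted_estimator.best_estimator_.named_steps["model"]
        return np.abs(model.coef_.ravel())
    return fitted_estimator.feature_importances_
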