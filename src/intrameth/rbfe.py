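"""Recursive best-feature elimination and single-feature rankings.

RBFE inverts the usual elimination logic: instead of discarding the
worst features, the *best* batch (by model-derived feature scores) is
moved out of the pool at each iteration.  Tracking the cross-validated
error of classifiers built on (i) everything selected so far, (ii) the
current batch alone, and (iii) the remaining pool shows whether the top
features are irreplaceable or whether many subsets discriminate almost
equally well.

Two single-feature rankings feed the enrichment scan: decision stumps
(depth-1 trees), whose importance is simply the cross-validated
misclassification error of a one-feature classifier, and the impurity
importances of a random forest.  The stump search is an exact
vectorized equivalent of CART's best gini split on one feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from intrameth.classify import (
    CVErrorReport,
    ModelSpec,
    _build_estimator,
    feature_scores,
    nested_cv_evaluate,
)
from intrameth.measures import COLUMN_SEP

DEFAULT_BATCH = {"l1_logistic": 250, "random_forest": 1000}

STUMP_ERROR_CUTOFF = 0.10


@dataclass
class RBFEIteration:
    batch: list[str]
    err_accumulated: CVErrorReport
    err_current: CVErrorReport
    err_remaining: CVErrorReport | None


@dataclass
class RBFETrace:
    """Per-iteration record of the elimination procedure."""

    iterations: list[RBFEIteration]
    base_family: str
    batch_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, it in enumerate(self.iterations):
            row = {"iteration": i, "batch_size": len(it.batch)}
            for tag, rep in (
                ("accumulated", it.err_accumulated),
                ("current", it.err_current),
                ("remaining", it.err_remaining),
            ):
                row[f"err_{tag}_mean"] = (
                    rep.misclassification_mean if rep is not None else np.nan
                )
                row[f"err_{tag}_sd"] = (
                    rep.misclassification_sd if rep is not None else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def batches(self) -> list[list[str]]:
        return [it.batch for it in self.iterations]


def _rank_features(
    matrix: pd.DataFrame, labels: pd.Series, spec: ModelSpec, seed: int
) -> pd.Series:
    """Model-derived feature scores on the full table, tie-broken by name."""
    y = labels.loc[matrix.index].to_numpy(dtype=object).astype(str)
    est = _build_estimator(spec, seed=seed)
    est.fit(matrix.to_numpy(dtype=float), y)
    return pd.Series(feature_scores(est, spec), index=matrix.columns)


def run_rbfe(
    matrix: pd.DataFrame,
    labels: pd.Series,
    base_model: ModelSpec,
    batch_size: int | None = None,
    seed: int = 0,
    n_folds: int = 5,
    induced_class: str | None = None,
    max_iterations: int | None = None,
) -> RBFETrace:
    """Iteratively move the top-scored feature batch out of the pool.

    At each iteration the base model is trained on the remaining pool,
    its ``batch_size`` best features (largest |coefficient| or
    importance; ties by name) join the selected set, and three
    cross-validated error reports are computed.  The final batch takes
    whatever remains.  Fold seeds derive from ``seed`` plus the
    iteration index, so single iterations are independently
    reproducible.

    ``max_iterations`` truncates the trace early (the batches then no
    longer partition the full feature set); by default the procedure
    runs until the pool is empty.
    """
    if base_model.family not in ("l1_logistic", "random_forest"):
        raise ValueError("RBFE base model must be l1_logistic or random_forest")
    if matrix.shape[1] == 0:
        raise ValueError("empty feature matrix")
    if batch_size is None:
        batch_size = DEFAULT_BATCH[base_model.family]
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")

    pool = list(matrix.columns)
    selected: list[str] = []
    iterations: list[RBFEIteration] = []
    i = 0
    while pool and (max_iterations is None or i < max_iterations):
        scores = _rank_features(matrix[pool], labels, base_model, seed=seed + 9000 + i)
        order = sorted(pool, key=lambda f: (-scores[f], f))
        batch = order[: min(batch_size, len(pool))]
        selected = selected + batch
        pool = [f for f in pool if f not in set(batch)]

        def _eval(cols: list[str]) -> CVErrorReport:
            return nested_cv_evaluate(
                matrix[cols],
                labels,
                base_model,
                n_outer=n_folds,
                seed=seed + i,
                induced_class=induced_class,
            )

        err_acc = _eval(selected)
        err_cur = err_acc if len(selected) == len(batch) else _eval(batch)
        err_rem = _eval(pool) if pool else None
        iterations.append(RBFEIteration(batch, err_acc, err_cur, err_rem))
        i += 1
    return RBFETrace(iterations, base_model.family, batch_size)


# ---------------------------------------------------------------------------
# vectorized decision stumps


def _fit_stumps(X: np.ndarray, y01: np.ndarray):
    """Best gini split per feature, all features at once.

    ``X`` is samples x features, ``y01`` binary 0/1.  Returns
    (threshold, left_class, right_class, has_split) arrays; features
    without a valid split (constant on the training part) fall back to
    the majority class.  Equivalent to CART's exhaustive midpoint
    search on a single feature with first-minimum tie-breaking.
    """
    n, f = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    xs = np.take_along_axis(X, order, axis=0)
    ys = y01[order]
    total1 = int(y01.sum())
    c1 = np.cumsum(ys, axis=0)  # class-1 count among the first i rows

    nl = np.arange(1, n)[:, None].astype(float)  # left sizes for cuts 1..n-1
    l1 = c1[:-1].astype(float)
    l0 = nl - l1
    nr = n - nl
    r1 = total1 - l1
    r0 = nr - r1
    # proxy: maximizing sum of squared class counts over child size
    with np.errstate(invalid="ignore", divide="ignore"):
        proxy = (l0**2 + l1**2) / nl + (r0**2 + r1**2) / nr
    valid = xs[:-1] < xs[1:]
    proxy = np.where(valid, proxy, -np.inf)

    best = np.argmax(proxy, axis=0)  # first maximum per feature
    cols = np.arange(f)
    has_split = np.isfinite(proxy[best, cols])
    thr = (xs[best, cols] + xs[best + 1, cols]) / 2.0

    bl1 = l1[best, cols]
    bl0 = l0[best, cols]
    br1 = r1[best, cols]
    br0 = r0[best, cols]
    left_class = (bl1 > bl0).astype(np.int8)  # tie -> class 0
    right_class = (br1 > br0).astype(np.int8)
    majority = np.int8(1 if total1 > n - total1 else 0)
    left_class = np.where(has_split, left_class, majority)
    right_class = np.where(has_split, right_class, majority)
    thr = np.where(has_split, thr, np.inf)  # everything goes left
    return thr, left_class, right_class, has_split


def _predict_stumps(
    X: np.ndarray, thr: np.ndarray, left_class: np.ndarray, right_class: np.ndarray
) -> np.ndarray:
    return np.where(X <= thr[None, :], left_class[None, :], right_class[None, :])


def stump_cv_errors(
    matrix: pd.DataFrame,
    labels: pd.Series,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated misclassification of a depth-1 tree per feature.

    Returns a frame indexed by feature with ``error_mean`` and
    ``error_sd`` over stratified folds.
    """
    X = matrix.to_numpy(dtype=float)
    y = labels.loc[matrix.index].to_numpy(dtype=object).astype(str)
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y01 = (y == classes[1]).astype(np.int8)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    fold_err = np.empty((folds, X.shape[1]))
    for k, (tr, te) in enumerate(skf.split(X, y01)):
        thr, lc, rc, _ = _fit_stumps(X[tr], y01[tr])
        pred = _predict_stumps(X[te], thr, lc, rc)
        fold_err[k] = (pred != y01[te][:, None]).mean(axis=0)
    return pd.DataFrame(
        {
            "error_mean": fold_err.mean(axis=0),
            "error_sd": fold_err.std(axis=0, ddof=1),
        },
        index=matrix.columns.copy(),
    )


def stump_rank(
    matrix: pd.DataFrame,
    labels: pd.Series,
    error_cutoff: float = STUMP_ERROR_CUTOFF,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank features by single-stump cross-validated error, best first.

    Intended for a table restricted to one measure, so rows of the
    result correspond to genes.  Ties are broken by feature name; a
    feature is ``retained`` only if its mean error is strictly below
    ``error_cutoff``.
    """
    errs = stump_cv_errors(matrix, labels, folds=folds, seed=seed)
    errs = errs.sort_index().sort_values("error_mean", kind="mergesort")
    errs["rank"] = np.arange(1, len(errs) + 1)
    # strictly below the cutoff; the epsilon keeps fold-average rounding
    # from sneaking an exactly-at-cutoff feature past the strict rule
    errs["retained"] = errs["error_mean"] < error_cutoff - 1e-9
    genes = [c.rsplit(COLUMN_SEP, 1)[0] if COLUMN_SEP in c else c for c in errs.index]
    meas = [c.rsplit(COLUMN_SEP, 1)[1] if COLUMN_SEP in c else "" for c in errs.index]
    errs.insert(0, "measure", meas)
    errs.insert(0, "gene", genes)
    errs.index.name = "feature"
    return errs


def rf_importance_rank(
    matrix: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Features ordered by random-forest impurity importance.

    Importances are non-negative and sum to 1 when any split was made;
    ties (including all-zero importances) are broken by feature name.
    """
    if spec is None:
        spec = ModelSpec(family="random_forest", seed=seed)
    elif spec.family != "random_forest":
        raise ValueError("importance ranking requires a random_forest spec")
    scores = _rank_features(matrix, labels, spec, seed=seed)
    out = scores.rename("importance").to_frame()
    out = out.sort_index().sort_values("importance", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    genes = [c.rsplit(COLUMN_SEP, 1)[0] if COLUMN_SEP in c else c for c in out.index]
    out.insert(0, "gene", genes)
    out.index.name = "feature"
    return out


def l1_selection_stability(
    matrix: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Jaccard overlap of L1-selected (nonzero-coefficient) feature sets.

    Diagnostic for the instability of the linear model's inherent
    selection across cross-validation folds; no threshold is attached.
    """
    y = labels.loc[matrix.index].to_numpy(dtype=object).astype(str)
    X = matrix.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    supports = []
    for k, (tr, _) in enumerate(skf.split(X, y)):
        est = _build_estimator(spec, seed=seed + 1 + k)
        est.fit(X[tr], y[tr])
        supports.append(frozenset(np.flatnonzero(feature_scores(est, spec) > 0)))
    rows = []
    for (i, a), (j, b) in combinations(enumerate(supports), 2):
        union = len(a | b)
        rows.append(
            {
                "fold_a": i,
                "fold_b": j,
                "jaccard": len(a & b) / union if union else 1.0,
                "size_a": len(a),
                "size_b": len(b),
            }
        )
    return pd.DataFrame(rows)
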