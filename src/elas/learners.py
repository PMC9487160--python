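"""Base-classifier families, their hyperparameter grids, and grid search.

Three families are supported: RBF-kernel SVM, L2-regularized logistic
regression, and CART (Gini impurity).  Hyperparameters are selected once by
stratified cross-validated grid search on the full training set and then
frozen for every base classifier trained along the active-sampling
curriculum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

FAMILIES = ("svm_rbf", "logreg_l2", "cart")

_DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm_rbf": [{"C": c} for c in (0.1, 1, 10)],
    "logreg_l2": [{"C": c} for c in (1, 10, 100)],
    "cart": [
        {"max_depth": d, "min_samples_leaf": m}
        for d, m in product((None, 5, 10), (1, 3, 5))
    ],
}


def default_grid(family: str) -> list[dict]:
    """The stock hyperparameter grid for a learner family."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return [dict(g) for g in _DEFAULT_GRIDS[family]]


@dataclass
class LearnerSpec:
    """A base-learner family plus its hyperparameter grid.

    ``grid=None`` means the stock grid; a single-point grid pins the
    hyperparameters (no search).
    """

    family: str
    grid: list[dict] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.grid is None:
            self.grid = default_grid(self.family)
        if not self.grid:
            raise ValueError("grid must be nonempty")


def make_estimator(family: str, params: dict, seed: int | None = 0):
    """Construct an unfitted probability-emitting classifier."""
    if family == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if family == "logreg_l2":
        # lbfgs with default settings is L2-regularized via C
        return LogisticRegression(solver="lbfgs", max_iter=2000, **params)
    if family == "cart":
        return DecisionTreeClassifier(criterion="gini", random_state=seed,
                                      **params)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _scorer(metric) -> callable:
    if callable(metric):
        return metric
    from elas import evaluation

    if metric == "auroc":
        return evaluation.auroc
    if metric == "auprc":
        return evaluation.auprc
    raise ValueError(f"unknown metric {metric!r}")


def tune(
    spec: LearnerSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    metric="auroc",
    seed: int = 0,
) -> dict:
    """Pick the grid point maximizing mean stratified-CV score.

    ``metric`` is ``"auroc"`` (default), ``"auprc"``, or a callable
    ``(scores, labels) -> float``.  Ties break toward earlier grid order.
    If a class is smaller than ``n_folds`` the fold count shrinks to the
    minority size (stratified refolding); below 2 it is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to tune")
    score_fn = _scorer(metric)
    n_folds_eff = min(n_folds, counts.min())
    if n_folds_eff < 2:
        raise ValueError(
            f"minority class has {counts.min()} member(s); cannot stratify"
        )
    if len(spec.grid) == 1:
        return dict(spec.grid[0])
    cv = StratifiedKFold(n_splits=int(n_folds_eff), shuffle=True,
                         random_state=seed)
    splits = list(cv.split(X, y))
    best_params, best_score = None, -np.inf
    for params in spec.grid:
        fold_scores = []
        for train_idx, val_idx in splits:
            clf = fit_base(spec, params, X[train_idx], y[train_idx], seed)
            p = clf.predict_proba(X[val_idx])[:, 1]
            fold_scores.append(score_fn(p, y[val_idx]))
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:  # strict: first grid point wins ties
            best_score, best_params = mean_score, params
    return dict(best_params)


def fit_base(
    spec: LearnerSpec,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = 0,
):
    """Fit one base classifier with frozen hyperparameters.

    Deterministic given the seed (the SVM's probability calibration uses an
    internal CV driven by ``random_state``).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit a base classifier on single-class data")
    clf = make_estimator(spec.family, params, seed)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf
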