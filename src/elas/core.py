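"""The ensemble-with-active-sampling training algorithm.

Training proceeds per internal-validation fold and per balanced-seed
initialization:

1. split the training set into stratified folds; each fold in turn is the
   internal validation set, the remaining folds form the training pool;
2. draw a class-balanced seed from the pool (``n_seed/2`` per class,
   without replacement) and remove it from the pool;
3. loop: fit a base classifier on the accumulated training data, then query
   the next ``n_batch`` pool samples by ranked batch-mode sampling and move
   them (with their true labels) into the training data; stop when fewer
   than ``n_batch`` pool samples remain — yielding exactly
   ``(N_pool - n_seed) // n_batch + 1`` classifiers, where ``N_pool`` is
   the pool size before seed removal;
4. keep the top ``k`` classifiers by internal-validation score.

The frozen ensemble holds ``n_folds * t_seed * k`` members and predicts the
unweighted mean of member probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold

from elas.learners import LearnerSpec, fit_base, tune

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class ELASConfig:
    """Hyperparameters of the ensemble training procedure.

    ``n_seed`` must be even and ``n_seed/2`` may not exceed the minority
    class size of any fold's training pool; ``k`` may not exceed the number
    of base classifiers a run produces.
    """

    learner: LearnerSpec = field(default_factory=lambda: LearnerSpec("svm_rbf"))
    n_seed: int = 50
    n_batch: int = 10
    t_seed: int = 3
    k: int = 20
    n_folds: int = 5
    selection_metric: str = "auroc"
    master_seed: int = 0
    alpha_literal: bool = False
    similarity_kind: str = "inverse"
    update_alpha_within_batch: bool = True
    standardize: bool = True
    tune_folds: int = 5
    tune_metric: str = "auroc"

    def __post_init__(self) -> None:
        if self.n_seed % 2 != 0:
            raise ValueError("n_seed must be even (n_seed/2 drawn per class)")
        if self.n_seed < 2:
            raise ValueError("n_seed must be >= 2")
        for name in ("n_batch", "t_seed", "k", "n_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.selection_metric not in ("auroc", "auprc"):
            raise ValueError("selection_metric must be 'auroc' or 'auprc'")


@dataclass
class SplitState:
    """The evolving index partition during one active-sampling run.

    The three index sets are pairwise disjoint; sampling moves indices from
    ``pool_indices`` to ``train_data_indices`` and never touches
    ``internal_val_indices``.  ``n_train_pool`` records the pool size
    *before* seed removal (the quantity the record-count law is stated in).
    """

    internal_val_indices: np.ndarray
    pool_indices: np.ndarray
    train_data_indices: np.ndarray
    n_train_pool: int

    def check(self) -> None:
        a = set(self.internal_val_indices.tolist())
        b = set(self.pool_indices.tolist())
        c = set(self.train_data_indices.tolist())
        if a & b or a & c or b & c:
            raise AssertionError("index sets overlap")
        if len(b) + len(c) != self.n_train_pool:
            raise AssertionError("pool/train_data do not conserve samples")


@dataclass
class BaseClassifierRecord:
    """One trained base classifier plus its provenance and validation score."""

    classifier: object
    iteration: int
    n_train: int
    internal_val_score: float | None = None


def expected_record_count(n_train_pool: int, n_seed: int, n_batch: int) -> int:
    """Closed form for the number of classifiers an active-sampling run yields."""
    return (n_train_pool - n_seed) // n_batch + 1


def make_internal_folds(
    y: np.ndarray,
    n_folds: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds as (pool_indices, internal_val_indices) pairs.

    The validation folds partition the index set; per-fold class
    proportions are within one sample of the global proportions.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot make "
            f"{n_folds} stratified folds"
        )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(train, val) for train, val in cv.split(np.zeros(len(y)), y)]


def draw_balanced_seed(
    pool_labels: np.ndarray,
    n_seed: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n_seed/2`` positions per class without replacement.

    Returns positions into ``pool_labels``; the caller removes them from
    the pool.
    """
    if n_seed % 2 != 0:
        raise ValueError("n_seed must be even")
    pool_labels = np.asarray(pool_labels)
    half = n_seed // 2
    out = []
    for cls in (0, 1):
        members = np.flatnonzero(pool_labels == cls)
        if len(members) < half:
            raise ValueError(
                f"class {cls} has {len(members)} pool members; need "
                f"n_seed/2 = {half} (n_seed/2 must not exceed the minority "
                "class size)"
            )
        out.append(rng.choice(members, size=half, replace=False))
    return np.concatenate(out)


def active_sampling_run(
    X: np.ndarray,
    y: np.ndarray,
    state: SplitState,
    learner: LearnerSpec,
    params: dict,
    config: ELASConfig,
    rng: np.random.Generator,
    history: list | None = None,
) -> list[BaseClassifierRecord]:
    """One active-sampling run: fit, query, repeat until the pool runs dry.

    Mutates ``state`` (pool shrinks, train_data grows).  ``history``, when
    given, receives one dict per iteration with copies of the index sets
    for invariant auditing.
    """
    from elas.query import rank_batch

    records: list[BaseClassifierRecord] = []
    iteration = 1
    while True:
        train_idx = state.train_data_indices
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            clf = fit_base(learner, params, X[train_idx], y[train_idx], fit_seed)
        except Exception as exc:
            raise RuntimeError(
                f"base learner failed at iteration {iteration} "
                f"(n_train={len(train_idx)}): {exc}"
            ) from exc
        records.append(
            BaseClassifierRecord(clf, iteration=iteration, n_train=len(train_idx))
        )
        if history is not None:
            history.append({
                "iteration": iteration,
                "pool_indices": state.pool_indices.copy(),
                "train_data_indices": state.train_data_indices.copy(),
            })
        if len(state.pool_indices) < config.n_batch:
            break
        picks = rank_batch(
            clf,
            X[state.pool_indices],
            X[train_idx],
            config.n_batch,
            alpha_literal=config.alpha_literal,
            similarity_kind=config.similarity_kind,
            update_alpha=config.update_alpha_within_batch,
        )
        chosen = state.pool_indices[picks]
        keep = np.ones(len(state.pool_indices), dtype=bool)
        keep[picks] = False
        state.pool_indices = state.pool_indices[keep]
        state.train_data_indices = np.concatenate([state.train_data_indices, chosen])
        iteration += 1
    return records


def _selection_scorer(metric: str):
    from elas import evaluation

    return evaluation.auroc if metric == "auroc" else evaluation.auprc


def select_top_k(
    records: list[BaseClassifierRecord],
    X_internal_val: np.ndarray,
    y_internal_val: np.ndarray,
    k: int,
    metric: str = "auroc",
) -> list[BaseClassifierRecord]:
    """Score each record on the internal-validation fold and keep the top k.

    Ties break toward the earlier iteration (smaller, more balanced
    training set).  Scores are stored on the records.
    """
    if k > len(records):
        raise ValueError(
            f"k={k} exceeds the number of base classifiers ({len(records)}); "
            "keep k <= (N_trainPool - n_seed) // n_batch + 1"
        )
    y_val = np.asarray(y_internal_val)
    if len(np.unique(y_val)) < 2:
        raise ValueError("internal validation fold must contain both classes")
    score_fn = _selection_scorer(metric)
    for rec in records:
        p = rec.classifier.predict_proba(X_internal_val)[:, 1]
        rec.internal_val_score = float(score_fn(p, y_val))
    order = sorted(records, key=lambda r: (-r.internal_val_score, r.iteration))
    return order[:k]


@dataclass
class ELASModel:
    """The frozen ensemble: selected members plus preprocessing state.

    Prediction is the unweighted mean of member class probabilities.
    """

    members: list[BaseClassifierRecord]
    config: ELASConfig
    chosen_params: dict
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    preprocess: object | None = None
    history: list | None = None
    format_version: int = MODEL_FORMAT_VERSION

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.center is not None:
            X = (X - self.center) / self.scale
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.members:
            raise ValueError("model has no members")
        Xs = self._transform(X)
        acc = np.zeros((Xs.shape[0], 2))
        for rec in self.members:
            acc += rec.classifier.predict_proba(Xs)
        return acc / len(self.members)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format_version": self.format_version, "model": self}, path
        )

    @classmethod
    def load(cls, path: str | Path) -> "ELASModel":
        blob = joblib.load(path)
        if blob.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version: {blob.get('format_version')}"
            )
        return blob["model"]


def _validate_feasibility(config: ELASConfig, folds, y: np.ndarray) -> None:
    y = np.asarray(y)
    for f, (pool_idx, _) in enumerate(folds):
        counts = np.bincount(y[pool_idx].astype(int), minlength=2)
        if counts.min() < config.n_seed // 2:
            raise ValueError(
                f"fold {f}: minority class has {counts.min()} pool members, "
                f"fewer than n_seed/2 = {config.n_seed // 2}"
            )
        n_records = expected_record_count(len(pool_idx), config.n_seed,
                                          config.n_batch)
        if config.k > n_records:
            raise ValueError(
                f"fold {f}: k={config.k} exceeds the run's record count "
                f"{n_records} = (N_trainPool - n_seed) // n_batch + 1"
            )


def fit_elas(
    X: np.ndarray,
    y: np.ndarray,
    config: ELASConfig,
    *,
    collect_history: bool = False,
) -> ELASModel:
    """Train the full ensemble on a numeric feature matrix.

    Hyperparameters are tuned once by stratified-CV grid search on the full
    (standardized) training set and frozen.  All randomness descends from
    ``config.master_seed`` through one spawned stream per
    (fold, seed-initialization) run, so runs are reproducible and
    order-independent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")

    center = scale = None
    Xs = X
    if config.standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        scale = np.where(scale == 0, 1.0, scale)
        Xs = (X - center) / scale

    folds = make_internal_folds(y, config.n_folds, config.master_seed)
    _validate_feasibility(config, folds, y)

    chosen_params = tune(config.learner, Xs, y, n_folds=config.tune_folds,
                         metric=config.tune_metric, seed=config.master_seed)
    logger.info("tuned %s hyperparameters: %s", config.learner.family,
                chosen_params)

    streams = np.random.SeedSequence(config.master_seed).spawn(
        config.n_folds * config.t_seed
    )
    members: list[BaseClassifierRecord] = []
    history: list | None = [] if collect_history else None
    for f, (pool_idx, val_idx) in enumerate(folds):
        for t in range(config.t_seed):
            rng = np.random.default_rng(streams[f * config.t_seed + t])
            seed_pos = draw_balanced_seed(y[pool_idx], config.n_seed, rng)
            seed_idx = pool_idx[seed_pos]
            keep = np.ones(len(pool_idx), dtype=bool)
            keep[seed_pos] = False
            state = SplitState(
                internal_val_indices=val_idx.copy(),
                pool_indices=pool_idx[keep],
                train_data_indices=seed_idx,
                n_train_pool=len(pool_idx),
            )
            run_history: list | None = [] if collect_history else None
            records = active_sampling_run(Xs, y, state, config.learner,
                                          chosen_params, config, rng,
                                          history=run_history)
            top = select_top_k(records, Xs[val_idx], y[val_idx], config.k,
                               config.selection_metric)
            logger.info(
                "fold %d seed-init %d: %d records, kept top %d "
                "(best internal-val %s = %.4f)",
                f, t, len(records), len(top), config.selection_metric,
                top[0].internal_val_score,
            )
            members.extend(top)
            if collect_history:
                history.append({
                    "fold": f,
                    "t_seed": t,
                    "n_train_pool": state.n_train_pool,
                    "internal_val_indices": val_idx.copy(),
                    "iterations": run_history,
                })

    expected = config.n_folds * config.t_seed * config.k
    assert len(members) == expected, (len(members), expected)
    return ELASModel(members=members, config=config,
                     chosen_params=chosen_params, center=center, scale=scale,
                     history=history)


class ELASClassifier:
    """scikit-learn-style estimator facade: fit / predict_proba / predict.

    Slots the ensemble into generic CV and resampling harnesses.
    """

    def __init__(self, config: ELASConfig | None = None, **overrides):
        base = config if config is not None else ELASConfig()
        self.config = replace(base, **overrides) if overrides else base
        self.model_: ELASModel | None = None

    def fit(self, X, y) -> "ELASClassifier":
        self.model_ = fit_elas(X, y, self.config)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("estimator is not fitted")
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("estimator is not fitted")
        return self.model_.predict(X)
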