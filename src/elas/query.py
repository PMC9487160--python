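"""Ranked batch-mode sampling: score and select informative pool candidates.

A candidate's final score combines its predictive uncertainty with its
dissimilarity to the already-selected/training points:

    final = alpha * (1 - similarity) + (1 - alpha) * uncertainty

Under the default diversity-first convention, ``alpha`` is large while the
pool dwarfs the accumulated training data, so early picks favor diversity;
as sampling proceeds the weight shifts to uncertainty.  A literal-ratio
convention (alpha = n_train_data / (n_pool + n_train_data)) is available
behind a flag.  Similarity maps Euclidean distance to (0, 1] via
``1 / (1 + d)`` by default (``exp(-d)`` optionally); a candidate coinciding
with a training point scores similarity exactly 1.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from scipy.spatial.distance import cdist

SIMILARITY_KINDS = ("inverse", "exponential")


class ProbabilityClassifier(Protocol):
    """Anything exposing scikit-learn's ``predict_proba`` can drive a query."""

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...


def uncertainty_scores(probability_rows: np.ndarray, *, atol: float = 1e-6) -> np.ndarray:
    """Least-confident uncertainty: ``1 - max_j p_ij`` per row.

    Rows must be probability vectors (non-negative, summing to 1 within
    ``atol``).  Output lies in ``[0, 1 - 1/n_classes]``.
    """
    p = np.asarray(probability_rows, dtype=float)
    if p.ndim != 2:
        raise ValueError("probability_rows must be 2-D (n_candidates, n_classes)")
    if (p < -atol).any():
        raise ValueError("negative probability entries")
    sums = p.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=atol):
        worst = np.abs(sums - 1.0).max()
        raise ValueError(f"probability rows must sum to 1 (max deviation {worst:.2e})")
    return 1.0 - p.max(axis=1)


def mixing_weight(
    n_train_data: int,
    n_train_pool: int,
    *,
    literal: bool = False,
) -> float:
    """Uncertainty/diversity mixing weight alpha.

    Default (diversity-first): ``alpha = pool / (pool + data)`` — weight on
    the diversity term is large on early iterations when the pool dominates.
    With ``literal=True``: ``alpha = data / (pool + data)``.
    """
    if n_train_data < 0 or n_train_pool < 0:
        raise ValueError("counts must be non-negative")
    total = n_train_data + n_train_pool
    if total == 0:
        raise ValueError("n_train_data and n_train_pool cannot both be zero")
    num = n_train_data if literal else n_train_pool
    return num / total


def _distance_to_similarity(d: np.ndarray, kind: str) -> np.ndarray:
    if kind == "inverse":
        return 1.0 / (1.0 + d)
    if kind == "exponential":
        return np.exp(-d)
    raise ValueError(f"unknown similarity kind {kind!r}; expected {SIMILARITY_KINDS}")


def similarity_scores(
    candidates: np.ndarray,
    estimated_set: np.ndarray,
    *,
    kind: str = "inverse",
) -> np.ndarray:
    """Max similarity of each candidate to the estimated set, in (0, 1].

    Similarity is a monotone-decreasing map of Euclidean distance, so the
    max over the set is attained at the nearest neighbor.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    estimated_set = np.atleast_2d(np.asarray(estimated_set, dtype=float))
    if estimated_set.shape[0] == 0:
        raise ValueError("estimated_set must be nonempty")
    if candidates.shape[1] != estimated_set.shape[1]:
        raise ValueError(
            f"dimension mismatch: candidates have {candidates.shape[1]} columns, "
            f"estimated_set has {estimated_set.shape[1]}"
        )
    dmin = cdist(candidates, estimated_set).min(axis=1)
    return _distance_to_similarity(dmin, kind)


def final_scores(
    uncertainty: np.ndarray,
    similarity: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Combine scores: ``alpha * (1 - similarity) + (1 - alpha) * uncertainty``."""
    uncertainty = np.asarray(uncertainty, dtype=float)
    similarity = np.asarray(similarity, dtype=float)
    if uncertainty.shape != similarity.shape:
        raise ValueError("uncertainty and similarity must have the same shape")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * (1.0 - similarity) + (1.0 - alpha) * uncertainty


def rank_batch(
    classifier: ProbabilityClassifier,
    pool: np.ndarray,
    train_data: np.ndarray,
    batch_size: int,
    *,
    alpha_literal: bool = False,
    similarity_kind: str = "inverse",
    update_alpha: bool = True,
    score_log: list | None = None,
) -> list[int]:
    """Greedily select a batch of pool indices by ranked batch-mode scoring.

    At each step the estimated set is the training data plus the candidates
    already selected this round; similarity (and, when ``update_alpha`` is
    on, alpha — with one sample migrating pool -> train per pick) is
    recomputed, and the argmax-final-score candidate is appended.  Ties
    break toward the lowest pool index.  Returns
    ``min(batch_size, len(pool))`` distinct indices in selection order.

    ``score_log``, when given, receives one dict per selection step with the
    full per-candidate score vectors for audit export.
    """
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    train_data = np.atleast_2d(np.asarray(train_data, dtype=float))
    if pool.shape[0] == 0:
        raise ValueError("pool must be nonempty")
    if train_data.shape[0] == 0:
        raise ValueError("train_data must be nonempty")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if not hasattr(classifier, "predict_proba"):
        raise TypeError("classifier must expose predict_proba")

    proba = np.asarray(classifier.predict_proba(pool), dtype=float)
    uncertainty = uncertainty_scores(proba)

    n_pool = pool.shape[0]
    n_data = train_data.shape[0]
    # running max-similarity (min distance) to the growing estimated set
    min_dist = cdist(pool, train_data).min(axis=1)

    remaining = np.ones(n_pool, dtype=bool)
    selected: list[int] = []
    n_select = min(batch_size, n_pool)
    for _ in range(n_select):
        if update_alpha:
            alpha = mixing_weight(n_data + len(selected),
                                  n_pool - len(selected),
                                  literal=alpha_literal)
        else:
            alpha = mixing_weight(n_data, n_pool, literal=alpha_literal)
        similarity = _distance_to_similarity(min_dist, similarity_kind)
        scores = final_scores(uncertainty, similarity, alpha)
        scores = np.where(remaining, scores, -np.inf)
        pick = int(np.argmax(scores))  # first max -> lowest index on ties
        selected.append(pick)
        remaining[pick] = False
        if score_log is not None:
            score_log.append({
                "alpha": alpha,
                "uncertainty": uncertainty.copy(),
                "similarity": similarity,
                "final": final_scores(uncertainty, similarity, alpha),
                "selected": pick,
            })
        d_new = cdist(pool, pool[pick:pick + 1]).ravel()
        min_dist = np.minimum(min_dist, d_new)
    return selected
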