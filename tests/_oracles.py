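"""Independent brute-force oracles used by the test and acceptance suites.

These deliberately avoid the package's implementation paths: distances are
computed with raw numpy arithmetic (not scipy.cdist), every candidate score
is recomputed from scratch at every greedy step, and the AUROC oracle is
the O(n^2) pairwise comparison.
"""

from __future__ import annotations

import numpy as np


def euclid(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((np.asarray(a, float) - np.asarray(b, float)) ** 2).sum()))


def sim_map(d: float, kind: str) -> float:
    if kind == "inverse":
        return 1.0 / (1.0 + d)
    if kind == "exponential":
        return float(np.exp(-d))
    raise ValueError(kind)


def oracle_rank_batch(
    classifier,
    pool: np.ndarray,
    train_data: np.ndarray,
    batch_size: int,
    *,
    alpha_literal: bool = False,
    similarity_kind: str = "inverse",
    update_alpha: bool = True,
) -> list[int]:
    """Greedy ranked-batch selection, re-scored from scratch at every step."""
    pool = np.asarray(pool, float)
    train_data = np.asarray(train_data, float)
    proba = np.asarray(classifier.predict_proba(pool), float)
    uncertainty = 1.0 - proba.max(axis=1)

    n_pool0 = pool.shape[0]
    n_data0 = train_data.shape[0]
    selected: list[int] = []
    for _ in range(min(batch_size, n_pool0)):
        estimated = list(train_data) + [pool[i] for i in selected]
        if update_alpha:
            n_data = n_data0 + len(selected)
            n_pool = n_pool0 - len(selected)
        else:
            n_data, n_pool = n_data0, n_pool0
        num = n_data if alpha_literal else n_pool
        alpha = num / (n_data + n_pool)
        best_idx, best_score = None, -np.inf
        for i in range(n_pool0):
            if i in selected:
                continue
            sim = max(sim_map(euclid(pool[i], e), similarity_kind)
                      for e in estimated)
            score = alpha * (1.0 - sim) + (1.0 - alpha) * uncertainty[i]
            if score > best_score:  # strict: lowest index wins ties
                best_score, best_idx = score, i
        selected.append(best_idx)
    return selected


def oracle_auroc(scores, labels) -> float:
    """Pairwise-comparison AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def simulate_record_count(n_train_pool: int, n_seed: int, n_batch: int) -> int:
    """Direct loop simulation of the active-sampling bookkeeping."""
    pool = n_train_pool - n_seed
    records = 0
    while True:
        records += 1  # fit one classifier
        if pool < n_batch:
            return records
        pool -= n_batch
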