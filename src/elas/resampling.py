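"""Minimal SMOTE over-sampling and Tomek-link under-sampling.

Compact self-contained implementations used only by the baseline roster
(the usual third-party samplers are not available in the deployment
environment).  Both operate on numeric matrices with binary labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by interpolating synthetic minority samples.

    Each synthetic point lies uniformly on the segment between a random
    minority sample and one of its ``k`` nearest minority neighbors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    minority = int(np.argmin(counts))
    n_new = int(counts.max() - counts.min())
    if n_new == 0:
        return X.copy(), y.copy()
    Xm = X[y == minority]
    k_eff = min(k, len(Xm) - 1)
    if k_eff < 1:
        raise ValueError("minority class too small for SMOTE (needs >= 2 samples)")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    neighbors = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xm), size=n_new)
    mate = neighbors[base, rng.integers(0, k_eff, size=n_new)]
    gap = rng.random((n_new, 1))
    X_new = Xm[base] + gap * (Xm[mate] - Xm[base])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=int)]),
    )


def tomek_links(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop majority members of Tomek links (mutual cross-class nearest pairs)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    majority = int(np.argmax(counts))
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    nearest = nn.kneighbors(X, return_distance=False)[:, 1]
    drop = np.zeros(len(y), dtype=bool)
    for i, j in enumerate(nearest):
        if nearest[j] == i and y[i] != y[j]:
            drop[i if y[i] == majority else j] = True
    keep = ~drop
    return X[keep], y[keep]
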