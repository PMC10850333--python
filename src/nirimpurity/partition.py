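"""SPXY sample-set partitioning (joint X-Y distance Kennard-Stone).

The joint distance between samples i and j is

    d(i, j) = dx(i, j) / max(dx) + dy(i, j) / max(dy)

with dx the Euclidean distance between spectra and dy the absolute target
difference.  Selection is deterministic maximin: seed with the pair at
maximum joint distance, then repeatedly add the sample whose minimum
distance to the selected set is largest.  Ties break toward the smaller
index.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .spectra_io import SplitIndices

__all__ = ["spxy_split", "joint_distance_matrix"]


def joint_distance_matrix(X: np.ndarray, y: np.ndarray | None) -> np.ndarray:
    """Normalized joint X-Y distance matrix; the dy term is dropped if y is
    constant or None (plain Kennard-Stone limit)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    dx = squareform(pdist(X, metric="euclidean"))
    max_dx = dx.max()
    d = np.zeros_like(dx)
    if max_dx > 0:
        d += dx / max_dx
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("y length must match number of rows of X")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        dy = np.abs(y[:, None] - y[None, :])
        max_dy = dy.max()
        if max_dy > 0:
            d += dy / max_dy
    return d


def spxy_split(X: np.ndarray, y: np.ndarray, n_train: int | float) -> SplitIndices:
    """Deterministic SPXY partition into ``n_train`` calibration samples.

    ``n_train`` may be an integer count or a fraction in (0, 1).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if isinstance(n_train, float) and not float(n_train).is_integer():
        if not 0.0 < n_train < 1.0:
            raise ValueError(f"train fraction must be in (0, 1), got {n_train}")
        n_train = int(round(n_train * n))
    n_train = int(n_train)
    if not 1 <= n_train <= n - 1:
        raise ValueError(f"n_train must be in [1, {n - 1}], got {n_train}")

    d = joint_distance_matrix(X, y)
    if d.max() == 0:
        raise ValueError("all samples identical in X and y: joint distance is zero")

    # seed pair: argmax of d, lowest (i, j) on ties via C-order argmax
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    i, j = min(i, j), max(i, j)
    selected = [i] if n_train == 1 else [i, j]

    mask = np.ones(n, dtype=bool)
    mask[selected] = False
    # min distance of every remaining sample to the selected set
    min_d = d[:, selected].min(axis=1)
    while len(selected) < n_train:
        cand = np.where(mask, min_d, -np.inf)
        nxt = int(np.argmax(cand))  # argmax takes the first max -> lowest index tie-break
        selected.append(nxt)
        mask[nxt] = False
        min_d = np.minimum(min_d, d[:, nxt])

    test = [k for k in range(n) if mask[k]]
    return SplitIndices(train=tuple(selected), test=tuple(test))
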