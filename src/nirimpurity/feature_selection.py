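"""Wavelength selection: successive projections algorithm and random frog.

SPA is deterministic forward selection: starting from one column, each step
projects every remaining column onto the orthogonal complement of the span
of the chain so far and appends the column with the largest residual norm.
Candidate subsets (every start column x every chain length) are scored by
k-fold cross-validated MLR RMSE on the training block.

Random frog is a seeded stochastic subset search.  Each iteration proposes
a resized subset (grown with the top remaining variables by absolute inner
PLS coefficient, or shrunk to the top-ranked members of the current subset),
accepts improvements in inner CV RMSE outright and worse candidates with a
damped probability, and tallies per-variable inclusion counts.  A variable's
selection probability is its count divided by the iteration total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .chemometric_models import pls1_coefficients
from .spectra_io import SelectionResult

__all__ = [
    "SpaConfig",
    "FrogConfig",
    "FrogState",
    "successive_projection",
    "spa_select",
    "random_frog_select",
]


# ---------------------------------------------------------------------------
# SPA

@dataclass(frozen=True)
class SpaConfig:
    min_vars: int = 1
    max_vars: int = 25
    cv_folds: int = 5
    seed: int = 0  # fold shuffling only; the selector itself is deterministic

    def __post_init__(self) -> None:
        if self.min_vars < 1:
            raise ValueError("min_vars must be >= 1")
        if self.min_vars > self.max_vars:
            raise ValueError("min_vars must be <= max_vars")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def successive_projection(X: np.ndarray, start: int, k: int) -> tuple[int, ...]:
    """Projection chain of length ``k`` beginning at column ``start``.

    Columns are mean-centered before projecting.  At each step the remaining
    column with the largest norm orthogonal to the span of the chain is
    appended.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start < p:
        raise ValueError(f"start column {start} out of range [0, {p})")
    if k > min(p, n - 1):
        raise ValueError(f"chain length {k} exceeds min(p, n-1) = {min(p, n - 1)}")
    E = X - X.mean(axis=0)
    if np.linalg.norm(E[:, start]) == 0:
        raise ValueError(f"start column {start} has zero variance")
    chain = [start]
    R = E.copy()  # residuals of all columns against the chain span
    for _ in range(k - 1):
        v = R[:, chain[-1]]
        nv2 = float(v @ v)
        if nv2 > 0:
            R = R - np.outer(v, (v @ R) / nv2)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        chain.append(int(np.argmax(norms)))
    return tuple(chain)


def _cv_rmse_mlr(X: np.ndarray, y: np.ndarray, cols, kf: KFold) -> float:
    """k-fold CV RMSE of MLR (with intercept) on the given columns.

    Rank-deficient subsets fall back to the least-squares pseudo-solution.
    """
    Xc = X[:, list(cols)]
    n = len(y)
    A = np.column_stack([np.ones(n), Xc])
    sq = 0.0
    for tr, te in kf.split(A):
        coef, *_ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
        resid = A[te] @ coef - y[te]
        sq += float(resid @ resid)
    return float(np.sqrt(sq / n))


def spa_select(X_train: np.ndarray, y_train: np.ndarray, config: SpaConfig = SpaConfig()) -> SelectionResult:
    """Exhaustive SPA: best (start, chain length) subset by CV MLR RMSE.

    Ties break toward the smaller subset, then the lexicographically smaller
    sorted index tuple.  ``scores`` carries the RMSE-vs-length path of the
    winning start column.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, p = X.shape
    max_vars = min(config.max_vars, p, n - 2)
    if max_vars < config.min_vars:
        raise ValueError(
            f"max usable chain length {max_vars} below min_vars {config.min_vars}"
        )
    kf = KFold(n_splits=min(config.cv_folds, n), shuffle=True, random_state=config.seed)

    best = None  # (rmse, len, sorted subset, start, path)
    norms0 = np.linalg.norm(X - X.mean(axis=0), axis=0)
    for start in range(p):
        if norms0[start] == 0:
            continue
        chain = successive_projection(X, start, max_vars)
        path = np.full(max_vars + 1, np.nan)
        for m in range(config.min_vars, max_vars + 1):
            subset = chain[:m]
            score = _cv_rmse_mlr(X, y, subset, kf)
            path[m] = score
            key = (score, m, tuple(sorted(subset)))
            if best is None or key < best[:3]:
                best = (score, m, tuple(sorted(subset)), chain[:m], path)
    if best is None:
        raise ValueError("no usable start column (all columns constant)")
    _, m, _, subset, path = best
    return SelectionResult(
        selected=subset,
        scores=path,
        method="spa",
        extras={"cv_rmse": best[0], "n_vars": m},
    )


# ---------------------------------------------------------------------------
# Random frog

@dataclass(frozen=True)
class FrogConfig:
    n_iter: int = 1000
    q_init: int = 5
    theta: float = 0.3  # sd of the subset-size proposal is theta * Q
    eta: float = 0.1  # acceptance damping for worse candidates
    inner_components: int = 5
    cv_folds: int = 5
    center: bool = True
    seed: int = 0
    final_k: int | str = "auto"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.q_init < 1:
            raise ValueError("q_init must be >= 1")
        if self.theta < 0 or not 0 <= self.eta <= 1:
            raise ValueError("need theta >= 0 and 0 <= eta <= 1")
        if self.final_k != "auto" and int(self.final_k) < 1:
            raise ValueError("final_k must be 'auto' or a positive integer")


@dataclass
class FrogState:
    """Mutable search state exposed for inspection/resumption."""

    V0: tuple[int, ...]
    Q: int
    V_star: tuple[int, ...] = ()
    Q_star: int = 0
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    iteration: int = 0


class _InnerPLS:
    """Centered PLS1 inner model used for ranking and CV scoring."""

    def __init__(self, n_components: int, center: bool):
        self.n_components = n_components
        self.center = center

    def coefficients(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        ncomp = max(1, min(self.n_components, X.shape[1], X.shape[0] - 1))
        beta, _, _, _ = pls1_coefficients(X, y, ncomp)
        return beta

    def cv_rmse(self, X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
        n = len(y)
        kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
        ncomp = max(1, min(self.n_components, X.shape[1], X.shape[0] - 2))
        sq = 0.0
        for tr, te in kf.split(X):
            beta, y_mean, x_mean, _ = pls1_coefficients(X[tr], y[tr], ncomp)
            resid = (X[te] - x_mean) @ beta + y_mean - y[te]
            sq += float(resid @ resid)
        return float(np.sqrt(sq / n))


def random_frog_select(
    X_train: np.ndarray, y_train: np.ndarray, config: FrogConfig = FrogConfig()
) -> SelectionResult:
    """Random-frog selection probabilities and final subset.

    The proposal resizes the current subset with
    Q* = max(1, min(p, round(|Normal(Q, theta*Q)|))); growth adds the
    top remaining variables ranked by absolute coefficient of an inner PLS
    model fitted on the full variable set, shrinkage keeps the top members
    of the current subset ranked on its own inner model.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    n, p = X.shape
    if config.q_init > p:
        raise ValueError(f"q_init {config.q_init} exceeds number of variables {p}")
    if config.center:
        X = X - X.mean(axis=0)
        y = y - y.mean()
    rng = np.random.default_rng(config.seed)
    inner = _InnerPLS(config.inner_components, config.center)

    # global ranking of variables for growth proposals (fixed: data do not change)
    beta_full = inner.coefficients(X, y)
    global_rank = np.argsort(-np.abs(beta_full), kind="stable")

    def score(subset: tuple[int, ...]) -> float:
        return inner.cv_rmse(X[:, list(subset)], y, config.cv_folds, config.seed)

    V0 = tuple(int(i) for i in sorted(rng.choice(p, size=config.q_init, replace=False)))
    rmse0 = score(V0)
    counts = np.zeros(p)
    state = FrogState(V0=V0, Q=len(V0), counts=counts)
    for it in range(config.n_iter):
        Q = len(V0)
        q_star = int(max(1, min(p, round(abs(rng.normal(Q, config.theta * Q))))))
        if q_star > Q:
            in_v0 = np.zeros(p, dtype=bool)
            in_v0[list(V0)] = True
            extras = [int(j) for j in global_rank if not in_v0[j]][: q_star - Q]
            V_star = tuple(sorted(V0 + tuple(extras)))
        elif q_star < Q:
            beta_sub = inner.coefficients(X[:, list(V0)], y)
            order = np.argsort(-np.abs(beta_sub), kind="stable")[:q_star]
            V_star = tuple(sorted(V0[i] for i in order))
        else:
            V_star = V0
        if V_star == V0:
            rmse_star = rmse0
        else:
            rmse_star = score(V_star)
        if not np.isfinite(rmse_star):
            raise ValueError(f"non-finite inner-model RMSE at iteration {it}")
        accept = rmse_star <= rmse0
        if not accept and rmse_star > 0:
            accept = rng.random() < config.eta * (rmse0 / rmse_star)
        if accept:
            V0, rmse0 = V_star, rmse_star
        counts[list(V0)] += 1
        state.V0, state.Q = V0, len(V0)
        state.V_star, state.Q_star = V_star, q_star
        state.iteration = it + 1

    probs = counts / config.n_iter
    order = np.argsort(-probs, kind="stable")
    if config.final_k == "auto":
        best = None
        max_k = min(p, max(1, n - 2))
        for k in range(1, max_k + 1):
            subset = tuple(sorted(int(j) for j in order[:k]))
            key = (score(subset), k)
            if best is None or key < best[:2]:
                best = (*key, subset)
        selected = best[2]
    else:
        k = int(config.final_k)
        if k > p:
            raise ValueError(f"final_k {k} exceeds number of variables {p}")
        selected = tuple(sorted(int(j) for j in order[:k]))
    return SelectionResult(
        selected=selected,
        scores=probs,
        method="frog",
        extras={"counts": counts, "state": state},
    )
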