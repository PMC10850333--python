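"""PLSR, epsilon-SVR and LSSVM regression with seeded CV hyperparameter search.

PLSR is a NIPALS PLS1 on centered data.  SVR wraps scikit-learn's libsvm
solver behind this module's contract (RBF kernel, epsilon tube).  LSSVM
solves the (n+1)x(n+1) KKT system

    [[0, 1^T], [1, K + I/gamma]] @ [b; alpha] = [0; y]

with K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)) and predicts
f(x) = sum_i alpha_i k(x_i, x) + b.

Hyperparameter grids are scored by seeded 5-fold CV RMSE; ties break toward
the smaller regularization value, then the smaller kernel width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "PLSRModel",
    "SVRModel",
    "LSSVMModel",
    "fit_plsr",
    "fit_svr",
    "fit_lssvm",
    "predict",
    "pls1_coefficients",
    "save_model",
    "load_model",
    "DEFAULT_GRID",
]

DEFAULT_N_COMPONENTS = 4
DEFAULT_GRID = tuple(10.0**k for k in range(-3, 4))
DEFAULT_EPSILON = 0.01


# ---------------------------------------------------------------------------
# PLS1 core (shared with the random-frog inner model)

def pls1_coefficients(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """NIPALS PLS1 regression on centered data.

    Returns (beta, y_mean, x_mean, weights) such that
    yhat = (X - x_mean) @ beta + y_mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * max(1.0, np.abs(f).max()):
            # residual exhausted: truncate
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 0:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        pvec = E.T @ t / tt
        qa = float(f @ t / tt)
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa
    if W.shape[1] == 0:
        return np.zeros(p), y_mean, x_mean, W
    beta = W @ np.linalg.solve(P.T @ W, q)
    return beta, y_mean, x_mean, W


@dataclass(frozen=True)
class PLSRModel:
    n_components: int
    coef: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    feature_indices: tuple[int, ...] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_features(X, self.x_mean.size, self.feature_indices)
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    feature_indices: Sequence[int] | None = None,
) -> PLSRModel:
    """Fit NIPALS PLS1; ``n_components`` must not exceed min(n-1, p)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    _check_xy(X, y)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} out of range [1, {min(n - 1, p)}] for shape {X.shape}"
        )
    beta, y_mean, x_mean, _ = pls1_coefficients(X, y, n_components)
    return PLSRModel(
        n_components=n_components,
        coef=beta,
        x_mean=x_mean,
        y_mean=y_mean,
        feature_indices=None if feature_indices is None else tuple(int(i) for i in feature_indices),
    )


# ---------------------------------------------------------------------------
# epsilon-SVR (RBF)

@dataclass(frozen=True)
class SVRModel:
    C: float
    gamma: float
    epsilon: float
    support_vectors: np.ndarray
    support_idx: np.ndarray  # row indices of the support vectors in the training set
    dual_coef: np.ndarray  # alpha_i - alpha_i^*, one per support vector
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    feature_indices: tuple[int, ...] | None = None
    cv_seed: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_features(X, self.x_mean.size, self.feature_indices)
        Z = (X - self.x_mean) / self.x_scale
        K = np.exp(-self.gamma * cdist(Z, self.support_vectors, "sqeuclidean"))
        return K @ self.dual_coef + self.intercept

    def dual_objective(self, y: np.ndarray) -> float:
        """Standard SVR dual objective at the stored solution (for audits).

        Since alpha_i * alpha_i^* == 0 at optimum, |alpha_i - alpha_i^*|
        equals alpha_i + alpha_i^*.
        """
        sv = self.support_vectors
        beta = self.dual_coef
        K = np.exp(-self.gamma * cdist(sv, sv, "sqeuclidean"))
        y_sv = np.asarray(y, dtype=float).ravel()[self.support_idx.astype(int)]
        return float(
            -0.5 * beta @ K @ beta - self.epsilon * np.sum(np.abs(beta)) + y_sv @ beta
        )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return (X - mean) / scale, mean, scale


def _cv_rmse(fit_fn, X: np.ndarray, y: np.ndarray, n_folds: int, seed: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sq = 0.0
    for tr, te in kf.split(X):
        model = fit_fn(X[tr], y[tr])
        resid = model.predict(X[te]) - y[te]
        sq += float(resid @ resid)
    return float(np.sqrt(sq / len(y)))


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float | None = None,
    gamma: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
    C_grid: Sequence[float] = DEFAULT_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    feature_indices: Sequence[int] | None = None,
    standardize: bool = True,
) -> SVRModel:
    """Fit epsilon-insensitive RBF SVR; grid-search C and gamma by CV if unset."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    _check_xy(X, y)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if standardize:
        Z, x_mean, x_scale = _standardize(X)
    else:
        Z, x_mean, x_scale = X, np.zeros(X.shape[1]), np.ones(X.shape[1])

    def _fit(Zi, yi, c, g):
        sk = _SkSVR(kernel="rbf", C=c, gamma=g, epsilon=epsilon, tol=1e-8)
        sk.fit(Zi, yi)
        return sk

    if C is None or gamma is None:
        if len(C_grid) == 0 or len(gamma_grid) == 0:
            raise ValueError("degenerate hyperparameter grid")
        folds = min(cv_folds, len(y))
        best = None
        for c in sorted(set(float(v) for v in C_grid)):
            for g in sorted(set(float(v) for v in gamma_grid)):
                score = _cv_rmse(
                    lambda Xi, yi: _fit(Xi, yi, c, g), Z, y, folds, seed
                )
                key = (score, c, g)
                if best is None or key < best:
                    best = key
        _, C, gamma = best
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    sk = _fit(Z, y, C, gamma)
    return SVRModel(
        C=float(C),
        gamma=float(gamma),
        epsilon=float(epsilon),
        support_vectors=sk.support_vectors_.copy(),
        support_idx=sk.support_.astype(int).copy(),
        dual_coef=sk.dual_coef_.ravel().copy(),
        intercept=float(sk.intercept_[0]),
        x_mean=x_mean,
        x_scale=x_scale,
        feature_indices=None if feature_indices is None else tuple(int(i) for i in feature_indices),
        cv_seed=seed,
    )


# ---------------------------------------------------------------------------
# LSSVM (RBF)

@dataclass(frozen=True)
class LSSVMModel:
    gamma: float  # regularization
    sigma: float  # RBF width
    alpha: np.ndarray
    bias: float
    train_X: np.ndarray  # standardized training inputs (kernel expansion points)
    x_mean: np.ndarray
    x_scale: np.ndarray
    feature_indices: tuple[int, ...] | None = None
    cv_seed: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_features(X, self.x_mean.size, self.feature_indices)
        Z = (X - self.x_mean) / self.x_scale
        K = np.exp(-cdist(Z, self.train_X, "sqeuclidean") / (2.0 * self.sigma**2))
        return K @ self.alpha + self.bias


def _lssvm_solve(Z: np.ndarray, y: np.ndarray, gamma: float, sigma: float):
    n = len(y)
    K = np.exp(-cdist(Z, Z, "sqeuclidean") / (2.0 * sigma**2))
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular LSSVM KKT system at gamma={gamma}; increase the 1/gamma ridge"
        ) from exc
    return float(sol[0]), sol[1:]


def fit_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float | None = None,
    sigma: float | None = None,
    gamma_grid: Sequence[float] = DEFAULT_GRID,
    sigma2_grid: Sequence[float] = DEFAULT_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    feature_indices: Sequence[int] | None = None,
) -> LSSVMModel:
    """Fit RBF LSSVM via the KKT linear system; CV grid search if unset.

    ``sigma2_grid`` ladders the squared kernel width.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    _check_xy(X, y)
    Z, x_mean, x_scale = _standardize(X)

    def _make(Zi, yi, g, s):
        b, a = _lssvm_solve(Zi, yi, g, s)
        return _RawLssvm(Zi, a, b, s)

    if gamma is None or sigma is None:
        if len(gamma_grid) == 0 or len(sigma2_grid) == 0:
            raise ValueError("degenerate hyperparameter grid")
        folds = min(cv_folds, len(y))
        best = None
        for g in sorted(set(float(v) for v in gamma_grid)):
            for s2 in sorted(set(float(v) for v in sigma2_grid)):
                s = float(np.sqrt(s2))
                score = _cv_rmse(lambda Xi, yi: _make(Xi, yi, g, s), Z, y, folds, seed)
                key = (score, g, s)
                if best is None or key < best:
                    best = key
        _, gamma, sigma = best
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be positive")
    bias, alpha = _lssvm_solve(Z, y, gamma, sigma)
    return LSSVMModel(
        gamma=float(gamma),
        sigma=float(sigma),
        alpha=alpha,
        bias=bias,
        train_X=Z,
        x_mean=x_mean,
        x_scale=x_scale,
        feature_indices=None if feature_indices is None else tuple(int(i) for i in feature_indices),
        cv_seed=seed,
    )


class _RawLssvm:
    """Minimal predictor used inside CV loops (already-standardized inputs)."""

    def __init__(self, Z, alpha, bias, sigma):
        self.Z, self.alpha, self.bias, self.sigma = Z, alpha, bias, sigma

    def predict(self, X):
        K = np.exp(-cdist(X, self.Z, "sqeuclidean") / (2.0 * self.sigma**2))
        return K @ self.alpha + self.bias


# ---------------------------------------------------------------------------
# shared helpers and artifact IO

def _check_xy(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(y) != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} entries")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")


def _check_features(
    X: np.ndarray, expected: int, feature_indices: tuple[int, ...] | None
) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != expected:
        hint = (
            f" (model was fitted on columns {list(feature_indices)})"
            if feature_indices is not None
            else ""
        )
        raise ValueError(f"expected {expected} features, got {X.shape[1]}{hint}")
    return X


def predict(model, X_new: np.ndarray) -> np.ndarray:
    """Uniform prediction entry point for any fitted model in this module."""
    return model.predict(X_new)


_MODEL_TAGS = {"PLSRModel": PLSRModel, "SVRModel": SVRModel, "LSSVMModel": LSSVMModel}


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted model to a self-contained JSON artifact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"kind": type(model).__name__}
    for key, val in vars(model).items():
        if isinstance(val, np.ndarray):
            payload[key] = {"__array__": val.tolist(), "shape": list(val.shape)}
        else:
            payload[key] = val
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)
    return path


def load_model(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    kind = payload.pop("kind")
    cls = _MODEL_TAGS[kind]
    kwargs = {}
    for key, val in payload.items():
        if isinstance(val, dict) and "__array__" in val:
            kwargs[key] = np.asarray(val["__array__"], dtype=float).reshape(val["shape"])
        elif isinstance(val, list):
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)
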