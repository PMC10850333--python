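"""Evaluation metrics: RMSE, Pearson R, and an audit-only variant of R.

The headline correlation coefficient is the Pearson product-moment
correlation.  ``printed_r_eq5`` evaluates a residual-over-dispersion ratio
kept only for auditing: it returns 0 at perfect prediction, so it cannot
serve as a goodness-of-fit correlation and is never reported as R.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["rmse", "pearson_r", "printed_r_eq5", "EvalReport", "evaluate_split"]


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean square error sqrt(mean((yhat - y)^2))."""
    y, yhat = _pair(y, yhat)
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson product-moment correlation between truth and predictions."""
    y, yhat = _pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 points for a correlation")
    sy = y - y.mean()
    sp = yhat - yhat.mean()
    denom = np.sqrt(np.sum(sy**2) * np.sum(sp**2))
    if denom == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.clip(np.sum(sy * sp) / denom, -1.0, 1.0))


def printed_r_eq5(y: np.ndarray, yhat: np.ndarray) -> float:
    """Audit-only ratio sqrt(sum((yhat-y)^2) / sum((yhat - mean(y))^2)).

    Returns 0 when yhat == y, demonstrating it is not a correlation; kept
    solely so reports can expose the discrepancy.
    """
    y, yhat = _pair(y, yhat)
    denom = float(np.sum((yhat - np.mean(y)) ** 2))
    if denom == 0:
        raise ValueError("zero denominator: predictions are constant at mean(y)")
    return float(np.sqrt(np.sum((yhat - y) ** 2) / denom))


@dataclass(frozen=True)
class EvalReport:
    """R and RMSE for one dataset split."""

    r: float
    rmse: float
    n: int
    split: str

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if self.n < 2:
            raise ValueError("need n >= 2")

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_split(y: np.ndarray, yhat: np.ndarray, split: str) -> EvalReport:
    y, yhat = _pair(y, yhat)
    return EvalReport(r=pearson_r(y, yhat), rmse=rmse(y, yhat), n=int(y.size), split=split)
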