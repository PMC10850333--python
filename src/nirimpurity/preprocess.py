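"""Spectral pretreatments: min-max normalization, SNV, and Savitzky-Golay.

All three operate row-wise on an (n, p) matrix of spectra and preserve
shape.  They are stateless per spectrum except per-wavelength min-max
normalization, which must be fitted on the training rows only to avoid
leaking test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PreprocessConfig",
    "minmax_normalize",
    "snv",
    "savitzky_golay",
    "apply_preprocess",
    "PREPROCESS_METHODS",
]

PREPROCESS_METHODS = ("normalization", "snv", "sg", "none")


@dataclass(frozen=True)
class PreprocessConfig:
    method: str = "none"
    sg_window: int = 11
    sg_polyorder: int = 2
    normalization_axis: str = "per_spectrum"

    def __post_init__(self) -> None:
        if self.method not in PREPROCESS_METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {PREPROCESS_METHODS}")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be an odd integer >= 3, got {self.sg_window}")
        if not 0 <= self.sg_polyorder < self.sg_window:
            raise ValueError(
                f"sg_polyorder must satisfy 0 <= polyorder < window, got "
                f"{self.sg_polyorder} with window {self.sg_window}"
            )
        if self.normalization_axis not in ("per_spectrum", "per_wavelength"):
            raise ValueError(f"unknown normalization_axis {self.normalization_axis!r}")


def _check_finite(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains NaN/Inf")
    return np.atleast_2d(X)


def minmax_normalize(
    X: np.ndarray,
    axis: str = "per_spectrum",
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Rescale to [0, 1] via (x - min) / (max - min) along the chosen axis.

    ``per_spectrum`` rescales each row over its channels; ``per_wavelength``
    rescales each column.  For ``per_wavelength``, pass ``stats=(mn, mx)``
    computed on the training rows to transform held-out rows consistently.
    """
    X = _check_finite(X)
    if axis == "per_spectrum":
        mn = X.min(axis=1, keepdims=True)
        mx = X.max(axis=1, keepdims=True)
        rng = mx - mn
        if np.any(rng == 0):
            row = int(np.flatnonzero(rng.ravel() == 0)[0])
            raise ValueError(f"degenerate range: row {row} is constant (max == min)")
    elif axis == "per_wavelength":
        if stats is not None:
            mn, mx = (np.asarray(s, dtype=float).reshape(1, -1) for s in stats)
        else:
            mn = X.min(axis=0, keepdims=True)
            mx = X.max(axis=0, keepdims=True)
        rng = mx - mn
        if np.any(rng == 0):
            col = int(np.flatnonzero(rng.ravel() == 0)[0])
            raise ValueError(f"degenerate range: column {col} is constant (max == min)")
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return (X - mn) / rng


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-row centering and unit sample-std scaling.

    Uses the n-1 denominator for the standard deviation.
    """
    X = _check_finite(X)
    if X.shape[1] < 2:
        raise ValueError("SNV requires at least 2 points per spectrum")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        row = int(np.flatnonzero(sd.ravel() == 0)[0])
        raise ValueError(f"zero-variance spectrum at row {row}")
    return (X - mean) / sd


def savitzky_golay(X: np.ndarray, window: int = 11, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing of each row; shape-preserving.

    Edge points are obtained by fitting the full window anchored at the
    boundary and evaluating the polynomial at the edge position
    (scipy's ``mode='interp'``), so wavelength indexing stays aligned.
    """
    X = _check_finite(X)
    p = X.shape[1]
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if window > p:
        raise ValueError(f"window {window} exceeds number of channels {p}")
    return savgol_filter(X, window_length=window, polyorder=polyorder, axis=1, mode="interp")


def apply_preprocess(
    cfg: PreprocessConfig, X_train: np.ndarray, X_other: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply a pretreatment to training spectra and optionally to held-out spectra.

    Only per-wavelength min-max normalization carries state from train to
    the held-out block; everything else is computed row-locally.
    """
    if cfg.method == "none":
        out_tr = np.array(X_train, dtype=float)
        out_ot = None if X_other is None else np.array(X_other, dtype=float)
    elif cfg.method == "normalization":
        if cfg.normalization_axis == "per_wavelength":
            Xt = _check_finite(X_train)
            stats = (Xt.min(axis=0), Xt.max(axis=0))
            out_tr = minmax_normalize(X_train, "per_wavelength", stats=stats)
            out_ot = (
                None
                if X_other is None
                else minmax_normalize(X_other, "per_wavelength", stats=stats)
            )
        else:
            out_tr = minmax_normalize(X_train, "per_spectrum")
            out_ot = None if X_other is None else minmax_normalize(X_other, "per_spectrum")
    elif cfg.method == "snv":
        out_tr = snv(X_train)
        out_ot = None if X_other is None else snv(X_other)
    elif cfg.method == "sg":
        out_tr = savitzky_golay(X_train, cfg.sg_window, cfg.sg_polyorder)
        out_ot = (
            None
            if X_other is None
            else savitzky_golay(X_other, cfg.sg_window, cfg.sg_polyorder)
        )
    else:  # pragma: no cover - guarded by PreprocessConfig
        raise ValueError(cfg.method)
    return out_tr, out_ot
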