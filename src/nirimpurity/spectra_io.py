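"""Reading, validating and writing spectra tables and pipeline artifacts.

The on-disk format is a plain CSV with one row per sample: a ``sample_id``
column, one column per spectral channel whose header is the wavelength in
nanometres, and a named target column (default ``"impurity"``).  Split and
selection artifacts are small JSON sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SplitIndices",
    "SelectionResult",
    "read_spectra",
    "write_spectra",
    "read_split",
    "write_split",
    "read_selection",
    "write_selection",
]

DEFAULT_TARGET_COLUMN = "impurity"


@dataclass(frozen=True)
class SpectraSet:
    """A validated n x p reflectance matrix with wavelength grid and targets.

    Attributes
    ----------
    wavelengths : ndarray, shape (p,)
        Strictly increasing wavelength grid in nm.
    reflectance : ndarray, shape (n, p)
        Non-negative, finite reflectance values; one row per sample.
    target : ndarray, shape (n,)
        Impurity mass fraction per sample.
    sample_ids : tuple of str, length n
        Unique sample labels.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    target: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        X = np.asarray(self.reflectance, dtype=float)
        y = np.asarray(self.target, dtype=float)
        ids = tuple(str(s) for s in self.sample_ids)
        if X.ndim != 2:
            raise ValueError(f"reflectance must be 2-D, got shape {X.shape}")
        n, p = X.shape
        if n == 0:
            raise ValueError("at least one sample is required (empty target)")
        if wl.ndim != 1 or wl.size != p:
            raise ValueError(
                f"wavelength grid length {wl.size} != number of spectral columns {p}"
            )
        if np.any(np.diff(wl) <= 0):
            bad = int(np.argmax(np.diff(wl) <= 0))
            raise ValueError(
                f"wavelengths must be strictly increasing (violation after index {bad})"
            )
        if y.ndim != 1 or y.size != n:
            raise ValueError(f"target length {y.size} != number of rows {n}")
        if len(ids) != n:
            raise ValueError(f"sample_ids length {len(ids)} != number of rows {n}")
        if len(set(ids)) != n:
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        if not np.all(np.isfinite(X)):
            r, c = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(
                f"non-finite reflectance at row {int(r)} (sample {ids[int(r)]}), column {int(c)}"
            )
        if not np.all(np.isfinite(y)):
            r = int(np.argwhere(~np.isfinite(y))[0])
            raise ValueError(f"non-finite target at row {r} (sample {ids[r]})")
        if np.any(X < 0):
            r, c = np.argwhere(X < 0)[0]
            raise ValueError(
                f"negative reflectance at row {int(r)}, column {int(c)}: {X[r, c]}"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", X)
        object.__setattr__(self, "target", y)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """Row-subset by sample indices, preserving order of `indices`."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths=self.wavelengths,
            reflectance=self.reflectance[idx],
            target=self.target[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test sample index sets covering 0..n-1."""

    train: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        train = tuple(int(i) for i in self.train)
        test = tuple(int(i) for i in self.test)
        if not train or not test:
            raise ValueError("both train and test must be non-empty")
        tr, te = set(train), set(test)
        if len(tr) != len(train) or len(te) != len(test):
            raise ValueError("split indices contain duplicates")
        if tr & te:
            raise ValueError(f"train/test overlap: {sorted(tr & te)[:5]}")
        n = len(train) + len(test)
        if tr | te != set(range(n)):
            raise ValueError("train and test must partition 0..n-1")
        object.__setattr__(self, "train", train)
        object.__setattr__(self, "test", test)

    @property
    def n(self) -> int:
        return len(self.train) + len(self.test)


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected wavelength indices plus per-variable diagnostics.

    ``scores`` holds the chain-length RMSE path for SPA or per-variable
    selection probabilities for random frog.
    """

    selected: tuple[int, ...]
    scores: np.ndarray
    method: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sel = tuple(int(i) for i in self.selected)
        if len(set(sel)) != len(sel):
            raise ValueError("selected indices must be unique")
        if sel and min(sel) < 0:
            raise ValueError("selected indices must be non-negative")
        object.__setattr__(self, "selected", sel)
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))


def read_spectra(path: str | Path, target_column: str = DEFAULT_TARGET_COLUMN) -> SpectraSet:
    """Read a spectra CSV into a validated :class:`SpectraSet`.

    Spectral columns are identified by numeric headers (wavelength in nm);
    the target column by name.  A ``sample_id`` column is used if present,
    otherwise row numbers become IDs.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if target_column not in df.columns:
        raise ValueError(
            f"{path}: missing target column {target_column!r}; columns present: "
            f"{list(df.columns)[:8]}..."
        )
    wl_cols: list[str] = []
    wl_vals: list[float] = []
    for col in df.columns:
        try:
            wl_vals.append(float(col))
            wl_cols.append(col)
        except ValueError:
            continue
    if not wl_cols:
        raise ValueError(f"{path}: no numeric wavelength columns found")

    if "sample_id" in df.columns:
        ids = df["sample_id"].tolist()
    else:
        ids = [str(i) for i in range(len(df))]

    def _parse_block(cols: list[str], what: str) -> np.ndarray:
        block = df[cols]
        if block.isna().any().any():
            row = int(block.isna().any(axis=1).idxmax())
            col = block.columns[block.isna().iloc[row].values.argmax()]
            raise ValueError(f"{path}: missing {what} cell at row {row}, column {col!r}")
        try:
            return block.astype(float).to_numpy()
        except ValueError:
            for r in range(len(block)):
                for c in cols:
                    try:
                        float(block.iloc[r][c])
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric {what} cell at row {r}, column {c!r}: "
                            f"{block.iloc[r][c]!r}"
                        ) from None
            raise

    X = _parse_block(wl_cols, "reflectance")
    y = _parse_block([target_column], "target").ravel()

    order = np.argsort(wl_vals, kind="stable")
    wl = np.asarray(wl_vals, dtype=float)[order]
    X = X[:, order]
    return SpectraSet(wavelengths=wl, reflectance=X, target=y, sample_ids=tuple(ids))


def write_spectra(
    data: SpectraSet, path: str | Path, target_column: str = DEFAULT_TARGET_COLUMN
) -> Path:
    """Write a :class:`SpectraSet` as CSV, round-trippable bit-for-bit.

    Floats are written with repr precision (17 significant digits) so that
    ``read_spectra(write_spectra(S)) == S`` exactly.
    """
    if data.target.size == 0:
        raise ValueError("cannot write a SpectraSet with an empty target")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = ["sample_id"] + [repr(float(w)) for w in data.wavelengths] + [target_column]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(header) + "\n")
        for sid, row, y in zip(data.sample_ids, data.reflectance, data.target):
            cells = [sid] + [repr(float(v)) for v in row] + [repr(float(y))]
            fh.write(",".join(cells) + "\n")
    return path


def write_split(split: SplitIndices, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"train": list(split.train), "test": list(split.test)}, fh)
    return path


def read_split(path: str | Path) -> SplitIndices:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return SplitIndices(train=tuple(obj["train"]), test=tuple(obj["test"]))


def write_selection(
    result: SelectionResult, path: str | Path, wavelengths: np.ndarray | None = None
) -> Path:
    """Write a selection artifact; reports both indices and nm when a grid is given."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    obj = {
        "method": result.method,
        "selected": list(result.selected),
        "scores": [float(s) for s in np.ravel(result.scores)],
    }
    if wavelengths is not None:
        obj["wavelengths_nm"] = [float(wavelengths[i]) for i in result.selected]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)
    return path


def read_selection(path: str | Path) -> SelectionResult:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    return SelectionResult(
        selected=tuple(obj["selected"]),
        scores=np.asarray(obj["scores"], dtype=float),
        method=obj["method"],
    )
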