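"""Config-driven orchestration of the preprocessing x selector x model grid.

``run_grid`` reproduces the report structure of the modelling tables: for
each preprocessing and each selector it selects wavelengths on the training
block only, then fits each requested model with seeded CV-tuned
hyperparameters and evaluates calibration and prediction splits.
``run_activation_ablation`` (in :mod:`.cotton_net`) covers the network grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometric_models import fit_lssvm, fit_plsr, fit_svr
from .cotton_net import TrainConfig, run_activation_ablation
from .feature_selection import FrogConfig, SpaConfig, random_frog_select, spa_select
from .metrics import evaluate_split
from .partition import spxy_split
from .preprocess import PreprocessConfig, apply_preprocess
from .spectra_io import SpectraSet, SplitIndices

__all__ = ["GridConfig", "run_grid", "best_model_comparison", "grid_to_frame"]

_PRETTY = {"sg": "SG", "normalization": "Normalization", "snv": "SNV",
           "spa": "SPA", "frog": "RF"}


@dataclass(frozen=True)
class GridConfig:
    preprocessors: tuple[str, ...] = ("sg", "normalization", "snv")
    selectors: tuple[str, ...] = ("spa", "frog")
    models: tuple[str, ...] = ("plsr", "svr", "lssvm")
    n_train: int | float = 180
    plsr_components: int = 4
    spa: SpaConfig = field(default_factory=SpaConfig)
    frog: FrogConfig = field(default_factory=FrogConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.preprocessors and self.selectors and self.models):
            raise ValueError("preprocessors, selectors and models must be non-empty")
        unknown = set(self.models) - {"plsr", "svr", "lssvm"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")


def _select(method: str, Xtr: np.ndarray, ytr: np.ndarray, cfg: GridConfig):
    if method == "spa":
        return spa_select(Xtr, ytr, cfg.spa)
    if method == "frog":
        return random_frog_select(Xtr, ytr, cfg.frog)
    raise ValueError(f"unknown selector {method!r}")


def _fit(model: str, Xtr, ytr, cfg: GridConfig, feature_indices):
    if model == "plsr":
        ncomp = min(cfg.plsr_components, Xtr.shape[1], Xtr.shape[0] - 1)
        return fit_plsr(Xtr, ytr, ncomp, feature_indices=feature_indices)
    if model == "svr":
        return fit_svr(Xtr, ytr, seed=cfg.seed, feature_indices=feature_indices)
    if model == "lssvm":
        return fit_lssvm(Xtr, ytr, seed=cfg.seed, feature_indices=feature_indices)
    raise ValueError(f"unknown model {model!r}")


def run_grid(
    cfg: GridConfig, data: SpectraSet, split: SplitIndices | None = None
) -> list[dict]:
    """Run every preprocessing x selector x model combination.

    Returns one row dict per combination with columns ``model``,
    ``pre_processing`` (e.g. ``"SG + SPA"``), ``VN``, ``R_C``, ``RMSE_C``,
    ``R_P``, ``RMSE_P``.
    """
    if split is None:
        split = spxy_split(data.reflectance, data.target, cfg.n_train)
    tr, te = list(split.train), list(split.test)
    X, y = data.reflectance, data.target
    rows: list[dict] = []
    for prep in cfg.preprocessors:
        Xtr, Xte = apply_preprocess(PreprocessConfig(method=prep), X[tr], X[te])
        for selector in cfg.selectors:
            try:
                selection = _select(selector, Xtr, y[tr], cfg)
            except Exception as exc:
                raise RuntimeError(f"selection failed at ({prep} + {selector}): {exc}") from exc
            cols = list(selection.selected)
            for model_name in cfg.models:
                try:
                    model = _fit(model_name, Xtr[:, cols], y[tr], cfg, selection.selected)
                except Exception as exc:
                    raise RuntimeError(
                        f"fit failed at ({prep} + {selector}, {model_name}): {exc}"
                    ) from exc
                cal = evaluate_split(y[tr], model.predict(Xtr[:, cols]), "train")
                prd = evaluate_split(y[te], model.predict(Xte[:, cols]), "test")
                rows.append(
                    {
                        "model": model_name,
                        "pre_processing": f"{_PRETTY[prep]} + {_PRETTY[selector]}",
                        "preprocess": prep,
                        "selector": selector,
                        "VN": len(cols),
                        "selected": list(selection.selected),
                        "R_C": cal.r,
                        "RMSE_C": cal.rmse,
                        "R_P": prd.r,
                        "RMSE_P": prd.rmse,
                        "seed": cfg.seed,
                    }
                )
    return rows


def grid_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Tabular view with the report columns of the modelling tables."""
    df = pd.DataFrame(rows)
    cols = [c for c in ("model", "pre_processing", "VN", "R_C", "RMSE_C", "R_P", "RMSE_P") if c in df]
    return df[cols + [c for c in df.columns if c not in cols]]


def best_model_comparison(grid_rows: list[dict], ablation_rows: list[dict]) -> dict:
    """Best row (max R_P, ties by lower RMSE_P) of each report, side by side."""
    if not grid_rows or not ablation_rows:
        raise ValueError("both reports must be non-empty")

    def best(rows):
        return min(rows, key=lambda r: (-r["R_P"], r["RMSE_P"]))

    bg, ba = best(grid_rows), best(ablation_rows)
    return {
        "best_chemometric": bg,
        "best_net": ba,
        "net_wins_on_R_P": bool(
            (ba["R_P"], -ba["RMSE_P"]) > (bg["R_P"], -bg["RMSE_P"])
        ),
    }
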