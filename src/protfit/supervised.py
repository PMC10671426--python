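"""Ridge regression to fitness, Spearman evaluation, and ablation.

The supervised unit is one DMS dataset: a fused representation X (mutant
per row) and measured fitness y.  Ridge solves the centered normal
equations (Xc'Xc + aI) w = Xc'yc; a = 0 falls back to the minimum-norm
least-squares solution so plain linear regression is the a = 0 special
case.  Regularization strength is chosen by cross-validated Spearman rank
correlation — the headline metric throughout, because protein engineering
cares about the ranking of mutants more than their absolute scores.

Evaluation is leakage-free by construction: within each outer fold,
column scaling, the alpha search (an inner CV on the training rows only)
and the final fit all see training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import KFold, train_test_split

from .ensemble import ScalerStats, SequenceRepresentation, slice_blocks, standardize_matrix
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: 13-point log-spaced default regularization grid.
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.logspace(-3, 3, 13))


@dataclass(frozen=True)
class RidgeModel:
    """Fitted linear map from (optionally scaled) features to fitness."""

    weights: np.ndarray
    intercept: float
    alpha: float
    scaler_stats: ScalerStats | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_stats is not None:
            X, _ = standardize_matrix(X, self.scaler_stats)
        return X @ self.weights + self.intercept


def fit_ridge(X: np.ndarray, y: np.ndarray, alpha: float,
              scaler_stats: ScalerStats | None = None) -> RidgeModel:
    """Solve centered ridge; alpha = 0 uses the pseudo-inverse path.

    ``scaler_stats`` is carried on the model for prediction-time scaling
    only; X is assumed already scaled by the caller.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise DataError(f"incompatible shapes X{X.shape}, y{y.shape}")
    if X.shape[0] < 2:
        raise DataError(f"need at least 2 samples, got {X.shape[0]}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("non-finite entries in X or y")
    if alpha < 0:
        raise ConfigError(f"alpha must be >= 0, got {alpha}")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if alpha == 0.0:
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    else:
        D = X.shape[1]
        w = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(D), Xc.T @ yc)
    intercept = y_mean - float(x_mean @ w)
    return RidgeModel(weights=w, intercept=intercept, alpha=float(alpha),
                      scaler_stats=scaler_stats)


def spearman(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties).

    Returns ``nan`` (logged) when either vector is constant, where the
    correlation is undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise DataError(f"incompatible shapes {y_true.shape}, {y_pred.shape}")
    if y_true.size < 2:
        raise DataError("need at least 2 observations")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise DataError("non-finite values passed to spearman")
    if np.ptp(y_true) == 0.0 or np.ptp(y_pred) == 0.0:
        logger.warning("spearman undefined: constant input vector")
        return float("nan")
    rho = sps.spearmanr(y_true, y_pred).statistic
    return float(rho)


def _cv_splits(n: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def select_alpha(
    X: np.ndarray,
    y: np.ndarray,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick alpha maximizing mean validation Spearman on a seeded k-fold split.

    The same fold partition is reused across all candidates; ties go to the
    smallest alpha.  Folds whose validation part has fewer than 2 points or
    an undefined correlation are skipped with a warning.
    """
    if k_folds < 2:
        raise ConfigError(f"k_folds must be >= 2, got {k_folds}")
    grid = sorted(float(a) for a in alpha_grid)
    if not grid:
        raise ConfigError("alpha grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    splits = _cv_splits(X.shape[0], min(k_folds, X.shape[0]), seed)
    rows = []
    for a in grid:
        fold_rhos = []
        for tr, va in splits:
            if va.size < 2 or tr.size < 2:
                logger.warning("alpha selection: skipping fold with too few points")
                continue
            Ztr, stats_ = standardize_matrix(X[tr])
            Zva, _ = standardize_matrix(X[va], stats_)
            model = fit_ridge(Ztr, y[tr], a)
            rho = spearman(y[va], model.predict(Zva))
            if np.isnan(rho):
                # constant predictions carry no ranking information
                logger.warning("alpha selection: degenerate fold scored as rho=0")
                rho = 0.0
            fold_rhos.append(rho)
        if not fold_rhos:
            raise DataError("alpha selection: every fold was skipped")
        rows.append({"alpha": a, "mean_rho": float(np.mean(fold_rhos)),
                     "n_folds": len(fold_rhos)})
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_rho"].idxmax()]  # idxmax takes first max -> smallest alpha
    return float(best["alpha"]), table


@dataclass(frozen=True)
class EvaluationResult:
    """Cross-validated Spearman performance of one feature configuration."""

    fold_rhos: tuple[float, ...]
    fold_alphas: tuple[float, ...]
    fold_sizes: tuple[tuple[int, int], ...]  # (n_train, n_test) per fold
    seed: int
    protocol: str
    blocks: tuple[str, ...] = ()

    @property
    def mean_rho(self) -> float:
        return float(np.mean(self.fold_rhos))

    @property
    def sd_rho(self) -> float:
        return float(np.std(self.fold_rhos, ddof=1)) if len(self.fold_rhos) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "mean_rho": self.mean_rho,
            "sd_rho": self.sd_rho,
            "fold_rhos": list(self.fold_rhos),
            "fold_alphas": list(self.fold_alphas),
            "fold_sizes": [list(s) for s in self.fold_sizes],
            "seed": self.seed,
            "protocol": self.protocol,
            "blocks": list(self.blocks),
        }


def _as_matrix(representation) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(representation, SequenceRepresentation):
        return representation.matrix, tuple(representation.block_names)
    return np.asarray(representation, dtype=float), ()


def evaluate(
    representation,
    fitness: Sequence[float],
    protocol: str = "kfold",
    k: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    inner_folds: int = 5,
) -> EvaluationResult:
    """Held-out Spearman under k-fold CV (default) or a single holdout split.

    Per fold: scale on train, select alpha on train (inner CV), fit on
    train, score Spearman on the held-out rows.  All randomness derives
    from ``seed``.
    """
    X, block_names = _as_matrix(representation)
    y = np.asarray(list(fitness), dtype=float)
    if X.shape[0] != y.shape[0]:
        raise DataError(f"representation rows {X.shape[0]} != fitness length {y.shape[0]}")
    n = X.shape[0]
    if protocol == "kfold":
        if n < k:
            raise DataError(f"n={n} too small for {k}-fold CV")
        splits = _cv_splits(n, k, seed)
    elif protocol == "holdout":
        if not (0.0 < test_fraction < 1.0):
            raise ConfigError(f"test_fraction must be in (0, 1), got {test_fraction}")
        if n < 5:
            raise DataError(f"n={n} too small for a holdout split")
        tr, te = train_test_split(np.arange(n), test_size=test_fraction, random_state=seed)
        splits = [(np.sort(tr), np.sort(te))]
    else:
        raise ConfigError(f"unknown protocol {protocol!r}")
    fold_rhos, fold_alphas, fold_sizes = [], [], []
    for tr, te in splits:
        alpha_star, _ = select_alpha(X[tr], y[tr], alpha_grid, inner_folds, seed)
        Ztr, stats_ = standardize_matrix(X[tr])
        Zte, _ = standardize_matrix(X[te], stats_)
        model = fit_ridge(Ztr, y[tr], alpha_star)
        rho = spearman(y[te], model.predict(Zte))
        if np.isnan(rho):
            logger.warning("evaluation: degenerate fold scored as rho=0")
            rho = 0.0
        fold_rhos.append(rho)
        fold_alphas.append(alpha_star)
        fold_sizes.append((int(tr.size), int(te.size)))
    return EvaluationResult(
        fold_rhos=tuple(fold_rhos),
        fold_alphas=tuple(fold_alphas),
        fold_sizes=tuple(fold_sizes),
        seed=seed,
        protocol=protocol,
        blocks=block_names,
    )


def default_ablation_subsets(
    global_blocks: Sequence[str], local_block: str | None
) -> list[tuple[str, ...]]:
    """The six-scenario grid for two global blocks and one local block.

    {each global alone, both globals ensembled} x {with, without local}.
    """
    g = list(global_blocks)
    bases = [[b] for b in g]
    if len(g) > 1:
        bases.append(g)
    subsets = [tuple(b) for b in bases]
    if local_block is not None:
        subsets += [tuple(b + [local_block]) for b in bases]
    return subsets


def ablate(
    representation: SequenceRepresentation,
    fitness: Sequence[float],
    subsets: Sequence[Sequence[str]],
    protocol: str = "kfold",
    k: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], EvaluationResult]]:
    """Re-evaluate block subsets on identical folds; report paired deltas.

    The reference ("full") configuration is the subset containing every
    block of the representation; it is evaluated even if not requested.
    ``delta_vs_full`` is the mean of per-fold paired differences, which is
    only meaningful because every subset shares the seeded splits.
    """
    if not subsets:
        raise ConfigError("no ablation subsets given")
    all_blocks = tuple(representation.block_names)
    results: dict[tuple[str, ...], EvaluationResult] = {}
    wanted = [tuple(s) for s in subsets]
    for key in wanted + [all_blocks]:
        if key in results:
            continue
        sliced = slice_blocks(representation, list(key))
        results[key] = evaluate(
            sliced, fitness, protocol=protocol, k=k,
            test_fraction=test_fraction, seed=seed, alpha_grid=alpha_grid,
        )
    full = np.array(results[all_blocks].fold_rhos)
    rows = []
    for key in wanted:
        res = results[key]
        delta = float(np.mean(np.array(res.fold_rhos) - full))
        rows.append(
            {
                "subset": "+".join(key),
                "n_blocks": len(key),
                "mean_rho": res.mean_rho,
                "sd_rho": res.sd_rho,
                "delta_vs_full": delta,
            }
        )
    return pd.DataFrame(rows), results
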