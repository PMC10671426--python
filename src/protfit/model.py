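"""Model/Results front-end for supervised mutation-effect prediction.

:class:`MutationEffectModel` bundles one DMS dataset's fused feature
representation with its fitness vector; ``fit()`` cross-validates the
ridge regularization, refits on all rows, and returns a
:class:`MutationEffectResults` carrying coefficients, per-fold held-out
Spearman correlations and a ``summary()`` table.  Ablation over feature
blocks hangs off the model so every subset shares the seeded folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DMSDataset
from .ensemble import SequenceRepresentation, slice_blocks, standardize_matrix
from .errors import ConfigError, DataError
from .supervised import (
    DEFAULT_ALPHA_GRID,
    EvaluationResult,
    RidgeModel,
    ablate,
    default_ablation_subsets,
    evaluate,
    fit_ridge,
    select_alpha,
    spearman,
)


class MutationEffectModel:
    """Ridge model from a fused sequence representation to DMS fitness.

    Parameters
    ----------
    representation
        Fused n x D representation (mutant per row).
    fitness
        Length-n measured scores, aligned with the representation rows.
    dataset
        Optional provenance; row order must match ``dataset.mutants``.
    """

    def __init__(
        self,
        representation: SequenceRepresentation,
        fitness: Sequence[float],
        dataset: DMSDataset | None = None,
    ):
        y = np.asarray(list(fitness), dtype=float)
        if representation.n != y.shape[0]:
            raise DataError(
                f"representation rows {representation.n} != fitness length {y.shape[0]}"
            )
        if dataset is not None and len(dataset) != y.shape[0]:
            raise DataError("dataset mutant count does not match fitness length")
        self.representation = representation
        self.fitness = y
        self.dataset = dataset

    @classmethod
    def from_dataset(
        cls,
        dataset: DMSDataset,
        embedders,
        coupling_model=None,
        **featurize_kwargs,
    ) -> "MutationEffectModel":
        """Featurize a dataset (see :func:`protfit.pipeline.featurize`)."""
        from .pipeline import featurize

        _, rep = featurize(dataset, embedders, coupling_model, **featurize_kwargs)
        return cls(rep, dataset.fitness, dataset)

    @classmethod
    def from_study(cls, bundle_dir, **featurize_kwargs) -> "MutationEffectModel":
        """Build straight from an on-disk study bundle."""
        from .pipeline import load_study

        dataset, embedders, coupling = load_study(bundle_dir)
        return cls.from_dataset(dataset, embedders, coupling, **featurize_kwargs)

    @property
    def nobs(self) -> int:
        return self.representation.n

    @property
    def block_names(self) -> list[str]:
        return self.representation.block_names

    def fit(
        self,
        alpha: float | None = None,
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
        protocol: str = "kfold",
        k: int = 5,
        test_fraction: float = 0.2,
        seed: int = 0,
    ) -> "MutationEffectResults":
        """Cross-validate, then refit on all rows.

        With ``alpha=None`` the regularization is selected by inner CV;
        held-out performance comes from :func:`protfit.supervised.evaluate`
        under the same seed.
        """
        grid = [alpha] if alpha is not None else list(alpha_grid)
        evaluation = evaluate(
            self.representation,
            self.fitness,
            protocol=protocol,
            k=k,
            test_fraction=test_fraction,
            seed=seed,
            alpha_grid=grid,
        )
        if alpha is None:
            alpha_final, alpha_table = select_alpha(
                self.representation.matrix, self.fitness, grid, k_folds=k, seed=seed
            )
        else:
            alpha_final, alpha_table = float(alpha), None
        Z, stats = standardize_matrix(self.representation.matrix)
        ridge = fit_ridge(Z, self.fitness, alpha_final, scaler_stats=stats)
        return MutationEffectResults(
            model=self, ridge=ridge, evaluation=evaluation, alpha_table=alpha_table
        )

    def ablate(
        self,
        subsets: Sequence[Sequence[str]] | None = None,
        protocol: str = "kfold",
        k: int = 5,
        test_fraction: float = 0.2,
        seed: int = 0,
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    ) -> tuple[pd.DataFrame, dict]:
        """Block-subset ablation on shared seeded folds.

        With ``subsets=None`` the default six-scenario grid is used:
        {each global alone, both globals} x {with, without local}.
        """
        if subsets is None:
            names = self.block_names
            local = "local" if "local" in names else None
            globals_ = [n for n in names if n != "local"]
            subsets = default_ablation_subsets(globals_, local)
        return ablate(
            self.representation,
            self.fitness,
            subsets,
            protocol=protocol,
            k=k,
            test_fraction=test_fraction,
            seed=seed,
            alpha_grid=alpha_grid,
        )


@dataclass
class MutationEffectResults:
    """Fit artifacts: coefficients, CV performance, diagnostics."""

    model: MutationEffectModel
    ridge: RidgeModel
    evaluation: EvaluationResult
    alpha_table: pd.DataFrame | None = None

    @property
    def params(self) -> np.ndarray:
        return self.ridge.weights

    @property
    def intercept(self) -> float:
        return self.ridge.intercept

    @property
    def alpha(self) -> float:
        return self.ridge.alpha

    @property
    def mean_rho(self) -> float:
        return self.evaluation.mean_rho

    @property
    def sd_rho(self) -> float:
        return self.evaluation.sd_rho

    def predict(self, X=None) -> np.ndarray:
        """Predict fitness; defaults to in-sample rows."""
        if X is None:
            X = self.model.representation.matrix
        elif isinstance(X, SequenceRepresentation):
            X = X.matrix
        return self.ridge.predict(np.asarray(X, dtype=float))

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.fitness - self.fittedvalues

    def block_weight_norms(self) -> pd.DataFrame:
        """L2 norm of the fitted weights within each block span."""
        rows = []
        for name, s, e in self.model.representation.block_spans:
            rows.append({"block": name, "width": e - s,
                         "weight_l2": float(np.linalg.norm(self.ridge.weights[s:e]))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        ev = self.evaluation
        lines = []
        title = "Mutation Effect Ridge Regression Results"
        lines.append(title)
        lines.append("=" * 58)
        ds = self.model.dataset
        rows = [
            ("Dataset:", ds.name if ds is not None else "<arrays>"),
            ("No. observations:", str(self.model.nobs)),
            ("Representation width:", str(self.model.representation.width)),
            ("Feature blocks:", ", ".join(self.model.block_names) or "<unnamed>"),
            ("Fusion strategy:", self.model.representation.strategy),
            ("Alpha (refit):", f"{self.alpha:g}"),
            ("CV protocol:", f"{ev.protocol} (seed {ev.seed})"),
            ("Spearman rho (CV mean):", f"{ev.mean_rho:.4f}"),
            ("Spearman rho (CV sd):", f"{ev.sd_rho:.4f}"),
            ("In-sample Spearman rho:",
             f"{spearman(self.model.fitness, self.fittedvalues):.4f}"),
        ]
        for label, value in rows:
            lines.append(f"{label:<28}{value}")
        lines.append("-" * 58)
        lines.append("Per-fold held-out Spearman rho:")
        for i, (rho, a, (ntr, nte)) in enumerate(
            zip(ev.fold_rhos, ev.fold_alphas, ev.fold_sizes)
        ):
            lines.append(
                f"  fold {i}: rho={rho:+.4f}  alpha={a:g}  n_train={ntr}  n_test={nte}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MutationEffectResults: n={self.model.nobs}, "
            f"D={self.model.representation.width}, mean CV rho={self.mean_rho:.3f}>"
        )
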