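"""Fusion of per-mutant feature blocks into one sequence representation.

Each feature source (a global embedder, the coupling-derived local
features) yields an n x d block with one row per mutant.  Blocks are fused
either by column-wise concatenation (the default; block column spans are
recorded so ablation can slice blocks back out) or by ``project_sum``:
every block is mapped through a seeded random orthonormal-column
projection to a common dimension and the projections are summed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import ConfigError, DataError

STRATEGIES = ("concat", "project_sum")


@dataclass(frozen=True)
class FeatureBlock:
    """One named n x d feature matrix (mutant per row)."""

    name: str
    vectors: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        object.__setattr__(self, "vectors", v)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def width(self) -> int:
        return self.vectors.shape[1]


@dataclass
class SequenceRepresentation:
    """Fused n x D_total representation with block provenance."""

    matrix: np.ndarray
    block_spans: list[tuple[str, int, int]]
    strategy: str = "concat"
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def block_names(self) -> list[str]:
        return [name for name, _, _ in self.block_spans]


def _projection(width: int, projection_dim: int, seed: int, name: str) -> np.ndarray:
    """Seeded random matrix with orthonormal columns, stable per block name."""
    rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
    G = rng.standard_normal((width, projection_dim))
    Q, R = np.linalg.qr(G)
    # fix column signs so the projection is unique, not solver-dependent
    Q = Q * np.sign(np.diag(R))
    return Q


def build_representation(
    blocks: Sequence[FeatureBlock],
    strategy: str = "concat",
    projection_dim: int | None = None,
    seed: int | None = None,
) -> SequenceRepresentation:
    """Fuse blocks into one representation (see module docstring)."""
    if not blocks:
        raise ConfigError("at least one feature block is required")
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown fusion strategy {strategy!r}; choose from {STRATEGIES}")
    n = blocks[0].n
    bad = [(b.name, b.n) for b in blocks if b.n != n]
    if bad:
        raise DataError(f"blocks disagree on row count {n}: {bad}")
    if strategy == "concat":
        spans = []
        start = 0
        for b in blocks:
            spans.append((b.name, start, start + b.width))
            start += b.width
        matrix = np.concatenate([b.vectors for b in blocks], axis=1)
        return SequenceRepresentation(matrix=matrix, block_spans=spans, strategy="concat")
    # project_sum
    if projection_dim is None:
        raise ConfigError("project_sum requires projection_dim")
    min_width = min(b.width for b in blocks)
    if projection_dim > min_width:
        raise ConfigError(
            f"projection_dim {projection_dim} exceeds narrowest block width {min_width}"
        )
    if seed is None:
        seed = 0
    total = np.zeros((n, projection_dim))
    for b in blocks:
        total += b.vectors @ _projection(b.width, projection_dim, seed, b.name)
    spans = [(b.name, 0, projection_dim) for b in blocks]
    return SequenceRepresentation(
        matrix=total, block_spans=spans, strategy="project_sum", seed=seed
    )


def slice_blocks(
    rep: SequenceRepresentation, keep: Sequence[str]
) -> SequenceRepresentation:
    """Keep only the named blocks (concat representations only)."""
    if rep.strategy != "concat":
        raise ConfigError("block slicing requires a concat representation")
    if not keep:
        raise ConfigError("keep list is empty")
    spans = {name: (s, e) for name, s, e in rep.block_spans}
    unknown = [name for name in keep if name not in spans]
    if unknown:
        raise ConfigError(f"unknown block name(s) {unknown}; available: {list(spans)}")
    cols = []
    new_spans = []
    start = 0
    for name in keep:
        s, e = spans[name]
        cols.append(rep.matrix[:, s:e])
        new_spans.append((name, start, start + (e - s)))
        start += e - s
    return SequenceRepresentation(
        matrix=np.concatenate(cols, axis=1), block_spans=new_spans, strategy="concat"
    )


@dataclass(frozen=True)
class ScalerStats:
    """Per-column mean/sd estimated on training rows."""

    mean: np.ndarray
    sd: np.ndarray


def standardize(
    rep: SequenceRepresentation, stats: ScalerStats | None = None
) -> tuple[SequenceRepresentation, ScalerStats]:
    """Column z-score; constant (sd = 0) columns become all-zero.

    Passing training ``stats`` standardizes held-out rows with the training
    distribution, never their own.
    """
    X = rep.matrix
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        stats = ScalerStats(mean=mean, sd=sd)
    elif stats.mean.shape[0] != X.shape[1]:
        raise DataError(
            f"scaler width {stats.mean.shape[0]} != representation width {X.shape[1]}"
        )
    safe_sd = np.where(stats.sd == 0.0, 1.0, stats.sd)
    Z = (X - stats.mean) / safe_sd
    Z[:, stats.sd == 0.0] = 0.0
    out = SequenceRepresentation(
        matrix=Z, block_spans=list(rep.block_spans), strategy=rep.strategy, seed=rep.seed
    )
    return out, stats


def standardize_matrix(
    X: np.ndarray, stats: ScalerStats | None = None
) -> tuple[np.ndarray, ScalerStats]:
    """Matrix-level counterpart of :func:`standardize`."""
    if stats is None:
        stats = ScalerStats(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0))
    safe_sd = np.where(stats.sd == 0.0, 1.0, stats.sd)
    Z = (X - stats.mean) / safe_sd
    Z[:, stats.sd == 0.0] = 0.0
    return Z, stats


def save_representation(path: str | Path, rep: SequenceRepresentation) -> None:
    """Cache to HDF5 with a JSON sidecar for spans/strategy/seed."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("matrix", data=rep.matrix, track_times=False)
    sidecar = {
        "block_spans": [list(s) for s in rep.block_spans],
        "strategy": rep.strategy,
        "seed": rep.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_representation(path: str | Path) -> SequenceRepresentation:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as h5:
        matrix = np.asarray(h5["matrix"], dtype=float)
    return SequenceRepresentation(
        matrix=matrix,
        block_spans=[tuple(s) for s in sidecar["block_spans"]],
        strategy=sidecar["strategy"],
        seed=sidecar["seed"],
    )
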