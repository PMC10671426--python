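"""Per-residue "global feature" matrices under a uniform embedder contract.

A global embedding of a length-L protein is an L x D matrix: one feature
row per residue.  Pre-trained protein language models (run elsewhere,
typically on GPU hosts) produce such matrices; this module provides

* two deterministic reference embedders computed internally (one-hot and
  a 5-dimensional physico-chemical property encoding), and
* a loader/writer for externally precomputed embedding stores (HDF5 or
  long-form TSV), keyed by sequence id.

Pooling reduces L x D to a fixed-length vector per sequence so ridge
regression can consume it; the default is the positional mean.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .datamodel import AA20, Mutation
from .errors import ConfigError, DataError, ValidationError

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

POOL_STRATEGIES = ("mean", "flatten", "mutated-positions")


@dataclass(frozen=True)
class GlobalEmbedding:
    """L x D per-residue feature matrix for one sequence."""

    embedder_name: str
    matrix: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValidationError(f"embedding matrix must be 2-D, got shape {m.shape}")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class EmbedderSpec:
    """Declared identity of one global-feature source."""

    name: str
    kind: str  # onehot | physchem | precomputed
    dim: int
    source_path: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"onehot", "physchem", "precomputed"}:
            raise ConfigError(f"unknown embedder kind {self.kind!r}")
        if self.dim < 1:
            raise ConfigError(f"embedder dimension must be >= 1, got {self.dim}")
        if self.kind == "precomputed" and not self.source_path:
            raise ConfigError(f"precomputed embedder {self.name!r} needs a source_path")


class Embedder:
    """Contract: deterministic ``embed(sequence) -> GlobalEmbedding``."""

    name: str
    dim: int

    def embed(self, sequence: str, sequence_id: str = "") -> GlobalEmbedding:
        raise NotImplementedError

    @property
    def spec(self) -> EmbedderSpec:
        kind = getattr(self, "kind", "precomputed")
        return EmbedderSpec(name=self.name, kind=kind, dim=self.dim,
                            source_path=getattr(self, "source_path", None))


class OneHotEmbedder(Embedder):
    """Indicator encoding over the 20 canonical residues (D = 20).

    Non-canonical residues get an all-zero row.
    """

    kind = "onehot"

    def __init__(self, name: str = "onehot"):
        self.name = name
        self.dim = len(AA20)

    def embed(self, sequence: str, sequence_id: str = "") -> GlobalEmbedding:
        m = np.zeros((len(sequence), self.dim))
        for i, c in enumerate(sequence.upper()):
            j = _AA_INDEX.get(c)
            if j is not None:
                m[i, j] = 1.0
        return GlobalEmbedding(self.name, m, sequence_id)


def _load_property_table() -> pd.DataFrame:
    with importlib.resources.files("protfit.data").joinpath("aa_properties.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("aa")


class PhyschemEmbedder(Embedder):
    """Five physico-chemical properties per residue (D = 5).

    Columns: Kyte-Doolittle hydropathy, side-chain volume (A^3), net charge
    at pH 7, Grantham polarity, isoelectric point.  Unknown residues map to
    the column means (logged).
    """

    kind = "physchem"

    def __init__(self, name: str = "physchem"):
        self.name = name
        self._table = _load_property_table()
        self._rows = {aa: self._table.loc[aa].to_numpy(dtype=float) for aa in self._table.index}
        self._mean = self._table.mean(axis=0).to_numpy(dtype=float)
        self.dim = self._table.shape[1]

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    def embed(self, sequence: str, sequence_id: str = "") -> GlobalEmbedding:
        rows = []
        n_unknown = 0
        for c in sequence.upper():
            row = self._rows.get(c)
            if row is None:
                n_unknown += 1
                row = self._mean
            rows.append(row)
        if n_unknown:
            logger.warning(
                "physchem embedder: %d unknown residue(s) mapped to property means",
                n_unknown,
            )
        return GlobalEmbedding(self.name, np.array(rows), sequence_id)


def write_embedding_store(
    path: str | Path,
    embeddings: Iterable[GlobalEmbedding],
    embedder_name: str,
) -> None:
    """Write an HDF5 store: group ``embeddings``, one float32 dataset per id."""
    with h5py.File(path, "w", track_order=True) as h5:
        grp = h5.create_group("embeddings", track_order=True)
        grp.attrs["embedder_name"] = embedder_name
        for emb in embeddings:
            grp.create_dataset(
                emb.sequence_id,
                data=emb.matrix.astype(np.float32),
                track_times=False,
            )


def write_embedding_tsv(
    path: str | Path,
    embeddings: Iterable[GlobalEmbedding],
) -> None:
    """Long-form TSV alternative: sequence_id, position (0-based), dim, value."""
    frames = []
    for emb in embeddings:
        L, D = emb.matrix.shape
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": np.repeat(emb.sequence_id, L * D),
                    "position": np.repeat(np.arange(L), D),
                    "dim": np.tile(np.arange(D), L),
                    "value": emb.matrix.reshape(-1),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def load_precomputed(
    spec: EmbedderSpec,
    sequence_ids: Sequence[str],
    lengths: Mapping[str, int] | None = None,
) -> dict[str, GlobalEmbedding]:
    """Load precomputed embeddings for the requested ids.

    Shapes are validated against ``lengths`` (id -> sequence length) when
    given; missing ids and shape mismatches raise a data error listing the
    offenders.
    """
    if spec.kind != "precomputed":
        raise ConfigError(f"embedder {spec.name!r} is not a precomputed store")
    path = Path(spec.source_path)
    if not path.exists():
        raise DataError(f"embedding store {path} does not exist")
    if path.suffix.lower() in {".h5", ".hdf5"}:
        out = _load_h5(path, spec, sequence_ids)
    else:
        out = _load_tsv(path, spec, sequence_ids)
    if lengths:
        bad = [
            (sid, out[sid].length, lengths[sid])
            for sid in sequence_ids
            if sid in lengths and out[sid].length != lengths[sid]
        ]
        if bad:
            raise DataError(
                f"embedding store {path}: length mismatches (id, stored, expected): {bad[:5]}"
            )
    wrong_d = [sid for sid in sequence_ids if out[sid].dim != spec.dim]
    if wrong_d:
        raise DataError(
            f"embedding store {path}: dimension != declared {spec.dim} for ids {wrong_d[:5]}"
        )
    return out


def _load_h5(path: Path, spec: EmbedderSpec, sequence_ids: Sequence[str]) -> dict[str, GlobalEmbedding]:
    out: dict[str, GlobalEmbedding] = {}
    with h5py.File(path, "r") as h5:
        if "embeddings" not in h5:
            raise DataError(f"{path}: no 'embeddings' group")
        grp = h5["embeddings"]
        missing = [sid for sid in sequence_ids if sid not in grp]
        if missing:
            raise DataError(f"{path}: missing sequence id(s) {missing[:5]}")
        for sid in sequence_ids:
            out[sid] = GlobalEmbedding(spec.name, np.asarray(grp[sid], dtype=float), sid)
    return out


def _load_tsv(path: Path, spec: EmbedderSpec, sequence_ids: Sequence[str]) -> dict[str, GlobalEmbedding]:
    df = pd.read_csv(path, sep="\t")
    required = {"sequence_id", "position", "dim", "value"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: TSV store needs columns {sorted(required)}")
    out: dict[str, GlobalEmbedding] = {}
    grouped = dict(tuple(df.groupby("sequence_id", sort=False)))
    missing = [sid for sid in sequence_ids if sid not in grouped]
    if missing:
        raise DataError(f"{path}: missing sequence id(s) {missing[:5]}")
    for sid in sequence_ids:
        g = grouped[sid]
        L = int(g["position"].max()) + 1
        D = int(g["dim"].max()) + 1
        m = np.zeros((L, D))
        m[g["position"].to_numpy(), g["dim"].to_numpy()] = g["value"].to_numpy()
        out[sid] = GlobalEmbedding(spec.name, m, sid)
    return out


class PrecomputedEmbedder(Embedder):
    """Embedder backed by a store of externally computed matrices.

    Lookup is by sequence id (language-model output cannot be recomputed
    from the sequence here), so ``embed`` requires ``sequence_id`` and
    validates the stored row count against the sequence length.
    """

    kind = "precomputed"

    def __init__(self, spec: EmbedderSpec, store: Mapping[str, GlobalEmbedding]):
        self.name = spec.name
        self.dim = spec.dim
        self.source_path = spec.source_path
        self._store = dict(store)

    @classmethod
    def from_store(
        cls,
        spec: EmbedderSpec,
        sequence_ids: Sequence[str],
        lengths: Mapping[str, int] | None = None,
    ) -> "PrecomputedEmbedder":
        return cls(spec, load_precomputed(spec, sequence_ids, lengths))

    def embed(self, sequence: str, sequence_id: str = "") -> GlobalEmbedding:
        if sequence_id not in self._store:
            raise DataError(f"embedder {self.name!r}: no stored embedding for id {sequence_id!r}")
        emb = self._store[sequence_id]
        if emb.length != len(sequence):
            raise DataError(
                f"embedder {self.name!r}: stored length {emb.length} != sequence "
                f"length {len(sequence)} for id {sequence_id!r}"
            )
        return emb


def pool_global(
    embedding: GlobalEmbedding,
    strategy: str = "mean",
    mutations: Sequence[Mutation] | None = None,
    max_order: int | None = None,
) -> np.ndarray:
    """Reduce an L x D embedding to a fixed-length vector.

    mean
        Column means (length D); robust to differing sequence lengths.
    flatten
        Row-major flattening (length L*D); requires a shared L per dataset.
    mutated-positions
        Concatenation of the rows at mutated sites (sorted by position),
        zero-padded to ``max_order`` slots (length max_order*D).
    """
    m = embedding.matrix
    if strategy == "mean":
        return m.mean(axis=0)
    if strategy == "flatten":
        return m.reshape(-1)
    if strategy == "mutated-positions":
        if mutations is None or max_order is None:
            raise ConfigError("mutated-positions pooling needs mutations and max_order")
        if len(mutations) > max_order:
            raise ConfigError(
                f"mutant has {len(mutations)} substitutions > max_order {max_order}"
            )
        D = m.shape[1]
        out = np.zeros(max_order * D)
        for k, mu in enumerate(sorted(mutations, key=lambda x: x.position)):
            out[k * D : (k + 1) * D] = m[mu.position - 1]
        return out
    raise ConfigError(f"unknown pooling strategy {strategy!r}; choose from {POOL_STRATEGIES}")
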