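"""End-to-end featurization: dataset + feature sources -> fused representation.

Glue between the I/O layer and the supervised layer: pools per-residue
global embeddings into one vector per mutant, resolves coupling-based
local features per mutant, and fuses everything into a
:class:`~protfit.ensemble.SequenceRepresentation` (local block last).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .couplings import (
    CouplingModel,
    read_ccmpred_matrix,
    read_ccmpred_raw,
    resolve_local_features,
    resolve_pairwise_features,
)
from .datamodel import DMSDataset, read_dms_table, read_fasta
from .embedders import Embedder, pool_global
from .ensemble import FeatureBlock, SequenceRepresentation, build_representation
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

LOCAL_BLOCK = "local"


def global_block(
    dataset: DMSDataset,
    embedder: Embedder,
    pooling: str = "mean",
    max_order: int | None = None,
) -> FeatureBlock:
    """Embed and pool every mutant sequence into one n x d block."""
    rows = []
    for rec in dataset.mutants:
        emb = embedder.embed(rec.sequence, rec.id)
        rows.append(
            pool_global(emb, strategy=pooling, mutations=rec.mutations, max_order=max_order)
        )
    return FeatureBlock(
        name=embedder.name, vectors=np.array(rows), provenance=f"embedder:{embedder.name}"
    )


def local_block(
    dataset: DMSDataset,
    coupling_model: CouplingModel,
    mode: str = "sum",
    msa_offset: int = 0,
) -> FeatureBlock:
    """Coupling-resolved local features for every mutant.

    When the coupling model covers only a sub-domain (``msa_offset`` > 0 or
    model length < wild-type length), features are resolved on the covered
    span; mutants whose substitutions all fall outside the span get a zero
    row (logged).
    """
    L_wt = len(dataset.wild_type)
    span = (msa_offset, msa_offset + coupling_model.L)
    if span[1] > L_wt:
        raise DataError(
            f"coupling model (L={coupling_model.L}, offset={msa_offset}) "
            f"extends beyond wild type length {L_wt}"
        )
    if mode not in {"sum", "pairwise"}:
        raise ConfigError(f"unknown local feature mode {mode!r}")
    resolver = resolve_local_features if mode == "sum" else resolve_pairwise_features
    rows = []
    n_outside = 0
    width = coupling_model.L if mode == "sum" else coupling_model.L**2
    for rec in dataset.mutants:
        in_span = [m for m in rec.mutations if span[0] < m.position <= span[1]]
        if rec.mutations and not in_span:
            n_outside += 1
            rows.append(np.zeros(width))
            continue
        sub = rec.sequence[span[0] : span[1]]
        feat = resolver(coupling_model, sub)
        rows.append(feat.values if mode == "sum" else feat)
    if n_outside:
        logger.warning(
            "%d mutant(s) fall entirely outside the coupling model span %s; "
            "their local features are zero",
            n_outside,
            span,
        )
    return FeatureBlock(
        name=LOCAL_BLOCK,
        vectors=np.array(rows),
        provenance=f"couplings:{coupling_model.source}",
    )


def featurize(
    dataset: DMSDataset,
    embedders: Sequence[Embedder],
    coupling_model: CouplingModel | None = None,
    pooling: str = "mean",
    local_mode: str = "sum",
    msa_offset: int = 0,
    strategy: str = "concat",
    projection_dim: int | None = None,
    seed: int | None = None,
    max_order: int | None = None,
) -> tuple[list[FeatureBlock], SequenceRepresentation]:
    """Build all feature blocks and fuse them (local block appended last)."""
    if not embedders and coupling_model is None:
        raise ConfigError("no feature sources: need embedders and/or a coupling model")
    if max_order is None and pooling == "mutated-positions":
        max_order = max((rec.order for rec in dataset.mutants), default=1)
    blocks = [global_block(dataset, emb, pooling, max_order) for emb in embedders]
    if coupling_model is not None:
        blocks.append(local_block(dataset, coupling_model, local_mode, msa_offset))
    rep = build_representation(blocks, strategy=strategy, projection_dim=projection_dim, seed=seed)
    return blocks, rep


def load_coupling_file(path: str | Path) -> CouplingModel:
    """Dispatch on dialect: ``.raw`` -> pair potentials, else summary matrix."""
    path = Path(path)
    if path.suffix.lower() == ".raw":
        return read_ccmpred_raw(path)
    return read_ccmpred_matrix(path)


def load_study(bundle_dir: str | Path):
    """Load a synthetic (or identically laid-out) study bundle.

    Returns ``(dataset, embedders, coupling_model)`` where embedders are
    :class:`~protfit.embedders.PrecomputedEmbedder` over the bundle's HDF5
    stores.
    """
    from .embedders import EmbedderSpec, PrecomputedEmbedder

    bundle_dir = Path(bundle_dir)
    fasta = read_fasta(bundle_dir / "wild_type.fasta")
    name, wild_type = fasta[0]
    dataset = read_dms_table(bundle_dir / "dms.csv", wild_type=wild_type, name=name)
    raw = bundle_dir / "couplings.raw"
    coupling = load_coupling_file(raw if raw.exists() else bundle_dir / "couplings.mat")
    embedders = []
    ids = [m.id for m in dataset.mutants]
    lengths = {m.id: len(m.sequence) for m in dataset.mutants}
    for store in sorted(bundle_dir.glob("embeddings_*.h5")):
        import h5py

        with h5py.File(store, "r") as h5:
            grp = h5["embeddings"]
            emb_name = grp.attrs.get("embedder_name", store.stem.removeprefix("embeddings_"))
            first = next(iter(grp.values()))
            dim = first.shape[1]
        spec = EmbedderSpec(name=str(emb_name), kind="precomputed", dim=int(dim),
                            source_path=str(store))
        embedders.append(PrecomputedEmbedder.from_store(spec, ids, lengths))
    return dataset, embedders, coupling
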