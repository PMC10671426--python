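"""Statistically controlled synthetic DMS studies.

Real studies of this kind need deep mutational scanning tables, homolog
MSAs run through CCMPred, and per-residue embeddings from large protein
language models — none of which can be regenerated on a laptop.  This
module emulates every input with known ground truth instead: a random
wild type, unique substitution mutants, a sparse Markov-random-field
coupling model, block-structured per-residue embeddings with a declared
informative subspace, and fitness generated as a noisy weighted sum of
chosen feature blocks plus a coupling-resolved epistatic term.

Default dimensions follow the envelope of published substitution DMS
collections (sequence lengths 86-881 aa, 298-6370 mutants per dataset),
scaled to the low end so a full study runs in seconds: L=120 residues,
500 mutants of order <= 2, two 32-dimensional global blocks, 5% coupling
sparsity, noise at 0.3 of the signal sd, with the signal split
35/35/30 across the two global blocks and the coupling term.

Everything is deterministic from the config seed; ``gen_study`` writes a
bundle (FASTA, DMS CSV, CCMPred-dialect files, HDF5 embedding stores,
ground-truth JSON, checksummed manifest) that round-trips through every
reader in the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .couplings import (
    CCMPRED_ALPHABET,
    CouplingModel,
    resolve_local_features,
    write_ccmpred_matrix,
    write_ccmpred_raw,
)
from .datamodel import (
    AA20,
    DMSDataset,
    Mutation,
    MutantRecord,
    write_dms_table,
    write_fasta,
)
from .embedders import Embedder, GlobalEmbedding
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Envelope of the emulated substitution-benchmark subset.
LENGTH_RANGE = (86, 881)
N_MUTANTS_RANGE = (298, 6370)


@dataclass(frozen=True)
class BlockSpec:
    """One synthetic global-feature block."""

    name: str
    dim: int
    informative_fraction: float

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ConfigError(f"block {self.name!r}: dim must be >= 1")
        if not (0.0 <= self.informative_fraction <= 1.0):
            raise ConfigError(f"block {self.name!r}: informative_fraction outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``signal_split`` assigns generative weight to each block name and to
    ``"local"`` (the coupling-resolved term); weights must sum to 1.
    ``noise_sd`` is relative to the sd of the noiseless signal, so
    correlation expectations are scale-free.
    """

    L: int = 120
    n_mutants: int = 500
    max_order: int = 2
    block_specs: tuple[BlockSpec, ...] = (
        BlockSpec("plm_a", 32, 0.5),
        BlockSpec("plm_b", 32, 0.5),
    )
    coupling_sparsity: float = 0.05
    signal_split: Mapping[str, float] = field(
        default_factory=lambda: {"plm_a": 0.35, "plm_b": 0.35, "local": 0.30}
    )
    noise_sd: float = 0.3
    seed: int = 0
    enforce_envelope: bool = True

    def __post_init__(self) -> None:
        if self.enforce_envelope:
            if not (LENGTH_RANGE[0] <= self.L <= LENGTH_RANGE[1]):
                raise ConfigError(
                    f"L={self.L} outside the emulated envelope {LENGTH_RANGE}"
                )
            if not (N_MUTANTS_RANGE[0] <= self.n_mutants <= N_MUTANTS_RANGE[1]):
                raise ConfigError(
                    f"n_mutants={self.n_mutants} outside the emulated envelope "
                    f"{N_MUTANTS_RANGE}"
                )
        if self.max_order < 1:
            raise ConfigError("max_order must be >= 1")
        if not (0.0 <= self.coupling_sparsity <= 1.0):
            raise ConfigError("coupling_sparsity outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        total = float(sum(self.signal_split.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"signal_split weights sum to {total}, expected 1")
        names = {b.name for b in self.block_specs}
        unknown = set(self.signal_split) - names - {"local"}
        if unknown:
            raise ConfigError(f"signal_split names unknown blocks: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_specs"] = [dataclasses.asdict(b) for b in self.block_specs]
        d["signal_split"] = dict(self.signal_split)
        return d


def gen_wild_type(L: int, seed: int) -> str:
    """Uniform random wild type over the 20 canonical residues."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA20), size=L))


def gen_mutants(
    wild_type: str, n: int, max_order: int, seed: int
) -> list[list[Mutation]]:
    """Draw ``n`` unique mutants; order uniform on 1..max_order.

    Positions within a mutant are sampled without replacement; substituted
    residues are uniform over the 19 non-wild-type letters.
    """
    L = len(wild_type)
    if max_order > L:
        raise ConfigError(f"max_order {max_order} exceeds sequence length {L}")
    if max_order == 1 and n > 19 * L:
        raise DataError(
            f"cannot draw {n} unique single mutants from {19 * L} possibilities"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple] = set()
    out: list[list[Mutation]] = []
    attempts = 0
    max_attempts = max(100 * n, 10_000)
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise DataError(
                f"exhausted mutant space: drew {len(out)}/{n} unique mutants "
                f"after {attempts} attempts"
            )
        order = int(rng.integers(1, max_order + 1))
        positions = np.sort(rng.choice(L, size=order, replace=False)) + 1
        muts = []
        for pos in positions:
            wt = wild_type[pos - 1]
            alt = rng.choice([aa for aa in AA20 if aa != wt])
            muts.append(Mutation(wt, int(pos), str(alt)))
        key = tuple((m.position, m.alt_aa) for m in muts)
        if key in seen:
            continue
        seen.add(key)
        out.append(muts)
    return out


def gen_coupling_model(L: int, sparsity: float, seed: int) -> CouplingModel:
    """Sparse symmetric pair potentials with standard-normal entries.

    Each of the L(L-1)/2 position pairs is active with probability
    ``sparsity``; active pairs get a dense 21 x 21 Gaussian block (gap
    state included), mirrored so e_ij(a,b) = e_ji(b,a).
    """
    rng = np.random.default_rng(seed)
    A = len(CCMPRED_ALPHABET)
    e = np.zeros((L, L, A, A))
    for i in range(L):
        for j in range(i + 1, L):
            if rng.random() < sparsity:
                block = rng.standard_normal((A, A))
                e[i, j] = block
                e[j, i] = block.T
    return CouplingModel(L=L, pair_potentials=e, source=f"synthetic(seed={seed})")


class SyntheticBlockEmbedder(Embedder):
    """Deterministic per-(position, residue) embedding with tunable signal.

    A declared fraction of the D dimensions is *informative*: the value
    depends on both position and residue identity (a frozen Gaussian
    lookup table), so substitutions move the pooled vector.  The remaining
    dimensions depend on position only and carry no mutant information.
    Stands in for a protein language model with controllable information
    content.
    """

    kind = "precomputed"

    def __init__(self, name: str, L: int, dim: int, informative_fraction: float, seed: int):
        self.name = name
        self.L = L
        self.dim = dim
        self.seed = seed
        self.n_informative = int(round(dim * informative_fraction))
        rng = np.random.default_rng(seed)
        # frozen lookup tables; embed() only indexes into them
        self._info = rng.standard_normal((L, len(AA20), self.n_informative))
        self._noise = rng.standard_normal((L, dim - self.n_informative))
        self._aa_index = {aa: i for i, aa in enumerate(AA20)}

    @classmethod
    def from_spec(cls, spec: BlockSpec, L: int, seed: int) -> "SyntheticBlockEmbedder":
        return cls(spec.name, L, spec.dim, spec.informative_fraction, seed)

    def embed(self, sequence: str, sequence_id: str = "") -> GlobalEmbedding:
        if len(sequence) != self.L:
            raise DataError(
                f"synthetic embedder {self.name!r} built for L={self.L}, "
                f"got sequence of length {len(sequence)}"
            )
        m = np.zeros((self.L, self.dim))
        if self.n_informative:
            for i, c in enumerate(sequence.upper()):
                j = self._aa_index.get(c)
                if j is not None:
                    m[i, : self.n_informative] = self._info[i, j]
        m[:, self.n_informative :] = self._noise
        return GlobalEmbedding(self.name, m, sequence_id)


def gen_block_embedder(
    name: str, L: int, dim: int, informative_fraction: float, seed: int
) -> SyntheticBlockEmbedder:
    return SyntheticBlockEmbedder(name, L, dim, informative_fraction, seed)


@dataclass
class GroundTruth:
    """Generative parameters stored alongside every synthetic dataset."""

    block_weights: dict[str, list[float]]
    signal_split: dict[str, float]
    noiseless_fitness: list[float]
    noise_sd: float
    coupling_source: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def gen_fitness(
    sequences: Sequence[str],
    pooled_blocks: Mapping[str, np.ndarray],
    coupling_model: CouplingModel | None,
    signal_split: Mapping[str, float],
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, GroundTruth]:
    """Fitness as a noisy weighted sum of block signals plus the local term.

    Each block contributes the z-scored linear score X_b w_b (w_b drawn
    standard normal, frozen in the ground truth); the ``"local"`` weight
    applies to the z-scored total coupling sum of each mutant sequence.
    Noise is N(0, noise_sd * sd(signal)).
    """
    n = len(sequences)
    rng = np.random.default_rng(seed)
    block_weights: dict[str, list[float]] = {}
    components: dict[str, np.ndarray] = {}
    for name, X in pooled_blocks.items():
        w = rng.standard_normal(X.shape[1])
        block_weights[name] = [float(v) for v in w]
        components[name] = _zscore(X @ w)
    if "local" in signal_split and signal_split["local"] > 0:
        if coupling_model is None:
            raise ConfigError("signal_split assigns weight to 'local' but no coupling model given")
        sums = np.array(
            [resolve_local_features(coupling_model, s).values.sum() for s in sequences]
        )
        components["local"] = _zscore(sums)
    signal = np.zeros(n)
    for name, weight in signal_split.items():
        if weight == 0:
            continue
        if name not in components:
            raise ConfigError(f"signal_split names unknown component {name!r}")
        signal += weight * components[name]
    sd_signal = signal.std()
    noise = rng.normal(0.0, noise_sd * sd_signal, size=n) if sd_signal > 0 else np.zeros(n)
    y = signal + noise
    truth = GroundTruth(
        block_weights=block_weights,
        signal_split={k: float(v) for k, v in signal_split.items()},
        noiseless_fitness=[float(v) for v in signal],
        noise_sd=float(noise_sd),
        coupling_source=coupling_model.source if coupling_model is not None else "",
        seed=int(seed),
    )
    return y, truth


@dataclass
class SyntheticStudy:
    """In-memory synthetic study: dataset plus every feature source."""

    config: GeneratorConfig
    dataset: DMSDataset
    embedders: list[SyntheticBlockEmbedder]
    coupling_model: CouplingModel
    truth: GroundTruth


def gen_dataset(config: GeneratorConfig) -> SyntheticStudy:
    """Generate a complete in-memory study from the config seed.

    Child seeds are fixed offsets of the config seed so each stage is
    independently reproducible.
    """
    s = config.seed
    wt = gen_wild_type(config.L, seed=s)
    mutant_lists = gen_mutants(wt, config.n_mutants, config.max_order, seed=s + 1)
    coupling = gen_coupling_model(config.L, config.coupling_sparsity, seed=s + 2)
    embedders = [
        SyntheticBlockEmbedder.from_spec(spec, config.L, seed=s + 10 + k)
        for k, spec in enumerate(config.block_specs)
    ]
    records = [
        MutantRecord.from_mutations(wt, muts, fitness=0.0) for muts in mutant_lists
    ]
    sequences = [r.sequence for r in records]
    pooled = {
        emb.name: np.array([emb.embed(seq).matrix.mean(axis=0) for seq in sequences])
        for emb in embedders
    }
    y, truth = gen_fitness(
        sequences, pooled, coupling, config.signal_split, config.noise_sd, seed=s + 3
    )
    records = [
        MutantRecord(mutations=r.mutations, sequence=r.sequence,
                     fitness=float(y[i]), id=r.id)
        for i, r in enumerate(records)
    ]
    dataset = DMSDataset(
        name=f"synthetic_L{config.L}_n{config.n_mutants}_seed{s}",
        wild_type=wt,
        mutants=records,
        taxon="synthetic",
    )
    return SyntheticStudy(
        config=config, dataset=dataset, embedders=embedders,
        coupling_model=coupling, truth=truth,
    )


def _gen_msa(wt: str, depth: int, seed: int) -> list[tuple[str, str]]:
    """Toy homolog alignment: the query plus point-mutated copies (no indels)."""
    rng = np.random.default_rng(seed)
    rows = [("query", wt)]
    L = len(wt)
    for k in range(depth):
        seq = list(wt)
        n_sub = max(1, int(0.1 * L))
        for pos in rng.choice(L, size=n_sub, replace=False):
            seq[pos] = str(rng.choice(list(AA20)))
        rows.append((f"homolog_{k}", "".join(seq)))
    return rows


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def gen_study(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write a complete on-disk bundle consumable by the CLI end-to-end.

    Files: ``wild_type.fasta``, ``msa.a3m``, ``dms.csv``,
    ``couplings.raw`` / ``couplings.mat``, one ``embeddings_<block>.h5``
    per block (WT plus every mutant id), ``ground_truth.json``,
    ``config.json`` and a ``manifest.json`` with sha256 checksums.
    Regeneration from the same config is bitwise-identical.
    """
    from .embedders import write_embedding_store  # local to avoid cycle at import

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = gen_dataset(config)
    ds = study.dataset

    write_fasta(out_dir / "wild_type.fasta", [(ds.name, ds.wild_type)])
    write_fasta(out_dir / "msa.a3m", _gen_msa(ds.wild_type, depth=20, seed=config.seed + 4))
    write_dms_table(out_dir / "dms.csv", ds)
    write_ccmpred_raw(out_dir / "couplings.raw", study.coupling_model)
    write_ccmpred_matrix(
        out_dir / "couplings.mat", study.coupling_model.summary_from_potentials()
    )
    ids = ["WT"] + [m.id for m in ds.mutants]
    seqs = [ds.wild_type] + [m.sequence for m in ds.mutants]
    for emb in study.embedders:
        write_embedding_store(
            out_dir / f"embeddings_{emb.name}.h5",
            (emb.embed(seq, sid) for sid, seq in zip(ids, seqs)),
            embedder_name=emb.name,
        )
    (out_dir / "ground_truth.json").write_text(study.truth.to_json())
    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    files = sorted(
        p.name for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": [
            {"name": name, "sha256": _sha256(out_dir / name),
             "bytes": (out_dir / name).stat().st_size}
            for name in files
        ],
        "seed": config.seed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("wrote synthetic study bundle to %s (%d files)", out_dir, len(files) + 1)
    return out_dir
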