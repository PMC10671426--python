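"""Evolutionary couplings from CCMPred output, and per-mutant local features.

CCMPred fits a Markov random field to an MSA of homologs.  Two artefacts
are consumed here:

* the default L x L summary matrix of coupling strengths (``.mat``), and
* the raw potential file with per-pair 21 x 21 tables e_ij(a, b) over the
  20 amino acids plus gap.

A mutant's *local feature* is a length-L vector resolving those couplings
at the mutant's actual residues:

    values[i] = sum_{j != i} e_ij(x_i, x_j)

so substituting one residue perturbs exactly the entries coupled to it.
With only a summary matrix available the fallback values[i] = sum_j C[i, j]
is sequence-independent (mutant specificity is lost; a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: CCMPred residue-state order: 20 amino acids then the gap state.
CCMPRED_ALPHABET = "ARNDCQEGHILKMFPSTWYV-"
GAP_STATE = len(CCMPRED_ALPHABET) - 1
_STATE_INDEX = {aa: i for i, aa in enumerate(CCMPRED_ALPHABET)}

_SYM_TOL = 1e-6


def encode_states(sequence: str, alphabet: str = CCMPRED_ALPHABET) -> np.ndarray:
    """Map residues to alphabet state indices; unknowns go to the gap state."""
    if alphabet == CCMPRED_ALPHABET:
        index = _STATE_INDEX
    else:
        index = {aa: i for i, aa in enumerate(alphabet)}
    gap = len(alphabet) - 1
    out = np.empty(len(sequence), dtype=np.intp)
    unknown = []
    for i, c in enumerate(sequence.upper()):
        s = index.get(c)
        if s is None:
            unknown.append(c)
            s = gap
        out[i] = s
    if unknown:
        logger.warning(
            "mapped %d residue(s) outside the coupling alphabet to the gap state: %s",
            len(unknown),
            sorted(set(unknown)),
        )
    return out


@dataclass
class CouplingModel:
    """MRF couplings over ``L`` positions and a 21-state residue alphabet.

    At least one of ``pair_potentials`` (L, L, A, A) and ``summary_matrix``
    (L, L) must be present.  Pair potentials satisfy e_ij(a,b) = e_ji(b,a);
    the summary matrix is symmetric with zero diagonal.
    """

    L: int
    alphabet: str = CCMPRED_ALPHABET
    pair_potentials: np.ndarray | None = None
    single_potentials: np.ndarray | None = None
    summary_matrix: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        A = len(self.alphabet)
        if self.pair_potentials is None and self.summary_matrix is None:
            raise ValidationError("coupling model needs pair potentials or a summary matrix")
        if self.pair_potentials is not None:
            e = np.asarray(self.pair_potentials, dtype=float)
            if e.shape != (self.L, self.L, A, A):
                raise ValidationError(
                    f"pair potentials shape {e.shape} != {(self.L, self.L, A, A)}"
                )
            if not np.allclose(e, e.transpose(1, 0, 3, 2), atol=_SYM_TOL):
                raise ValidationError("pair potentials violate e_ij(a,b) = e_ji(b,a)")
            self.pair_potentials = e
        if self.summary_matrix is not None:
            C = np.asarray(self.summary_matrix, dtype=float)
            if C.shape != (self.L, self.L):
                raise ValidationError(f"summary matrix shape {C.shape} != {(self.L, self.L)}")
            if np.abs(np.diag(C)).max(initial=0.0) > _SYM_TOL:
                raise ValidationError("summary matrix diagonal not zero")
            if np.abs(C - C.T).max(initial=0.0) > _SYM_TOL:
                raise ValidationError("summary matrix not symmetric")
            self.summary_matrix = C

    @property
    def has_pair_potentials(self) -> bool:
        return self.pair_potentials is not None

    def summary_from_potentials(self, include_gap: bool = False) -> np.ndarray:
        """Coupling-strength summary: Frobenius norm of each pair block."""
        if self.pair_potentials is None:
            raise DataError("no pair potentials to summarize")
        k = len(self.alphabet) if include_gap else len(self.alphabet) - 1
        block = self.pair_potentials[:, :, :k, :k]
        C = np.sqrt((block**2).sum(axis=(2, 3)))
        np.fill_diagonal(C, 0.0)
        return C


@dataclass(frozen=True)
class LocalFeature:
    """Per-position coupling sums for one mutant sequence (length L)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def read_ccmpred_matrix(path: str | Path) -> CouplingModel:
    """Read CCMPred's default L x L summary matrix (whitespace-delimited text).

    An asymmetric matrix is symmetrized as (C + C')/2 with a warning; the
    diagonal is zeroed.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-numeric entry ({exc})") from exc
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    C = np.array(rows, dtype=float)
    if C.shape[0] != C.shape[1]:
        raise FormatError(f"{path}: matrix is {C.shape[0]}x{C.shape[1]}, not square")
    if np.abs(C - C.T).max(initial=0.0) > _SYM_TOL:
        logger.warning("%s: asymmetric summary matrix; symmetrizing as (C + C')/2", path)
        C = (C + C.T) / 2.0
    np.fill_diagonal(C, 0.0)
    return CouplingModel(L=C.shape[0], summary_matrix=C, source=str(path))


def write_ccmpred_matrix(path: str | Path, C: np.ndarray) -> None:
    """Fixture writer for the summary-matrix dialect (value-exact)."""
    np.savetxt(path, np.asarray(C, dtype=float), fmt="%.17g", delimiter="\t")


def read_ccmpred_raw(path: str | Path, one_based_headers: bool = False) -> CouplingModel:
    """Read the CCMPred raw-potential dialect.

    Layout: L leading lines of 21 single-site values, then for every pair
    i < j a header ``# i j`` (0-based unless ``one_based_headers``)
    followed by 21 rows of 21 columns giving e_ij(a, b).
    """
    path = Path(path)
    A = len(CCMPRED_ALPHABET)
    singles: list[list[float]] = []
    blocks: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    while pos < len(lines) and not lines[pos].startswith("#"):
        if lines[pos].strip():
            vals = lines[pos].split()
            if len(vals) != A:
                raise FormatError(
                    f"{path}:{pos + 1}: single-site row has {len(vals)} values, expected {A}"
                )
            singles.append([float(v) for v in vals])
        pos += 1
    L = len(singles)
    if L < 2:
        raise FormatError(f"{path}: found {L} single-site rows; need at least 2")
    while pos < len(lines):
        header = lines[pos].strip()
        if not header:
            pos += 1
            continue
        if not header.startswith("#"):
            raise FormatError(f"{path}:{pos + 1}: expected pair header, got {header!r}")
        parts = header[1:].split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{pos + 1}: malformed pair header {header!r}")
        i, j = int(parts[0]), int(parts[1])
        if one_based_headers:
            i, j = i - 1, j - 1
        if not (0 <= i < L and 0 <= j < L and i != j):
            raise FormatError(f"{path}:{pos + 1}: pair ({i}, {j}) out of range for L={L}")
        block_lines = lines[pos + 1 : pos + 1 + A]
        if len(block_lines) < A:
            raise FormatError(f"{path}: truncated block for pair ({i}, {j})")
        try:
            block = np.array([[float(v) for v in bl.split()] for bl in block_lines])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric block for pair ({i}, {j})") from exc
        if block.shape != (A, A):
            raise FormatError(
                f"{path}: block for pair ({i}, {j}) has shape {block.shape}, expected {(A, A)}"
            )
        blocks[(min(i, j), max(i, j))] = block if i < j else block.T
        pos += 1 + A
    expected = {(i, j) for i in range(L) for j in range(i + 1, L)}
    missing = expected - set(blocks)
    if missing:
        raise FormatError(f"{path}: missing pair block(s), e.g. {sorted(missing)[:3]}")
    e = np.zeros((L, L, A, A))
    for (i, j), block in blocks.items():
        e[i, j] = block
        e[j, i] = block.T
    return CouplingModel(
        L=L,
        pair_potentials=e,
        single_potentials=np.array(singles),
        source=str(path),
    )


def write_ccmpred_raw(path: str | Path, model: CouplingModel) -> None:
    """Fixture writer for the raw-potential dialect (value-exact round-trip)."""
    if model.pair_potentials is None:
        raise DataError("model has no pair potentials to write")
    A = len(model.alphabet)
    singles = model.single_potentials
    if singles is None:
        singles = np.zeros((model.L, A))
    with open(path, "w") as fh:
        for row in singles:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
        for i in range(model.L):
            for j in range(i + 1, model.L):
                fh.write(f"# {i} {j}\n")
                for row in model.pair_potentials[i, j]:
                    fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def resolve_local_features(model: CouplingModel, sequence: str) -> LocalFeature:
    """Resolve the per-position coupling sums of ``sequence`` under ``model``.

    With pair potentials: values[i] = sum_{j != i} e_ij(x_i, x_j), the
    mutant-specific reading.  With only a summary matrix: the
    sequence-independent row sums of C (logged once per call).
    """
    if len(sequence) != model.L:
        raise DataError(f"sequence length {len(sequence)} != model length {model.L}")
    if model.pair_potentials is not None:
        states = encode_states(sequence, model.alphabet)
        L = model.L
        idx = np.arange(L)
        pair_vals = model.pair_potentials[
            idx[:, None], idx[None, :], states[:, None], states[None, :]
        ]
        np.fill_diagonal(pair_vals, 0.0)
        # accumulate left-to-right (not pairwise) so the result is
        # bit-identical to a naive double loop over j
        values = np.zeros(L)
        for j in range(L):
            values += pair_vals[:, j]
        return LocalFeature(values=values)
    logger.warning(
        "coupling model %s has summary scores only: local features are "
        "sequence-independent (mutant specificity lost)",
        model.source or "<unnamed>",
    )
    return LocalFeature(values=model.summary_matrix.sum(axis=1))


def resolve_pairwise_features(model: CouplingModel, sequence: str) -> np.ndarray:
    """Full per-position coupling profile [e_ij(x_i, x_j)]_{ij}, flattened.

    The length L*L row-major alternative local representation (available
    for ablation; higher-dimensional than the default per-position sums).
    """
    if model.pair_potentials is None:
        raise DataError("pairwise local features require raw pair potentials")
    if len(sequence) != model.L:
        raise DataError(f"sequence length {len(sequence)} != model length {model.L}")
    states = encode_states(sequence, model.alphabet)
    idx = np.arange(model.L)
    pair_vals = model.pair_potentials[
        idx[:, None], idx[None, :], states[:, None], states[None, :]
    ]
    np.fill_diagonal(pair_vals, 0.0)
    return pair_vals.reshape(-1)
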