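"""Core domain types and I/O for deep mutational scanning (DMS) data.

A DMS experiment measures a quantitative fitness score for many variants
of one wild-type protein.  Variants are substitution-only and written in
the ProteinGym convention: ``A1P`` mutates residue A at 1-based position 1
to P; multiple substitutions are joined with ``:`` (``A1P:G2K``).

Coordinates are 1-based in mutation notation and in all user-facing
interfaces; internal array indices are 0-based, with the conversion
confined to the parsing/formatting functions in this module.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError, DataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet (alphabetical by one-letter code).
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_SET = frozenset(AA20)

#: Ambiguity / non-canonical codes tolerated in wild-type and MSA sequences
#: (mapped to embedder-specific "unknown" handling), but rejected in
#: mutation strings.
NONCANONICAL = frozenset("XBZUO")

_MUT_TOKEN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class Mutation:
    """A single amino-acid substitution.

    Attributes
    ----------
    wt_aa : str
        Wild-type residue (single letter, canonical alphabet).
    position : int
        1-based position in the wild-type sequence.
    alt_aa : str
        Substituted residue; must differ from ``wt_aa``.
    """

    wt_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA20_SET:
            raise ValidationError(f"wild-type residue {self.wt_aa!r} is not canonical")
        if self.alt_aa not in AA20_SET:
            raise ValidationError(f"substituted residue {self.alt_aa!r} is not canonical")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.wt_aa == self.alt_aa:
            raise ValidationError(
                f"synonymous substitution {self.wt_aa}{self.position}{self.alt_aa}"
            )

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.alt_aa}"

    def inverse(self) -> "Mutation":
        return Mutation(self.alt_aa, self.position, self.wt_aa)


def parse_mutant_string(text: str, separator: str = ":") -> list[Mutation]:
    """Parse a ProteinGym-style mutant string into a position-sorted list.

    ``","`` is accepted as an alternative separator regardless of the one
    requested, as both occur in the wild.
    """
    if not text or not text.strip():
        raise FormatError("empty mutant string")
    normalized = text.strip().replace(",", separator)
    mutations = []
    for token in normalized.split(separator):
        token = token.strip()
        m = _MUT_TOKEN.match(token)
        if m is None:
            raise FormatError(f"malformed mutation token {token!r} in {text!r}")
        wt, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        mutations.append(Mutation(wt, pos, alt))
    mutations.sort(key=lambda mu: mu.position)
    positions = [mu.position for mu in mutations]
    if len(set(positions)) != len(positions):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValidationError(f"duplicate mutated position(s) {dupes} in {text!r}")
    return mutations


def format_mutant_string(mutations: Sequence[Mutation], separator: str = ":") -> str:
    """Inverse of :func:`parse_mutant_string` (positions emitted sorted)."""
    return separator.join(str(mu) for mu in sorted(mutations, key=lambda m: m.position))


def apply_mutations(wild_type: str, mutations: Sequence[Mutation]) -> str:
    """Apply substitutions to the wild type, validating each wt residue."""
    seq = list(wild_type)
    for mu in mutations:
        if mu.position > len(wild_type):
            raise ValidationError(
                f"position {mu.position} beyond wild-type length {len(wild_type)}"
            )
        found = seq[mu.position - 1]
        if found != mu.wt_aa:
            raise ValidationError(
                f"wild-type mismatch at position {mu.position}: "
                f"expected {mu.wt_aa}, found {found}"
            )
        seq[mu.position - 1] = mu.alt_aa
    return "".join(seq)


@dataclass(frozen=True)
class MutantRecord:
    """One measured variant: its substitutions, full sequence and score."""

    mutations: tuple[Mutation, ...]
    sequence: str
    fitness: float
    id: str = ""

    @classmethod
    def from_mutations(
        cls,
        wild_type: str,
        mutations: Sequence[Mutation],
        fitness: float,
        id: str = "",
    ) -> "MutantRecord":
        mutations = tuple(sorted(mutations, key=lambda m: m.position))
        sequence = apply_mutations(wild_type, mutations)
        if not id:
            id = format_mutant_string(mutations) if mutations else "WT"
        return cls(mutations=mutations, sequence=sequence, fitness=float(fitness), id=id)

    @property
    def mutant_string(self) -> str:
        return format_mutant_string(self.mutations)

    @property
    def order(self) -> int:
        return len(self.mutations)


@dataclass
class DMSDataset:
    """A deep mutational scan: one wild type plus scored substitution mutants.

    Supervised modeling is performed separately per dataset; mutants are the
    rows of every feature matrix downstream, in list order.
    """

    name: str
    wild_type: str
    mutants: list[MutantRecord]
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.wild_type:
            raise ValidationError(f"dataset {self.name!r}: empty wild type")
        bad = [c for c in self.wild_type if c not in AA20_SET and c not in NONCANONICAL]
        if bad:
            raise ValidationError(
                f"dataset {self.name!r}: invalid residues {sorted(set(bad))} in wild type"
            )
        if not self.mutants:
            raise DataError(f"dataset {self.name!r}: no mutants")
        L = len(self.wild_type)
        for rec in self.mutants:
            if len(rec.sequence) != L:
                raise ValidationError(
                    f"mutant {rec.id!r}: length {len(rec.sequence)} != wild-type {L}"
                )
            if not math.isfinite(rec.fitness):
                raise DataError(f"mutant {rec.id!r}: non-finite fitness")
            for mu in rec.mutations:
                if self.wild_type[mu.position - 1] != mu.wt_aa:
                    raise ValidationError(
                        f"mutant {rec.id!r}: wild-type mismatch at {mu.position} "
                        f"(expected {mu.wt_aa}, wild type has "
                        f"{self.wild_type[mu.position - 1]})"
                    )

    def __len__(self) -> int:
        return len(self.mutants)

    @property
    def fitness(self) -> list[float]:
        return [m.fitness for m in self.mutants]

    @property
    def sequences(self) -> list[str]:
        return [m.sequence for m in self.mutants]


def read_dms_table(
    path: str | Path,
    mutant_column: str = "mutant",
    score_column: str = "DMS_score",
    wild_type: str = "",
    name: str | None = None,
    separator: str = ":",
) -> DMSDataset:
    """Read a ProteinGym-convention variant table (CSV or TSV by extension).

    Rows with non-finite scores are dropped with a logged count; mutant
    strings inconsistent with the wild type raise a validation error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (mutant_column, score_column):
        if col not in df.columns:
            raise ConfigError(
                f"{path}: missing column {col!r}; available: {list(df.columns)}"
            )
    scores = pd.to_numeric(df[score_column], errors="coerce")
    keep = scores.notna() & ~scores.isin([float("inf"), float("-inf")])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite scores", path, n_dropped)
    df = df.loc[keep]
    if df.empty:
        raise DataError(f"{path}: no rows with finite scores")
    mutants = [
        MutantRecord.from_mutations(
            wild_type, parse_mutant_string(str(mut), separator), float(score)
        )
        for mut, score in zip(df[mutant_column], scores.loc[keep])
    ]
    return DMSDataset(name=name or path.stem, wild_type=wild_type, mutants=mutants)


def write_dms_table(
    path: str | Path,
    dataset: DMSDataset,
    mutant_column: str = "mutant",
    score_column: str = "DMS_score",
) -> None:
    df = pd.DataFrame(
        {
            mutant_column: [m.mutant_string for m in dataset.mutants],
            score_column: [repr(m.fitness) for m in dataset.mutants],
        }
    )
    df.to_csv(path, index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``(id, sequence)`` pairs."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@dataclass
class MSA:
    """Query-anchored multiple sequence alignment of homologs.

    ``offset`` maps alignment columns to wild-type positions when the MSA
    covers only a sub-domain: column ``c`` (0-based) corresponds to
    wild-type position ``offset + c + 1`` (1-based).
    """

    aligned_sequences: list[str]
    query_index: int = 0
    ids: list[str] = field(default_factory=list)
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.aligned_sequences:
            raise FormatError("empty alignment")
        widths = {len(s) for s in self.aligned_sequences}
        if len(widths) != 1:
            raise FormatError(f"ragged alignment: row widths {sorted(widths)}")
        if not (0 <= self.query_index < len(self.aligned_sequences)):
            raise ValidationError(f"query_index {self.query_index} out of range")

    @property
    def width(self) -> int:
        return len(self.aligned_sequences[0])

    @property
    def depth(self) -> int:
        return len(self.aligned_sequences)

    @property
    def query(self) -> str:
        return self.aligned_sequences[self.query_index]

    def validate_against(self, wild_type: str) -> None:
        """Check the degapped query matches the wild type at ``offset``."""
        degapped = self.query.replace("-", "").replace(".", "")
        span = wild_type[self.offset : self.offset + len(degapped)]
        if degapped.upper() != span.upper():
            raise ValidationError(
                f"MSA query (degapped, {len(degapped)} aa) does not match "
                f"wild type at offset {self.offset}"
            )


def read_msa(
    path: str | Path,
    dialect: str = "a3m",
    query_index: int = 0,
    offset: int = 0,
) -> MSA:
    """Read an alignment in A3M or aligned-FASTA dialect.

    A3M marks insertions relative to the query as lowercase letters (and
    ``.`` gaps); removing them yields rows of query length.
    """
    if dialect not in {"a3m", "aligned-fasta"}:
        raise ConfigError(f"unknown MSA dialect {dialect!r}")
    records = read_fasta(path)
    ids = [rid for rid, _ in records]
    if dialect == "a3m":
        rows = ["".join(c for c in seq if not (c.islower() or c == ".")) for _, seq in records]
    else:
        rows = [seq.upper() for _, seq in records]
    return MSA(aligned_sequences=rows, query_index=query_index, ids=ids, offset=offset)
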