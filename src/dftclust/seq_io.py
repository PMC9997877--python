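"""FASTA input, record validation, and tabular/matrix text output.

DNA sequences enter the pipeline as plain multi-record FASTA (wrapped or
unwrapped).  Residues are normalized to uppercase, RNA ``U`` is silently
mapped to ``T``, and any character outside the IUPAC nucleotide alphabet
raises an error naming the offending record.  Distance matrices are written
as square PHYLIP-style text so they can be consumed by standard phylogenetic
tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Every single-letter IUPAC nucleotide code (after U -> T normalization).
IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHV")

#: Codes that are *not* an unambiguous A, C, G or T.
AMBIGUOUS_CODES = frozenset("NRYSWKMBDHV")


class SeqIOError(ValueError):
    """Base class for sequence-input validation failures."""


class EmptyFastaError(SeqIOError):
    """The FASTA file contained no records."""


class EmptySequenceError(SeqIOError):
    """A FASTA record had a header but no residues."""


class DuplicateIdError(SeqIOError):
    """Two records in one dataset share an identifier."""


class InvalidResidueError(SeqIOError):
    """A residue falls outside the IUPAC nucleotide alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence.

    Attributes
    ----------
    id:
        Unique (per dataset) identifier, taken from the FASTA header up to
        the first whitespace.
    residues:
        Uppercase IUPAC nucleotide string, ``U`` already mapped to ``T``.
    source:
        Free-text provenance (file of origin, record index, ...).
    """

    id: str
    residues: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("record id must be non-empty")
        if not self.residues:
            raise EmptySequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_NUCLEOTIDES
        if bad:
            raise InvalidResidueError(
                f"record {self.id!r}: non-IUPAC residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> str:
    """Uppercase, drop internal whitespace, and map RNA U to T."""
    return "".join(raw.split()).upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read and validate every record of a FASTA file.

    Record order is preserved.  Raises :class:`EmptyFastaError`,
    :class:`EmptySequenceError`, :class:`DuplicateIdError` or
    :class:`InvalidResidueError` with the offending record named.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise EmptySequenceError(f"record {rec.id!r} in {path}: empty sequence")
        records.append(
            SequenceRecord(rec.id, residues, source=f"{path.name}#{idx}")
        )
    if not records:
        raise EmptyFastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA (deterministic layout)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_distance_matrix(D: "DistanceMatrix", path: str | Path) -> None:
    """Write a square PHYLIP-style distance matrix.

    First line is ``n``; each following line is the id plus the full row of
    tab-separated distances at full float precision (round-trips to 1e-9).
    """
    from .cluster import DistanceMatrix  # deferred: cluster imports none of seq_io

    if not isinstance(D, DistanceMatrix):
        raise TypeError("expected a DistanceMatrix")
    with open(path, "w") as fh:
        fh.write(f"{len(D.ids)}\n")
        for name, row in zip(D.ids, D.d):
            cells = "\t".join(f"{v:.17g}" for v in row)
            fh.write(f"{name}\t{cells}\n")


def read_distance_matrix(path: str | Path) -> "DistanceMatrix":
    """Read back a matrix produced by :func:`write_distance_matrix`."""
    from .cluster import DistanceMatrix

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0])
    ids, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split("\t")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(ids=ids, d=np.asarray(rows, dtype=float))
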