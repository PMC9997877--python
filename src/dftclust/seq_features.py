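"""Per-sequence composition statistics: length, base counts, GC content.

GC content is reported as ``100 * (G + C) / length`` where the length
includes ambiguous positions (N and other non-ACGT IUPAC codes).  An
alternative denominator that excludes ambiguous positions is available
behind a flag.  Displayed values are rounded half-up to one decimal; the
full-precision value is kept on the object.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_io import SequenceRecord

TABLE_COLUMNS = ["id", "length", "A", "C", "G", "T", "ambiguous", "GC%"]


@dataclass(frozen=True)
class SequenceFeatures:
    id: str
    length: int
    count_A: int
    count_C: int
    count_G: int
    count_T: int
    count_ambiguous: int
    gc_percent: float  # full precision; render with round_half_up_1

    def __post_init__(self) -> None:
        total = (
            self.count_A + self.count_C + self.count_G + self.count_T
            + self.count_ambiguous
        )
        if total != self.length:
            raise ValueError(
                f"{self.id!r}: base counts sum to {total}, length is {self.length}"
            )
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError(f"{self.id!r}: GC% {self.gc_percent} out of [0, 100]")


def round_half_up_1(x: float) -> float:
    """Round to one decimal with ties away from zero (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gc_percent_from_counts(
    count_G: int, count_C: int, length: int, *, exclude_ambiguous_from: int = 0
) -> float:
    """GC% from raw tallies; optionally drop ambiguous positions from the denominator."""
    denom = length - exclude_ambiguous_from
    if denom <= 0:
        raise ValueError("GC denominator must be positive")
    return 100.0 * (count_G + count_C) / denom


def compute_features(
    rec: SequenceRecord, *, exclude_ambiguous_in_gc: bool = False
) -> SequenceFeatures:
    """Exact character tallies and GC content for one record."""
    counts = {b: rec.residues.count(b) for b in "ACGT"}
    n_amb = len(rec.residues) - sum(counts.values())
    gc = gc_percent_from_counts(
        counts["G"],
        counts["C"],
        len(rec.residues),
        exclude_ambiguous_from=n_amb if exclude_ambiguous_in_gc else 0,
    )
    return SequenceFeatures(
        id=rec.id,
        length=len(rec.residues),
        count_A=counts["A"],
        count_C=counts["C"],
        count_G=counts["G"],
        count_T=counts["T"],
        count_ambiguous=n_amb,
        gc_percent=gc,
    )


def features_table(
    records: Sequence[SequenceRecord],
    *,
    exclude_ambiguous_in_gc: bool = False,
    extra_columns: Mapping[str, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """One row per record, in input order, with GC% rendered to one decimal.

    ``extra_columns`` maps a column name to a per-id mapping of pass-through
    metadata (e.g. exon counts from an annotation source).
    """
    if not records:
        raise ValueError("features_table requires at least one record")
    rows = []
    for rec in records:
        f = compute_features(rec, exclude_ambiguous_in_gc=exclude_ambiguous_in_gc)
        rows.append(
            {
                "id": f.id,
                "length": f.length,
                "A": f.count_A,
                "C": f.count_C,
                "G": f.count_G,
                "T": f.count_T,
                "ambiguous": f.count_ambiguous,
                "GC%": round_half_up_1(f.gc_percent),
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if extra_columns:
        for col, mapping in extra_columns.items():
            df[col] = [mapping.get(i, "") for i in df["id"]]
    return df


def write_features_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.1f")
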