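"""Binary indicator (Voss) representation of DNA.

A sequence of length N becomes four binary vectors, one per base: the
A-vector ``w`` holds 1 exactly where the residue is A, and likewise ``x``
for T, ``y`` for G and ``z`` for C.  Ambiguous residues (N, R, Y, ...)
contribute 0 to all four vectors, so the four vectors sum to 1 at
unambiguous positions and 0 at ambiguous ones.  The encoding is lossless on
unambiguous sequence: the residue at a position is recoverable from the
unique vector holding a 1 there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .seq_io import SequenceRecord

#: Layout order of the four indicator vectors (and of downstream features).
BASE_ORDER = ("A", "T", "G", "C")


@dataclass(frozen=True)
class IndicatorSet:
    """The four binary indicator vectors of one record.

    Vector naming follows the genomic-signal-processing convention:
    ``w`` = A, ``x`` = T, ``y`` = G, ``z`` = C.
    """

    id: str
    n: int
    w: np.ndarray  # base A
    x: np.ndarray  # base T
    y: np.ndarray  # base G
    z: np.ndarray  # base C

    def vectors(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (base, vector) pairs in the fixed A, T, G, C order."""
        yield "A", self.w
        yield "T", self.x
        yield "G", self.y
        yield "C", self.z

    def vector(self, base: str) -> np.ndarray:
        return dict(self.vectors())[base.upper()]


def indicator_set(rec: SequenceRecord) -> IndicatorSet:
    """Encode a record as its four binary indicator vectors."""
    arr = np.frombuffer(rec.residues.encode("ascii"), dtype="S1")
    vecs = {b: (arr == b.encode()).astype(np.int8) for b in BASE_ORDER}
    return IndicatorSet(
        id=rec.id,
        n=len(rec.residues),
        w=vecs["A"],
        x=vecs["T"],
        y=vecs["G"],
        z=vecs["C"],
    )


def indicator_text(ind: IndicatorSet) -> str:
    """Debug dump: one 0/1 row per base, in A, T, G, C order."""
    lines = [f"{base}\t" + "".join(map(str, vec.tolist())) for base, vec in ind.vectors()]
    return "\n".join(lines) + "\n"
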