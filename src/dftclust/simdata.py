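"""Seeded synthetic sequence families for end-to-end pipeline testing.

Each family descends from an independent random ancestor; members accrue
i.i.d. substitutions and geometric-length indels, so members of one family
are similar but of *unequal* length — deliberately exercising the
length-invariance of the spectral moment features.  The default parameters
(4 families of 6 members, 3 kb ancestors, 2% substitutions, 0.2% indel
events per site) sit at desk scale: familial divergence well below, and
between-family divergence at, the saturation level of random sequence, the
regime the clustering method targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cluster import ClusterLabeling
from .seq_io import SequenceRecord, write_fasta

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the synthetic family generator.

    gc_bias is the expected G+C fraction of ancestors (and of inserted
    sequence); substitution_rate and indel_rate are per-site event
    probabilities per member.
    """

    n_families: int = 4
    members_per_family: int = 6
    ancestor_length: int = 3000
    substitution_rate: float = 0.02
    indel_rate: float = 0.002
    gc_bias: float = 0.5
    seed: int = 20230309

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("need at least one family and one member")
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be positive")
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.gc_bias < 1.0:
            raise ValueError("gc_bias must lie in (0, 1)")


def _base_probs(gc_bias: float) -> np.ndarray:
    at = (1.0 - gc_bias) / 2.0
    gc = gc_bias / 2.0
    return np.array([at, gc, gc, at])  # order A, C, G, T


def _random_seq(rng: np.random.Generator, length: int, gc_bias: float) -> np.ndarray:
    return rng.choice(_BASES, size=length, p=_base_probs(gc_bias))


def _mutate(
    rng: np.random.Generator, ancestor: np.ndarray, spec: FamilySpec
) -> str:
    seq = ancestor.copy()
    # substitutions: each hit site moves to one of the three other bases
    hits = np.nonzero(rng.random(len(seq)) < spec.substitution_rate)[0]
    for i in hits:
        others = _BASES[_BASES != seq[i]]
        seq[i] = others[rng.integers(3)]
    # indels: per-site events; geometric lengths keep most events short
    pieces: list[str] = []
    i = 0
    while i < len(seq):
        r = rng.random()
        if r < spec.indel_rate / 2.0:  # deletion starting here
            gap = rng.geometric(0.5)
            i += gap
        elif r < spec.indel_rate:  # insertion before this site
            ins = _random_seq(rng, rng.geometric(0.5), spec.gc_bias)
            pieces.append("".join(ins))
            pieces.append(seq[i])
            i += 1
        else:
            pieces.append(seq[i])
            i += 1
    return "".join(pieces)


def generate_families(spec: FamilySpec) -> tuple[list[SequenceRecord], ClusterLabeling]:
    """Draw the families; returns records plus true family labels.

    Deterministic: identical spec (including seed) gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    labels: list[int] = []
    for fam in range(spec.n_families):
        ancestor = _random_seq(rng, spec.ancestor_length, spec.gc_bias)
        for mem in range(spec.members_per_family):
            residues = _mutate(rng, ancestor, spec)
            if not residues:  # extreme indel rates can delete everything
                residues = "".join(_random_seq(rng, 1, spec.gc_bias))
            records.append(
                SequenceRecord(
                    id=f"fam{fam + 1}_m{mem + 1}",
                    residues=residues,
                    source=f"simdata(seed={spec.seed})",
                )
            )
            labels.append(fam)
    return records, ClusterLabeling(
        ids=[r.id for r in records], labels=np.array(labels)
    )


def write_family_fixture(
    spec: FamilySpec, fasta_path: str | Path, truth_path: str | Path
) -> tuple[list[SequenceRecord], ClusterLabeling]:
    """Generate and persist FASTA plus a two-column truth-label TSV."""
    records, truth = generate_families(spec)
    write_fasta(records, fasta_path)
    with open(truth_path, "w") as fh:
        fh.write("id\tfamily\n")
        for i, lab in zip(truth.ids, truth.labels):
            fh.write(f"{i}\t{lab}\n")
    return records, truth
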