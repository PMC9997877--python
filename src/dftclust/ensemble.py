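"""Evidence-accumulation fusion of multiple clusterings into one consensus.

Each base clustering is converted to a binary co-membership matrix; their
average is the co-association matrix, whose entry (i, j) is the fraction of
base clusterings in which i and j share a cluster.  The consensus tree is
then hierarchical clustering of the dissimilarity 1 - co-association
(average linkage by default), and the consensus partition is that tree cut
at k.  Fusing over single, complete, average and median trees hedges the
result against the sensitivity of any one linkage rule to noise, outliers
and cluster shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cluster import (
    ClusterLabeling,
    DistanceMatrix,
    LINKAGE_METHODS,
    MergeTree,
    cut_tree,
    euclidean_distances,
    linkage,
    standardize_features,
)
from .spectral import FeatureVector

DEFAULT_METHODS: tuple[str, ...] = LINKAGE_METHODS
DEFAULT_K = 4


@dataclass(frozen=True)
class CoAssociationMatrix:
    ids: list[str]
    c: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        n = len(self.ids)
        if c.shape != (n, n):
            raise ValueError("co-association matrix shape mismatch")
        if not np.allclose(c, c.T):
            raise ValueError("co-association matrix must be symmetric")
        if np.any((c < 0) | (c > 1)) or np.any(np.diag(c) != 1):
            raise ValueError("entries must lie in [0, 1] with unit diagonal")
        object.__setattr__(self, "c", c)


def coassociation(labelings: Sequence[ClusterLabeling]) -> CoAssociationMatrix:
    """Fraction of base clusterings co-clustering each pair."""
    if not labelings:
        raise ValueError("need at least one labeling")
    ids = labelings[0].ids
    for lab in labelings[1:]:
        if lab.ids != ids:
            raise ValueError("labelings must share an identical id list")
    acc = np.zeros((len(ids), len(ids)))
    for lab in labelings:
        acc += (lab.labels[:, None] == lab.labels[None, :]).astype(float)
    return CoAssociationMatrix(ids=list(ids), c=acc / len(labelings))


def consensus_tree(c: CoAssociationMatrix, method: str = "average") -> MergeTree:
    """Hierarchical clustering of the evidence, via d = 1 - c."""
    d = 1.0 - c.c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return linkage(DistanceMatrix(ids=list(c.ids), d=d), method)


def run_ensemble(
    features: Sequence[FeatureVector],
    methods: Sequence[str] = DEFAULT_METHODS,
    k: int = DEFAULT_K,
    *,
    consensus_linkage: str = "average",
    standardize: bool = True,
) -> tuple[CoAssociationMatrix, MergeTree, ClusterLabeling]:
    """Full fusion pipeline: per-method tree + cut, co-association, consensus.

    Feature columns are z-scored before the Euclidean distance by default:
    the total-power and moment coordinates live on incommensurate scales
    (total power grows with sequence length, moments are normalized
    frequencies below 1/2), so raw Euclidean distance would reduce to a
    composition-and-length comparison and waste the spectral shape terms.
    Returns the co-association matrix, the consensus merge tree, and the
    consensus partition at the shared cluster count ``k``.
    """
    if not methods:
        raise ValueError("need at least one linkage method")
    if standardize:
        features = standardize_features(features)
    D = euclidean_distances(features)
    labelings = [cut_tree(linkage(D, m), k) for m in methods]
    c = coassociation(labelings)
    tree = consensus_tree(c, consensus_linkage)
    return c, tree, cut_tree(tree, k)
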