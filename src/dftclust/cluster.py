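"""Distances, agglomerative hierarchical clustering, tree cutting, Newick.

Four Lance-Williams linkages are supported — single (nearest distance),
complete (furthest distance), average (UPGMA) and median (WPGMC) — matching
the four tree-building rules the pipeline fuses downstream.  Median linkage
operates on squared distances with the update d(k, ij)^2 = d(k,i)^2/2 +
d(k,j)^2/2 - d(i,j)^2/4 and reports square-rooted heights so all four trees
share a scale; it is the one method whose merge heights may invert
(decrease), which the tree type tolerates and Newick export clamps.

Tie-breaking is deterministic: among pairs at the minimal distance, the
lexicographically smallest (node-index, node-index) pair merges.  Distances
within a 1e-9 relative band of the minimum count as tied, so mathematically
equal values reached by different summation orders (e.g. equal averages of
integer distances) break the same way in any arithmetically equivalent
implementation.  Leaves are nodes 0..n-1 in input order; merge t creates
node n+t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .spectral import FeatureVector

LINKAGE_METHODS = ("single", "complete", "average", "median")
#: The paper-of-record taxonomy calls median linkage WPGMC; accept both.
LINKAGE_ALIASES = {"upgma": "average", "wpgmc": "median"}

_NEWICK_UNSAFE = set("(),:;'\" \t\n[]")


@dataclass(frozen=True)
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class MergeEvent:
    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class MergeTree:
    """Full agglomeration history: n-1 merges over leaves 0..n-1."""

    ids: list[str]
    merges: list[MergeEvent]
    linkage_name: str

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    def to_scipy_linkage(self) -> np.ndarray:
        """(n-1, 4) array in scipy.cluster.hierarchy layout."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )


@dataclass(frozen=True)
class ClusterLabeling:
    """A flat partition: integer labels 0..k-1 over an ordered id list."""

    ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (len(self.ids),):
            raise ValueError("one label per id required")
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must form a contiguous 0..k-1 range")
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def standardize_features(features: Sequence[FeatureVector]) -> list[FeatureVector]:
    """Z-score each feature column; zero-variance columns become 0."""
    X = np.vstack([f.values for f in features])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    return [FeatureVector(f.id, row) for f, row in zip(features, Z)]


def euclidean_distances(features: Sequence[FeatureVector]) -> DistanceMatrix:
    """Pairwise Euclidean distances between feature vectors."""
    if len(features) < 2:
        raise ValueError("need at least two feature vectors")
    dims = {f.values.shape for f in features}
    if len(dims) != 1:
        raise ValueError(f"feature dimension mismatch: {sorted(dims)}")
    X = np.vstack([f.values for f in features])
    return DistanceMatrix(ids=[f.id for f in features], d=squareform(pdist(X)))


def resolve_method(method: str) -> str:
    m = method.lower()
    m = LINKAGE_ALIASES.get(m, m)
    if m not in LINKAGE_METHODS:
        raise ValueError(
            f"unknown linkage {method!r}; choose from {LINKAGE_METHODS} "
            f"or aliases {sorted(LINKAGE_ALIASES)}"
        )
    return m


def linkage(D: DistanceMatrix, method: str) -> MergeTree:
    """Agglomerate under one of the four Lance-Williams update rules."""
    method = resolve_method(method)
    n = D.n
    if n < 2:
        raise ValueError("clustering needs at least two items")

    squared = method == "median"
    # Working distances between *active* nodes, keyed by (lo, hi) node index.
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = D.d[i, j]
            dist[(i, j)] = v * v if squared else v
    active: list[int] = list(range(n))
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    merges: list[MergeEvent] = []

    for t in range(n - 1):
        pairs = []
        for idx_a in range(len(active)):
            for idx_b in range(idx_a + 1, len(active)):
                a, b = active[idx_a], active[idx_b]
                key = (a, b) if a < b else (b, a)
                pairs.append((dist[key], key))
        dmin = min(v for v, _ in pairs)
        tol = 1e-9 * max(1.0, dmin)
        a, b = min(key for v, key in pairs if v - dmin <= tol)
        new = n + t
        dab = dist[(a, b)]
        height = float(np.sqrt(max(dab, 0.0))) if squared else float(dab)
        merges.append(MergeEvent(a, b, height, sizes[a] + sizes[b]))
        for c in active:
            if c in (a, b):
                continue
            dca = dist[(min(a, c), max(a, c))]
            dcb = dist[(min(b, c), max(b, c))]
            if method == "single":
                dnew = min(dca, dcb)
            elif method == "complete":
                dnew = max(dca, dcb)
            elif method == "average":
                na, nb = sizes[a], sizes[b]
                dnew = (na * dca + nb * dcb) / (na + nb)
            else:  # median, in squared space
                dnew = 0.5 * dca + 0.5 * dcb - 0.25 * dab
            dist[(c, new)] = dnew
        active = [c for c in active if c not in (a, b)] + [new]
        sizes[new] = sizes[a] + sizes[b]

    return MergeTree(ids=list(D.ids), merges=merges, linkage_name=method)


def _children(tree: MergeTree) -> dict[int, tuple[int, int]]:
    n = tree.n_leaves
    return {n + t: (m.left, m.right) for t, m in enumerate(tree.merges)}


def _leaves_under(node: int, children: dict[int, tuple[int, int]]) -> list[int]:
    if node not in children:
        return [node]
    l, r = children[node]
    return _leaves_under(l, children) + _leaves_under(r, children)


def cut_tree(tree: MergeTree, k: int) -> ClusterLabeling:
    """Partition into k clusters by undoing the last k-1 merges.

    Labels are 0..k-1, numbered by order of first leaf appearance.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    return _labels_from_merges(tree, n - k)


def cut_at_height(tree: MergeTree, height: float) -> ClusterLabeling:
    """Partition by keeping only merges at or below ``height``.

    With non-monotone (median) trees this keeps the longest prefix of merges
    whose heights all lie at or below the threshold, which matches the
    visual horizontal-line cut on a monotone dendrogram.
    """
    kept = 0
    for m in tree.merges:
        if m.height <= height:
            kept += 1
        else:
            break
    return _labels_from_merges(tree, kept)


def _labels_from_merges(tree: MergeTree, n_merges: int) -> ClusterLabeling:
    n = tree.n_leaves
    parent = list(range(n + n_merges))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for t in range(n_merges):
        m = tree.merges[t]
        new = n + t
        parent[find(m.left)] = new
        parent[find(m.right)] = new
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in seen:
            seen[root] = len(seen)
        labels[leaf] = seen[root]
    return ClusterLabeling(ids=list(tree.ids), labels=labels)


def plot_dendrogram(tree: MergeTree, path: str | Path, **kwargs) -> None:
    """Render the merge tree to PNG/SVG (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    fig, ax = plt.subplots(figsize=(8, 0.3 * tree.n_leaves + 2))
    dendrogram(
        tree.to_scipy_linkage(), labels=tree.ids, orientation="left", ax=ax, **kwargs
    )
    ax.set_title(f"{tree.linkage_name} linkage")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _quote_label(label: str) -> str:
    if set(label) & _NEWICK_UNSAFE:
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: MergeTree) -> str:
    """Newick string with branch lengths from merge heights (leaves at 0).

    A child branch is parent height minus child height; with median linkage
    height inversions this can go negative, in which case it is clamped to
    zero with a warning.
    """
    n = tree.n_leaves
    children = _children(tree)
    heights = {i: 0.0 for i in range(n)}
    for t, m in enumerate(tree.merges):
        heights[n + t] = m.height
    clamped = False

    def render(node: int, parent_height: float) -> str:
        nonlocal clamped
        branch = parent_height - heights[node]
        if branch < 0:
            clamped = True
            branch = 0.0
        if node in children:
            l, r = children[node]
            body = f"({render(l, heights[node])},{render(r, heights[node])})"
        else:
            body = _quote_label(tree.ids[node])
        return f"{body}:{branch:.10g}"

    root = n + len(tree.merges) - 1
    l, r = children[root]
    h = heights[root]
    out = f"({render(l, h)},{render(r, h)});"
    if clamped:
        warnings.warn(
            f"{tree.linkage_name} tree has height inversions; "
            "negative branch lengths clamped to 0",
            stacklevel=2,
        )
    return out
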