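"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: the DFT oracle is the
literal defining sum, and the clustering oracle re-derives inter-cluster
distances from leaf sets at every step instead of using running
Lance-Williams updates.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


def naive_dft(signal) -> np.ndarray:
    """Term-by-term evaluation of X[k] = sum_n x[n] e^{-2j pi k n / N}."""
    x = list(signal)
    N = len(x)
    return np.array(
        [
            sum(x[n] * cmath.exp(-2j * cmath.pi * k * n / N) for n in range(N))
            for k in range(N)
        ]
    )


def brute_force_linkage(D: np.ndarray, method: str):
    """From-scratch agglomeration oracle.

    single/complete/average distances are recomputed from the original
    matrix over explicit leaf sets each step; median recurses the centroid
    rule on squared distances in an independent dict-based structure.
    Tie-break: lexicographically smallest (node, node) pair, with values
    inside a 1e-9 relative band of the minimum counting as tied.  Returns a
    list of (left, right, height, size) merge tuples, node numbering as in
    the package (leaves 0..n-1, merge t creates n+t).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    if method == "median":
        sq = {(i, j): D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    merges = []
    for t in range(n - 1):
        cand = []
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                if method == "single":
                    d = min(D[i, j] for i in members[a] for j in members[b])
                elif method == "complete":
                    d = max(D[i, j] for i in members[a] for j in members[b])
                elif method == "average":
                    vals = [D[i, j] for i in members[a] for j in members[b]]
                    d = sum(vals) / len(vals)
                elif method == "median":
                    d = sq[(a, b)]
                else:
                    raise ValueError(method)
                cand.append((d, (a, b)))
        dmin = min(v for v, _ in cand)
        tol = 1e-9 * max(1.0, dmin)
        a, b = min(key for v, key in cand if v - dmin <= tol)
        d = {key: v for v, key in cand}[(a, b)]
        new = n + t
        members[new] = members[a] | members[b]
        if method == "median":
            for c in sorted(active - {a, b}):
                ca = sq[(min(a, c), max(a, c))]
                cb = sq[(min(b, c), max(b, c))]
                sq[(c, new)] = 0.5 * ca + 0.5 * cb - 0.25 * sq[(a, b)]
            height = math.sqrt(max(d, 0.0))
        else:
            height = d
        active -= {a, b}
        active.add(new)
        merges.append((a, b, height, len(members[new])))
    return merges
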