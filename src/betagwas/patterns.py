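"""Index-overlap pattern machinery for moments of pairwise-score statistics.

A distance-association score has the form ``S = sum_{i<j} a_ij X_ij`` where
``a_ij`` are fixed weights from a centered distance matrix and ``X_ij`` is a
centered kernel of the two subjects' genotypes (and, for the interaction
score, their environment values).  Because ``X_ij`` and ``X_kl`` are
independent exactly when ``{i,j}`` and ``{k,l}`` are disjoint, the null
moments decompose over the ways the ``2m`` pair endpoints can coincide:

    E[S_1 ... S_m] = 2^{-m} * sum over patterns  count * D(pattern) * M(pattern)

where a *pattern* is a multigraph on a handful of abstract vertices,
``D(pattern)`` sums products of ``a_ij`` over tuples of **distinct** subjects
arranged as the pattern, and ``M(pattern)`` is the expectation of the product
of centered kernels over the pattern's edges under iid Hardy-Weinberg
genotypes.

Patterns are enumerated programmatically, as set partitions of the 2m edge
endpoints, rather than catalogued by hand; any pattern containing a
connected component with a single edge vanishes because the kernels are
centered.  Distinct-vertex sums are evaluated with einsum contractions plus
inclusion-exclusion over vertex coincidences (quotient patterns); quotients
that create a self-loop vanish because the weight matrix has a zero
diagonal.  Vertices may carry a stratum (environment level); a stratified
sum restricts each vertex to subjects of its stratum via indicator vectors
folded into the contraction.
"""

from __future__ import annotations

import string
from functools import lru_cache
from itertools import permutations

import numpy as np
from sympy.utilities.iterables import multiset_partitions

#: edge kinds: main-effect kernel |g_i - g_j| vs interaction kernel |g_i E_i - g_j E_j|
KIND_MAIN = 0
KIND_INTER = 1

__all__ = [
    "KIND_MAIN",
    "KIND_INTER",
    "edge_patterns",
    "pattern_name",
    "DistinctSums",
]


def _n_vertices(edges) -> int:
    return 1 + max(max(u, v) for _, u, v in edges)


def _canonical(edges):
    """Canonical form of a kind-labeled multigraph (min over vertex relabelings)."""
    k = _n_vertices(edges)
    best = None
    for perm in permutations(range(k)):
        cand = tuple(
            sorted((kd, *sorted((perm[u], perm[v]))) for kd, u, v in edges)
        )
        if best is None or cand < best:
            best = cand
    return best


def _canonical_typed(edges, vtypes):
    """Canonical form of an (unlabeled-edge, vertex-typed) multigraph."""
    k = len(vtypes)
    best = None
    for perm in permutations(range(k)):
        e = tuple(sorted(tuple(sorted((perm[u], perm[v]))) for u, v in edges))
        t = [0] * k
        for v in range(k):
            t[perm[v]] = vtypes[v]
        cand = (e, tuple(t))
        if best is None or cand < best:
            best = cand
    return best


def _has_isolated_edge(edges, k) -> bool:
    """True if some connected component of the multigraph has exactly one edge."""
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    n_edges = {}
    for _, u, v in edges:
        r = find(u)
        n_edges[r] = n_edges.get(r, 0) + 1
    return any(c == 1 for c in n_edges.values())


@lru_cache(maxsize=None)
def edge_patterns(kinds: tuple):
    """Enumerate coincidence patterns for the product ``E[S_{k1} ... S_{km}]``.

    Parameters
    ----------
    kinds
        Tuple of edge kinds (KIND_MAIN / KIND_INTER), one per score factor.

    Returns
    -------
    tuple of ``(edges, count)`` where ``edges`` is a canonical tuple of
    ``(kind, u, v)`` triples on contiguous vertices and ``count`` is the
    number of endpoint set-partitions collapsing to that pattern.  Patterns
    whose expectation vanishes by centering (an isolated single edge) are
    omitted.
    """
    m = len(kinds)
    counts: dict = {}
    for part in multiset_partitions(list(range(2 * m))):
        block_of = {}
        for b, blk in enumerate(part):
            for s in blk:
                block_of[s] = b
        if any(block_of[2 * k] == block_of[2 * k + 1] for k in range(m)):
            continue  # a pair of one subject with itself never occurs
        edges = tuple(
            (kinds[k], *sorted((block_of[2 * k], block_of[2 * k + 1])))
            for k in range(m)
        )
        if _has_isolated_edge(edges, len(part)):
            continue
        canon = _canonical(edges)
        counts[canon] = counts.get(canon, 0) + 1
    return tuple(sorted(counts.items()))


_SHAPE_NAMES = {
    # order 2
    ((0, 1), (0, 1)): "pair_squared",
    ((0, 1), (0, 2)): "cherry",
    # order 3
    ((0, 1), (0, 1), (0, 1)): "pair_cubed",
    ((0, 1), (0, 1), (0, 2)): "pair_sq_adjacent",
    ((0, 1), (0, 2), (1, 2)): "triangle",
    ((0, 1), (0, 2), (0, 3)): "star3",
    ((0, 1), (0, 2), (1, 3)): "path3",
}


def pattern_name(untyped_edges) -> str:
    """Human-readable name for an (unlabeled) pattern's shape."""
    canon = _canonical_typed(untyped_edges, (0,) * (1 + max(max(e) for e in untyped_edges)))[0]
    if canon in _SHAPE_NAMES:
        return _SHAPE_NAMES[canon]
    k = 1 + max(max(e) for e in canon)
    mult = sorted(
        (canon.count(e) for e in set(canon)), reverse=True
    )
    tag = "e" + "".join(str(c) for c in mult)
    return f"v{k}_{tag}_" + "_".join(f"{u}{v}" for u, v in canon)


class DistinctSums:
    """Distinct-vertex contraction sums of a symmetric zero-diagonal matrix.

    ``dsum(edges, vtypes)`` returns ``sum over injective vertex->subject
    assignments (vertex v restricted to stratum vtypes[v]) of the product of
    ``A[i, j]`` over the pattern's edges``.  Computed as the unrestricted
    einsum contraction minus quotient contributions (inclusion-exclusion over
    vertex coincidences), memoized on canonical typed patterns.
    """

    def __init__(self, A: np.ndarray, indicators):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be a square matrix")
        self.A = A
        self.indicators = [np.asarray(v, dtype=float) for v in indicators]
        self._memo: dict = {}

    def dsum(self, edges, vtypes) -> float:
        edges = tuple(sorted(tuple(sorted(e)) for e in edges))
        vtypes = tuple(vtypes)
        key = _canonical_typed(edges, vtypes)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        val = self._contract(edges, vtypes)
        k = len(vtypes)
        for part in multiset_partitions(list(range(k))):
            if len(part) == k:
                continue  # identity partition = the distinct sum itself
            if any(len({vtypes[v] for v in blk}) != 1 for blk in part):
                continue  # merging across strata is impossible
            block_of = {}
            for b, blk in enumerate(part):
                for v in blk:
                    block_of[v] = b
            qedges = [(block_of[u], block_of[v]) for u, v in edges]
            if any(u == v for u, v in qedges):
                continue  # self-loop: zero diagonal kills it
            qtypes = tuple(vtypes[blk[0]] for blk in part)
            val -= self.dsum(qedges, qtypes)
        self._memo[key] = val
        return val

    def _contract(self, edges, vtypes) -> float:
        letters = string.ascii_lowercase
        operands, subs = [], []
        for u, v in edges:
            operands.append(self.A)
            subs.append(letters[u] + letters[v])
        for v in range(len(vtypes)):
            operands.append(self.indicators[vtypes[v]])
            subs.append(letters[v])
        return float(np.einsum(",".join(subs) + "->", *operands, optimize=True))
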