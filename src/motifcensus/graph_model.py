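"""Loop-free simple digraph model and small-digraph integer encodings.

The whole package speaks one vocabulary: a :class:`DirectedGraph` is a simple
directed graph without self-loops, in which a reciprocal arc pair
``(u, v), (v, u)`` models one bidirectional edge.  A ``k``-node digraph with an
explicit vertex order is encoded as its *graphID*: the ``k x k`` adjacency
matrix read row-major as a binary number, most significant bit first (entry
``(1, 1)`` is the top bit).  The *canonical ID* of an isomorphism class is the
minimum graphID over all ``k!`` relabelings.  This is the classic
Mfinder/FanMod convention, under which the 3-node feed-forward loop has
canonical ID 38 and the complete triad 238.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from collections.abc import Iterable, Sequence

#: graphID encodings are defined for subgraph sizes in this closed range.
MIN_K = 2
MAX_K = 6


class GraphSizeError(ValueError):
    """Raised when an operation is asked for a node count it does not support."""


class MalformedGraphIDError(ValueError):
    """Raised for integer encodings that cannot be a loop-free digraph."""


class DirectedGraph:
    """A mutable loop-free simple digraph on vertices ``0 .. n_nodes-1``.

    Adjacency is stored both forward and backward so arc membership, successor
    and predecessor queries are O(1)/O(degree).  Parallel arcs are impossible
    (arcs form a set); self-loops are rejected.
    """

    __slots__ = ("n_nodes", "_succ", "_pred", "_n_arcs")

    def __init__(self, n_nodes: int, arcs: Iterable[tuple[int, int]] = ()):
        if n_nodes < 0:
            raise ValueError("n_nodes must be non-negative")
        self.n_nodes = n_nodes
        self._succ: list[set[int]] = [set() for _ in range(n_nodes)]
        self._pred: list[set[int]] = [set() for _ in range(n_nodes)]
        self._n_arcs = 0
        for u, v in arcs:
            self.add_arc(u, v)

    # -- mutation ---------------------------------------------------------

    def add_arc(self, u: int, v: int) -> None:
        if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
            raise ValueError(f"arc ({u}, {v}) out of range for {self.n_nodes} nodes")
        if u == v:
            raise ValueError(f"self-loop ({u}, {u}) not allowed")
        if v not in self._succ[u]:
            self._succ[u].add(v)
            self._pred[v].add(u)
            self._n_arcs += 1

    def remove_arc(self, u: int, v: int) -> None:
        if v not in self._succ[u]:
            raise KeyError(f"arc ({u}, {v}) not present")
        self._succ[u].remove(v)
        self._pred[v].remove(u)
        self._n_arcs -= 1

    # -- queries ----------------------------------------------------------

    def has_arc(self, u: int, v: int) -> bool:
        return v in self._succ[u]

    def successors(self, u: int) -> frozenset[int]:
        return frozenset(self._succ[u])

    def predecessors(self, u: int) -> frozenset[int]:
        return frozenset(self._pred[u])

    def out_degree(self, u: int) -> int:
        return len(self._succ[u])

    def in_degree(self, u: int) -> int:
        return len(self._pred[u])

    def undirected_neighbors(self, u: int) -> set[int]:
        """Neighbors when arc direction is forgotten."""
        return self._succ[u] | self._pred[u]

    @property
    def n_arcs(self) -> int:
        return self._n_arcs

    @property
    def arcs(self) -> set[tuple[int, int]]:
        return {(u, v) for u in range(self.n_nodes) for v in self._succ[u]}

    def iter_arcs(self) -> Iterable[tuple[int, int]]:
        for u in range(self.n_nodes):
            for v in self._succ[u]:
                yield (u, v)

    def copy(self) -> "DirectedGraph":
        g = DirectedGraph(self.n_nodes)
        for u in range(self.n_nodes):
            g._succ[u] = set(self._succ[u])
            g._pred[u] = set(self._pred[u])
        g._n_arcs = self._n_arcs
        return g

    def induced_subgraph(self, vertices: Sequence[int]) -> "DirectedGraph":
        """Induced subgraph on ``vertices``, relabeled by position."""
        index = {v: i for i, v in enumerate(vertices)}
        sub = DirectedGraph(len(vertices))
        for v in vertices:
            i = index[v]
            for w in self._succ[v]:
                j = index.get(w)
                if j is not None:
                    sub.add_arc(i, j)
        return sub

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return self.n_nodes == other.n_nodes and self._succ == other._succ

    def __hash__(self):
        raise TypeError("DirectedGraph is mutable and unhashable")

    def __repr__(self) -> str:
        return f"DirectedGraph(n_nodes={self.n_nodes}, arcs={sorted(self.arcs)!r})"


# -- graphID codec --------------------------------------------------------


def _check_k(k: int) -> None:
    if not MIN_K <= k <= MAX_K:
        raise GraphSizeError(f"graphIDs are defined for {MIN_K} <= k <= {MAX_K}, got {k}")


def graph_id(g: DirectedGraph, order: Sequence[int] | None = None) -> int:
    """Encode ``g`` (restricted to ``order``) as its row-major adjacency integer.

    ``order`` defaults to ``0 .. n_nodes-1``.  The bit for matrix entry
    ``(i, j)`` (1-based positions within ``order``) has weight
    ``2**(k*k - 1 - (k*(i-1) + (j-1)))``; diagonal bits are always zero.
    """
    verts = range(g.n_nodes) if order is None else order
    k = len(verts)
    _check_k(k)
    value = 0
    for u in verts:
        for v in verts:
            value = (value << 1) | (1 if u != v and g.has_arc(u, v) else 0)
    return value


def decode_graph_id(gid: int, k: int) -> DirectedGraph:
    """Inverse of :func:`graph_id` on vertex order ``0 .. k-1``."""
    _check_k(k)
    if not 0 <= gid < 1 << (k * k):
        raise MalformedGraphIDError(f"id {gid} out of range for k={k}")
    g = DirectedGraph(k)
    for i in range(k):
        for j in range(k):
            if (gid >> (k * k - 1 - (k * i + j))) & 1:
                if i == j:
                    raise MalformedGraphIDError(f"id {gid} has diagonal bit ({i},{i}) set")
                g.add_arc(i, j)
    return g


def relabel_graph_id(gid: int, k: int, perm: Sequence[int]) -> int:
    """graphID of the graph with vertex ``i`` renamed to ``perm[i]``."""
    out = 0
    kk = k * k
    for i in range(k):
        for j in range(k):
            if i != j and (gid >> (kk - 1 - (k * i + j))) & 1:
                out |= 1 << (kk - 1 - (k * perm[i] + perm[j]))
    return out


def canonical_id_bruteforce(gid: int, k: int) -> int:
    """Minimum graphID over all ``k!`` relabelings (exhaustive search).

    Idempotent and constant on isomorphism classes; the workhorse oracle that
    the table- and deck-based classifiers are checked against.
    """
    decode_graph_id(gid, k)  # validates range and diagonal bits
    return min(relabel_graph_id(gid, k, perm) for perm in itertools.permutations(range(k)))


# -- isomorphism and connectivity -----------------------------------------


def _degree_signature(g: DirectedGraph) -> Counter:
    return Counter((g.out_degree(v), g.in_degree(v)) for v in range(g.n_nodes))


def is_isomorphic(g1: DirectedGraph, g2: DirectedGraph) -> bool:
    """Exact isomorphism test by pruned permutation search.

    A mismatch in node count or in the multiset of (out-degree, in-degree)
    pairs short-circuits to ``False`` before any permutation is tried.
    """
    n = g1.n_nodes
    if n != g2.n_nodes or g1.n_arcs != g2.n_arcs:
        return False
    if _degree_signature(g1) != _degree_signature(g2):
        return False
    deg1 = [(g1.out_degree(v), g1.in_degree(v)) for v in range(n)]
    deg2 = [(g2.out_degree(v), g2.in_degree(v)) for v in range(n)]
    arcs1 = g1.arcs
    for perm in itertools.permutations(range(n)):
        if any(deg1[i] != deg2[perm[i]] for i in range(n)):
            continue
        if all(g2.has_arc(perm[u], perm[v]) for (u, v) in arcs1):
            return True
    return False


def is_weakly_connected(g: DirectedGraph) -> bool:
    """True iff the underlying undirected graph is connected (single node: True)."""
    n = g.n_nodes
    if n <= 1:
        return True
    seen = bytearray(n)
    seen[0] = 1
    queue = deque([0])
    count = 1
    while queue:
        v = queue.popleft()
        for w in g.undirected_neighbors(v):
            if not seen[w]:
                seen[w] = 1
                count += 1
                queue.append(w)
    return count == n
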