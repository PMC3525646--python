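"""Exhaustive enumeration and classification of connected induced subgraphs.

Enumeration follows the rooted composition scheme popularized by Kavosh: for
each root vertex ``v`` (in ascending label order), the remaining ``k - 1``
vertices of a subgraph are drawn from successive neighborhood levels of the
already-selected vertices, considering only vertices with labels greater than
the root (so each vertex subset is produced exactly once, rooted at its
minimum label).  Candidates of a level are marked visited before the level's
subsets are explored and unmarked afterwards, which is what prevents a vertex
reachable at level ``i`` from reappearing at a deeper level.  Adjacency is
undirected for enumeration purposes — the census counts *weakly* connected
induced subgraphs, and distinct copies may overlap.

Classification of each enumerated subgraph goes through the pretreatment
canonical table for ``k <= 5`` and through deck labeling for ``k = 6``.  A
deliberately naive :func:`census_bruteforce` (iterate all C(n, k) subsets,
filter by connectivity, canonicalize by exhaustive relabeling) provides the
ground truth that both fast paths are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterator

import numpy as np

from . import canon_tables
from .deck_labeling import SubgraphList
from .graph_model import (
    DirectedGraph,
    GraphSizeError,
    is_weakly_connected,
)

_CENSUS_KS = (3, 4, 5, 6)


@dataclass
class CensusResult:
    """Per-class counts of connected induced ``k``-subgraphs of one graph.

    For ``k <= 5`` keys are canonical graphIDs; for ``k = 6`` keys are the
    graphIDs of the stored (first-encountered, not necessarily canonical)
    representatives.  ``total`` is the number of connected ``k``-subgraphs,
    which equals the sum of the counts for a full census.
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)
    total: int = 0
    subgraph_list: SubgraphList | None = None
    representatives: dict[int, DirectedGraph] = field(default_factory=dict)


def enumerate_connected_subgraphs(g: DirectedGraph, k: int) -> Iterator[tuple[int, ...]]:
    """Yield each weakly connected induced ``k``-subset exactly once.

    Subsets are emitted as sorted vertex tuples in a deterministic order
    (roots ascending; within a root, level compositions by increasing level
    size and candidate combinations lexicographically).  ``k > n`` yields
    nothing.
    """
    n = g.n_nodes
    if k < 1 or k > n:
        return
    adj = [sorted(g.undirected_neighbors(v)) for v in range(n)]
    visited = bytearray(n)
    sel: list[int] = []

    def extend(frontier: tuple[int, ...], remainder: int, root: int) -> Iterator[tuple[int, ...]]:
        if remainder == 0:
            yield tuple(sorted(sel))
            return
        cand: list[int] = []
        for v in frontier:
            for w in adj[v]:
                if w > root and not visited[w]:
                    visited[w] = 1
                    cand.append(w)
        for size in range(1, min(len(cand), remainder) + 1):
            for combo in combinations(cand, size):
                sel.extend(combo)
                yield from extend(combo, remainder - size, root)
                del sel[len(sel) - size:]
        for w in cand:
            visited[w] = 0

    for root in range(n):
        sel = [root]
        yield from extend((root,), k - 1, root)


class CensusEngine:
    """Reusable census machinery for a fixed subgraph size ``k``.

    Building the engine triggers the pretreatment phase (the ``k`` table for
    ``k <= 5``, the ``k = 5`` table for deck labeling at ``k = 6``); the same
    engine then serves the input network and every comparison graph, and is
    safe to share across census worker threads (tables are read-only and all
    per-census state is local).
    """

    def __init__(self, k: int, cache: bool = True):
        if k not in _CENSUS_KS:
            raise GraphSizeError(f"census supports k in {_CENSUS_KS}, got {k}")
        self.k = k
        self.table = canon_tables.build_canon_table(min(k, 5), cache=cache)
        self._unpack_memo: dict[int, int] = {}

    # -- packed encoding of one induced subgraph --------------------------

    def _packed_id(self, g: DirectedGraph, verts: tuple[int, ...]) -> int:
        packed = 0
        for u in verts:
            for v in verts:
                if u != v:
                    packed <<= 1
                    if g.has_arc(u, v):
                        packed |= 1
        return packed

    def _canonical_full(self, packed: int) -> int:
        canon_packed = self.table.lookup_packed(packed)
        full = self._unpack_memo.get(canon_packed)
        if full is None:
            full = canon_tables.unpack_offdiag(canon_packed, self.k)
            self._unpack_memo[canon_packed] = full
        return full

    # -- stage 1: the input network ---------------------------------------

    def census_input(self, g: DirectedGraph) -> CensusResult:
        result = CensusResult(self.k)
        if self.k <= 5:
            counts = result.counts
            for verts in enumerate_connected_subgraphs(g, self.k):
                key = self._canonical_full(self._packed_id(g, verts))
                counts[key] = counts.get(key, 0) + 1
                result.total += 1
        else:
            slist = SubgraphList()
            for verts in enumerate_connected_subgraphs(g, self.k):
                slist.classify_stage1(g.induced_subgraph(verts), self.table)
                result.total += 1
            result.subgraph_list = slist
            for entry in slist.entries():
                result.counts[entry.key] = entry.count
                result.representatives[entry.key] = entry.representative
        return result

    # -- stage 2: comparison graphs ---------------------------------------

    def census_comparison(self, g: DirectedGraph, base: CensusResult) -> tuple[dict[int, int], int]:
        """Counts of the input network's classes in one comparison graph.

        Returns ``(counts keyed like base.counts, total connected
        k-subgraphs)``.  Classes absent from the input network are dropped
        ("do nothing"), matching the frozen stage-2 list protocol; classes
        absent from the comparison graph report zero.
        """
        counts = dict.fromkeys(base.counts, 0)
        total = 0
        if self.k <= 5:
            for verts in enumerate_connected_subgraphs(g, self.k):
                total += 1
                key = self._canonical_full(self._packed_id(g, verts))
                if key in counts:
                    counts[key] += 1
        else:
            slist = base.subgraph_list
            assert slist is not None, "census_input must run before census_comparison"
            for verts in enumerate_connected_subgraphs(g, self.k):
                total += 1
                entry = slist.classify_stage2(g.induced_subgraph(verts), self.table)
                if entry is not None:
                    counts[entry.key] += 1
        return counts, total


def census(g: DirectedGraph, k: int, cache: bool = True) -> CensusResult:
    """One-shot census of ``g`` at size ``k`` (stage-1 semantics)."""
    return CensusEngine(k, cache=cache).census_input(g)


def census_bruteforce(g: DirectedGraph, k: int, max_nodes: int = 16) -> CensusResult:
    """Ground-truth census: all subsets, connectivity filter, exhaustive labels.

    Classifies every connected subset by the minimum graphID over all ``k!``
    relabelings (vectorized over the distinct subgraph encodings seen), fully
    independent of the canonical tables and of deck classification.  Guarded
    to small graphs — cost grows as C(n, k).
    """
    if g.n_nodes > max_nodes:
        raise ValueError(f"census_bruteforce is limited to n <= {max_nodes} nodes")
    if k not in _CENSUS_KS:
        raise GraphSizeError(f"census supports k in {_CENSUS_KS}, got {k}")
    result = CensusResult(k)
    packed_ids: list[int] = []
    pos = canon_tables._positions(k, True)
    nb = len(pos)
    for verts in combinations(range(g.n_nodes), k):
        sub = g.induced_subgraph(verts)
        if not is_weakly_connected(sub):
            continue
        packed = 0
        for t, (i, j) in enumerate(pos):
            if sub.has_arc(i, j):
                packed |= 1 << (nb - 1 - t)
        packed_ids.append(packed)
    result.total = len(packed_ids)
    if packed_ids:
        unique, inverse = np.unique(np.array(packed_ids, dtype=np.uint64), return_inverse=True)
        canon = canon_tables.canonical_ids_exhaustive(unique, k, directed=True)
        for c in canon[inverse]:
            key = canon_tables.unpack_offdiag(int(c), k)
            result.counts[key] = result.counts.get(key, 0) + 1
    return result


def complete_graph_count(n: int, k: int) -> int:
    """Closed-form subgraph count for the complete digraph: C(n, k)."""
    return comb(n, k)
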