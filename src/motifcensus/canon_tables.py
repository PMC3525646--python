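"""Pretreatment phase: in-memory canonical-label tables for small digraphs.

Instead of calling an isomorphism package once per subgraph encountered, the
census precomputes the canonical ID of *every* loop-free ``k``-node digraph
(``k <= 5``) in one vectorized pass and then classifies subgraphs with a
single array lookup.  Tables are indexed by the ``k*(k-1)`` off-diagonal bits
of the graphID (diagonal bits are always zero, so storing them would double
memory for nothing); the packed order preserves the numeric order of full
graphIDs, so the minimum packed ID in an orbit unpacks to the minimum graphID.

The table is built by an orbit fixpoint iteration rather than a per-entry
``k!`` minimization: adjacent vertex transpositions generate the symmetric
group, each transposition induces a bit permutation of the packed index space,
and repeatedly assigning ``canon[x] = min(canon[x], canon[t(x)])`` over the
generators converges to the orbit minimum.  The ``k = 5`` table (2^20
entries) builds in seconds this way.

The same machinery enumerates isomorphism classes of weakly connected graphs,
directed and undirected (undirected graphs are encoded as symmetric
digraphs).  Sizes beyond the table range use isomorph-free growth: every
connected graph has a non-cut vertex, so every connected ``k``-class arises by
attaching one new vertex (with some nonempty neighborhood) to a connected
``(k-1)``-class; canonicalizing and deduplicating the candidates is exhaustive.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .graph_model import (
    DirectedGraph,
    GraphSizeError,
    MalformedGraphIDError,
    is_weakly_connected,
)

_CACHE_VERSION = 1
_TABLE_KS = (3, 4, 5)

# in-process cache: k -> CanonTable
_TABLES: dict[int, "CanonTable"] = {}


@lru_cache(maxsize=None)
def _positions(k: int, directed: bool) -> list[tuple[int, int]]:
    """Bit positions (vertex pairs) of the packed encoding, MSB first."""
    if directed:
        return [(i, j) for i in range(k) for j in range(k) if i != j]
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


@lru_cache(maxsize=None)
def _pos_index(k: int, directed: bool) -> dict[tuple[int, int], int]:
    return {p: t for t, p in enumerate(_positions(k, directed))}


def pack_offdiag(gid: int, k: int) -> int:
    """Compress a full k*k-bit graphID to its k*(k-1) off-diagonal bits."""
    pos = _positions(k, True)
    nb = len(pos)
    kk = k * k
    out = 0
    for t, (i, j) in enumerate(pos):
        if (gid >> (kk - 1 - (k * i + j))) & 1:
            out |= 1 << (nb - 1 - t)
    return out


def unpack_offdiag(packed: int, k: int) -> int:
    """Inverse of :func:`pack_offdiag`."""
    pos = _positions(k, True)
    nb = len(pos)
    kk = k * k
    out = 0
    for t, (i, j) in enumerate(pos):
        if (packed >> (nb - 1 - t)) & 1:
            out |= 1 << (kk - 1 - (k * i + j))
    return out


def _perm_bit_moves(k: int, perm, directed: bool) -> list[tuple[int, int]]:
    """(source shift, destination shift) pairs realizing one vertex relabeling."""
    pos = _positions(k, directed)
    index = _pos_index(k, directed)
    nb = len(pos)
    moves = []
    for t, (i, j) in enumerate(pos):
        a, b = perm[i], perm[j]
        if not directed and a > b:
            a, b = b, a
        t2 = index[(a, b)]
        moves.append((nb - 1 - t, nb - 1 - t2))
    return moves


def _compile_moves(moves) -> list[tuple[int, int]]:
    """Group bit moves by shift distance so one shift handles many bits."""
    masks: dict[int, int] = {}
    for src, dst in moves:
        masks[src - dst] = masks.get(src - dst, 0) | (1 << dst)
    return sorted(masks.items())


@lru_cache(maxsize=None)
def _all_compiled_moves(k: int, directed: bool) -> list[list[tuple[int, int]]]:
    """Compiled bit moves for every permutation of S_k, identity first."""
    return [_compile_moves(_perm_bit_moves(k, perm, directed))
            for perm in itertools.permutations(range(k))]


def _apply_perm_vec(ids: np.ndarray, compiled) -> np.ndarray:
    out = np.zeros_like(ids)
    for delta, mask in compiled:
        if delta >= 0:
            out |= (ids >> delta) & mask
        else:
            out |= (ids << -delta) & mask
    return out


def _orbit_minimum_full_space(k: int, directed: bool) -> np.ndarray:
    """Canonical (orbit-minimum) packed ID for every packed ID, as one array."""
    nb = len(_positions(k, directed))
    n_ids = 1 << nb
    ids = np.arange(n_ids, dtype=np.uint32)
    gen_maps = []
    for t in range(k - 1):
        perm = list(range(k))
        perm[t], perm[t + 1] = perm[t + 1], perm[t]
        gen_maps.append(
            _apply_perm_vec(ids, _compile_moves(_perm_bit_moves(k, perm, directed))))
    canon = ids.copy()
    changed = True
    while changed:
        changed = False
        for pmap in gen_maps:
            new = np.minimum(canon, canon[pmap])
            if not np.array_equal(new, canon):
                canon = new
                changed = True
    return canon


def canonical_ids_exhaustive(ids: np.ndarray, k: int, directed: bool = True,
                             chunk: int = 1 << 21) -> np.ndarray:
    """Vectorized exhaustive canonicalization: min over all ``k!`` relabelings.

    Independent of both the orbit-fixpoint table build and the deck
    classifier; serves as the mid-scale oracle and as the canonicalizer for
    growth-based class enumeration.
    """
    ids = np.ascontiguousarray(ids, dtype=np.uint64)
    all_moves = _all_compiled_moves(k, directed)
    out = np.empty_like(ids)
    for lo in range(0, len(ids), chunk):
        block = ids[lo:lo + chunk]
        best = block.copy()
        for compiled in all_moves[1:]:  # identity already in `best`
            np.minimum(best, _apply_perm_vec(block, compiled), out=best)
        out[lo:lo + chunk] = best
    return out


def _packed_is_connected(packed: int, k: int, directed: bool) -> bool:
    pos = _positions(k, directed)
    nb = len(pos)
    g = DirectedGraph(k)
    for t, (i, j) in enumerate(pos):
        if (packed >> (nb - 1 - t)) & 1:
            g.add_arc(i, j)
            if not directed:
                g.add_arc(j, i)
    return is_weakly_connected(g)


def _sym_full_id(packed: int, k: int) -> int:
    """Symmetric-digraph graphID of an undirected packed (triangle) encoding."""
    pos = _positions(k, False)
    nb = len(pos)
    kk = k * k
    out = 0
    for t, (i, j) in enumerate(pos):
        if (packed >> (nb - 1 - t)) & 1:
            out |= 1 << (kk - 1 - (k * i + j))
            out |= 1 << (kk - 1 - (k * j + i))
    return out


@dataclass(frozen=True)
class CanonTable:
    """Flat canonical-label map for all loop-free ``k``-node digraphs.

    ``labels[p]`` is the packed canonical ID of the digraph with packed
    off-diagonal encoding ``p``; length ``2**(k*(k-1))``.
    """

    k: int
    labels: np.ndarray

    def lookup_packed(self, packed: int) -> int:
        return int(self.labels[packed])

    def lookup(self, gid: int) -> int:
        """Canonical full graphID of ``gid``; O(1) after the build."""
        if not 0 <= gid < 1 << (self.k * self.k):
            raise MalformedGraphIDError(f"id {gid} out of range for k={self.k}")
        kk = self.k * self.k
        for i in range(self.k):
            if (gid >> (kk - 1 - (self.k * i + i))) & 1:
                raise MalformedGraphIDError(f"id {gid} has a diagonal bit set")
        return unpack_offdiag(int(self.labels[pack_offdiag(gid, self.k)]), self.k)


def _cache_dir() -> Path:
    env = os.environ.get("MOTIFCENSUS_CACHE")
    if env:
        return Path(env)
    return Path(os.environ.get("XDG_CACHE_HOME", Path.home() / ".cache")) / "motifcensus"


def lookup(table: CanonTable, gid: int) -> int:
    """Module-level alias for :meth:`CanonTable.lookup`."""
    return table.lookup(gid)


def build_canon_table(k: int, cache: bool = True) -> CanonTable:
    """Build (or load) the canonical-label table for ``k`` in 3..5.

    The one-off pretreatment cost is amortized: tables live in a process-level
    cache and, when ``cache`` is true, in a versioned ``.npy`` file under the
    user cache directory.  ``k = 6`` is deliberately unsupported — a full
    table would need 2^30 entries; 6-node subgraphs are classified through
    their 5-node decks instead (see :mod:`motifcensus.deck_labeling`).
    """
    if k == 6:
        raise GraphSizeError(
            "no full canonical table for k=6; use deck_labeling (5-node cards)")
    if k not in _TABLE_KS:
        raise GraphSizeError(f"canonical tables support k in {_TABLE_KS}, got {k}")
    if k in _TABLES:
        return _TABLES[k]
    path = _cache_dir() / f"canon_k{k}_v{_CACHE_VERSION}.npy"
    labels = None
    if cache and path.is_file():
        try:
            arr = np.load(path)
            if arr.shape == (1 << (k * (k - 1)),) and arr.dtype == np.uint32:
                labels = arr
        except Exception:
            labels = None
    if labels is None:
        labels = _orbit_minimum_full_space(k, directed=True)
        if cache:
            try:
                path.parent.mkdir(parents=True, exist_ok=True)
                np.save(path, labels)
            except OSError:
                pass  # cache is an optimization, never a requirement
    table = CanonTable(k, labels)
    _TABLES[k] = table
    return table


def class_catalog(table: CanonTable) -> list[tuple[int, bool, int]]:
    """(canonical full graphID, is_connected, class size) for every class."""
    values, counts = np.unique(table.labels, return_counts=True)
    out = []
    for packed, size in zip(values.tolist(), counts.tolist()):
        out.append((unpack_offdiag(packed, table.k),
                    _packed_is_connected(packed, table.k, True),
                    size))
    return out


def _grow_connected_classes(k: int, directed: bool) -> np.ndarray:
    """Packed canonical IDs of connected ``k``-classes by one-vertex growth."""
    _, parent_reps = enumerate_connected_classes(k - 1, directed=directed)
    # re-pack parents (returned as full/symmetric IDs) into (k-1) packed form,
    # then remap their bits onto vertices 0..k-2 of the k-node encoding
    idx_k = _pos_index(k, directed)
    pos_parent = _positions(k - 1, directed)
    nb_parent = len(pos_parent)
    nb_k = len(_positions(k, directed))
    base = np.zeros(len(parent_reps), dtype=np.uint64)
    parents_packed = np.array(
        [_repack_parent(rep, k - 1, directed) for rep in parent_reps], dtype=np.uint64)
    for t, (i, j) in enumerate(pos_parent):
        src = nb_parent - 1 - t
        dst = nb_k - 1 - idx_k[(i, j)]
        base |= ((parents_packed >> np.uint64(src)) & np.uint64(1)) << np.uint64(dst)
    # every nonempty attachment of the new vertex k-1 to the old vertices
    masks = []
    if directed:
        for code in range(1, 4 ** (k - 1)):
            m, c = 0, code
            for j in range(k - 1):
                c, r = divmod(c, 4)
                if r & 1:
                    m |= 1 << (nb_k - 1 - idx_k[(k - 1, j)])
                if r & 2:
                    m |= 1 << (nb_k - 1 - idx_k[(j, k - 1)])
            masks.append(m)
    else:
        for code in range(1, 1 << (k - 1)):
            m = 0
            for j in range(k - 1):
                if (code >> j) & 1:
                    m |= 1 << (nb_k - 1 - idx_k[(j, k - 1)])
            masks.append(m)
    masks_arr = np.array(masks, dtype=np.uint64)
    candidates = (base[:, None] | masks_arr[None, :]).ravel()
    canon = canonical_ids_exhaustive(candidates, k, directed=directed)
    return np.unique(canon)


def _repack_parent(rep: int, k: int, directed: bool) -> int:
    """Packed encoding of a class representative returned by the enumerator."""
    if directed:
        return pack_offdiag(rep, k)
    # undirected reps are symmetric-digraph IDs; keep the upper triangle
    pos = _positions(k, False)
    nb = len(pos)
    kk = k * k
    out = 0
    for t, (i, j) in enumerate(pos):
        if (rep >> (kk - 1 - (k * i + j))) & 1:
            out |= 1 << (nb - 1 - t)
    return out


def enumerate_connected_classes(k: int, directed: bool = True) -> tuple[int, list[int]]:
    """Count (and list) isomorphism classes of weakly connected graphs.

    Directed graphs are supported for ``3 <= k <= 6`` and undirected for
    ``3 <= k <= 7``; class representatives are returned as graphIDs
    (symmetric-digraph graphIDs in the undirected case).  ``k <= 5`` directed
    uses the pretreatment table, ``k <= 6`` undirected an exhaustive orbit
    fixpoint over all labeled graphs, and the largest size of each kind the
    growth construction.  Directed ``k = 6`` enumerates all 1.5M classes and
    takes many minutes; it is meant for one-off verification scripts.
    """
    if directed:
        if k in _TABLE_KS:
            packed = np.unique(build_canon_table(k).labels)
            reps = [unpack_offdiag(int(p), k) for p in packed
                    if _packed_is_connected(int(p), k, True)]
            return len(reps), reps
        if k == 6:
            packed = _grow_connected_classes(k, directed=True)
            kk_pos = _positions(k, True)
            nb = len(kk_pos)
            reps = [_unpack_generic(int(p), k, nb, kk_pos, sym=False) for p in packed]
            return len(reps), reps
        raise GraphSizeError(f"directed class enumeration supports 3 <= k <= 6, got {k}")
    if 3 <= k <= 6:
        canon = _orbit_minimum_full_space(k, directed=False)
        packed = np.unique(canon)
        reps = [_sym_full_id(int(p), k) for p in packed
                if _packed_is_connected(int(p), k, False)]
        return len(reps), reps
    if k == 7:
        packed = _grow_connected_classes(k, directed=False)
        reps = [_sym_full_id(int(p), k) for p in packed]
        return len(reps), reps
    raise GraphSizeError(f"undirected class enumeration supports 3 <= k <= 7, got {k}")


def _unpack_generic(packed: int, k: int, nb: int, pos, sym: bool) -> int:
    kk = k * k
    out = 0
    for t, (i, j) in enumerate(pos):
        if (packed >> (nb - 1 - t)) & 1:
            out |= 1 << (kk - 1 - (k * i + j))
            if sym:
                out |= 1 << (kk - 1 - (k * j + i))
    return out
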