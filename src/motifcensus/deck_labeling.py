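"""Classify 6-node subgraphs through their decks of 5-node cards.

A full canonical table for 6-node digraphs (2^30 entries) is impractical, so
6-node subgraphs are classified indirectly: delete each vertex in turn, look
up the canonical ID of the resulting 5-node *card* in the pretreatment table,
and sort the six card IDs into the *deck*.  Isomorphic graphs always have
equal decks; the converse holds for loop-free 6-node digraphs up to a handful
of exceptional pairs.  Rather than hard-coding that exception list, equal
decks trigger an explicit isomorphism test against the stored representative,
which makes classification unconditionally correct — an exceptional pair
merely costs one extra comparison.

Classification is organized as a two-stage list protocol.  Stage 1 processes
the input network: each newly seen class inserts an entry storing the first
subgraph encountered verbatim (not necessarily in canonical form).  Stage 2
processes comparison graphs with the list frozen: subgraphs whose class never
appeared in the input network are silently ignored, so only classes present
in the input are ever reported.  Entries live in hash buckets keyed by a
64-bit mix of the deck; within a bucket, candidates are compared deck-first,
then by isomorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .canon_tables import CanonTable, _pos_index, _positions, unpack_offdiag
from .graph_model import DirectedGraph, GraphSizeError, graph_id, is_isomorphic

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1

# bit-move tables: for each deleted vertex, (src shift in the 30-bit 6-node
# packed id, dst shift in the 20-bit 5-node packed id) for every card bit
_IDX6 = _pos_index(6, True)
_POS5 = _positions(5, True)
_CARD_MOVES: list[list[tuple[int, int]]] = []
for _d in range(6):
    _rem = [v for v in range(6) if v != _d]
    _CARD_MOVES.append(
        [(29 - _IDX6[(_rem[a], _rem[b])], 19 - t) for t, (a, b) in enumerate(_POS5)]
    )


# memo: packed 5-node canonical id -> full canonical graphID
_UNPACK5: dict[int, int] = {}


def compute_deck(g: DirectedGraph, table5: CanonTable) -> tuple[int, ...]:
    """Sorted 6-tuple of canonical card graphIDs.

    Invariant under relabeling of ``g``: each card is canonicalized through
    the k=5 table, and sorting removes the dependence on deletion order.
    """
    if g.n_nodes != 6:
        raise GraphSizeError(f"decks are defined for 6-node graphs, got {g.n_nodes}")
    packed = 0
    for t, (i, j) in enumerate(_positions(6, True)):
        if g.has_arc(i, j):
            packed |= 1 << (29 - t)
    cards = []
    for moves in _CARD_MOVES:
        card = 0
        for src, dst in moves:
            card |= ((packed >> src) & 1) << dst
        canon_packed = table5.lookup_packed(card)
        full = _UNPACK5.get(canon_packed)
        if full is None:
            full = _UNPACK5[canon_packed] = unpack_offdiag(canon_packed, 5)
        cards.append(full)
    cards.sort()
    return tuple(cards)


def deck_hash(deck: tuple[int, ...]) -> int:
    """Deterministic 64-bit FNV-1a mix of the sorted card tuple.

    Stable across runs and platforms; collisions between distinct decks are
    permitted and resolved by full deck comparison downstream.
    """
    h = _FNV_OFFSET
    for card in deck:
        for _ in range(4):  # card graphIDs are < 2^25, so 4 bytes suffice
            h ^= card & 0xFF
            h = (h * _FNV_PRIME) & _MASK64
            card >>= 8
    return h


@dataclass
class SubgraphEntry:
    """One isomorphism class observed in the input network."""

    representative: DirectedGraph  # first subgraph encountered, stored verbatim
    deck: tuple[int, ...]
    key: int  # graphID of the representative; reporting/count key
    count: int = 0


@dataclass
class SubgraphList:
    """Hash-bucketed list of the 6-node classes found in the input network."""

    buckets: dict[int, list[SubgraphEntry]] = field(default_factory=dict)

    def entries(self) -> list[SubgraphEntry]:
        return [e for bucket in self.buckets.values() for e in bucket]

    def _find(self, g: DirectedGraph, deck: tuple[int, ...]) -> SubgraphEntry | None:
        bucket = self.buckets.get(deck_hash(deck))
        if not bucket:
            return None
        for entry in bucket:
            if entry.deck == deck and is_isomorphic(g, entry.representative):
                return entry
        return None

    def classify_stage1(self, g: DirectedGraph, table5: CanonTable) -> SubgraphEntry:
        """Count ``g`` in the input network, inserting a new entry if needed."""
        deck = compute_deck(g, table5)
        entry = self._find(g, deck)
        if entry is None:
            rep = g.copy()
            entry = SubgraphEntry(representative=rep, deck=deck, key=graph_id(rep))
            self.buckets.setdefault(deck_hash(deck), []).append(entry)
        entry.count += 1
        return entry

    def classify_stage2(self, g: DirectedGraph, table5: CanonTable) -> SubgraphEntry | None:
        """Match ``g`` against the frozen list; unseen classes are ignored."""
        return self._find(g, compute_deck(g, table5))
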