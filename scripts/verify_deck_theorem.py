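"""Exhaustive deck-collision survey over all loop-free 6-node digraphs.

Long-running verification script (tens of minutes on one core; not part of
the test suite).  It enumerates every isomorphism class of loop-free 6-node
digraphs — the 1,530,843 weakly connected classes by one-vertex growth from
the 9,364 connected 5-node classes, plus the 10,101 disconnected classes by
block-diagonal composition of smaller connected classes — computes the deck
(sorted multiset of canonical 5-node vertex-deleted cards) of one
representative per class, and reports every pair of distinct classes sharing
a deck.  Those pairs are exactly the cases in which deck-based classification
of 6-node subgraphs needs its explicit isomorphism fallback.

Usage:  python scripts/verify_deck_theorem.py [--out FILE]
"""

from __future__ import annotations

import argparse
import itertools
import sys
import time

import numpy as np

from motifcensus import canon_tables as ct
from motifcensus.graph_model import DirectedGraph, graph_id, decode_graph_id


def connected_classes_by_size() -> dict[int, list[DirectedGraph]]:
    by_size: dict[int, list[DirectedGraph]] = {
        1: [DirectedGraph(1)],
        2: [DirectedGraph(2, [(0, 1)]), DirectedGraph(2, [(0, 1), (1, 0)])],
    }
    for k in (3, 4, 5):
        _, reps = ct.enumerate_connected_classes(k, directed=True)
        by_size[k] = [decode_graph_id(r, k) for r in reps]
    return by_size


def partitions(n: int, max_part: int) -> list[list[int]]:
    if n == 0:
        return [[]]
    out = []
    for p in range(min(n, max_part), 0, -1):
        for rest in partitions(n - p, p):
            out.append([p] + rest)
    return out


def disconnected_reps_packed(by_size) -> np.ndarray:
    """One representative (packed 6-node id) per disconnected 6-node class."""
    reps = []
    for parts in partitions(6, 5):  # max part 5 excludes the connected case
        # group equal part sizes; choose a multiset of classes per group
        groups = [(s, sum(1 for q in parts if q == s)) for s in sorted(set(parts), reverse=True)]
        pools = [list(itertools.combinations_with_replacement(range(len(by_size[s])), c))
                 for s, c in groups]
        for choice in itertools.product(*pools):
            g = DirectedGraph(6)
            offset = 0
            for (s, _c), picks in zip(groups, choice):
                for idx in picks:
                    comp = by_size[s][idx]
                    for (u, v) in comp.iter_arcs():
                        g.add_arc(offset + u, offset + v)
                    offset += s
            reps.append(ct.pack_offdiag(graph_id(g), 6))
    return np.array(reps, dtype=np.uint64)


def decks_vectorized(packed6: np.ndarray, table5: ct.CanonTable) -> np.ndarray:
    """Sorted decks (N, 6) of canonical 5-node card IDs, packed encoding."""
    idx6 = ct._pos_index(6, True)
    pos5 = ct._positions(5, True)
    cards = np.empty((len(packed6), 6), dtype=np.uint32)
    for d in range(6):
        rem = [v for v in range(6) if v != d]
        moves = []
        for t5, (a, b) in enumerate(pos5):
            src = 30 - 1 - idx6[(rem[a], rem[b])]
            dst = 20 - 1 - t5
            moves.append((src, dst))
        card = ct._apply_perm_vec(packed6, ct._compile_moves(moves))
        cards[:, d] = table5.labels[card.astype(np.int64)]
    cards.sort(axis=1)
    return cards


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default=None, help="write the collision report here")
    args = ap.parse_args(argv)
    t0 = time.time()

    print("enumerating connected 6-node digraph classes (growth; long) ...", flush=True)
    n_conn, conn_reps = ct.enumerate_connected_classes(6, directed=True)
    print(f"  connected classes: {n_conn}  [{time.time()-t0:.0f}s]", flush=True)

    by_size = connected_classes_by_size()
    disc = disconnected_reps_packed(by_size)
    print(f"  disconnected classes: {len(disc)}  [{time.time()-t0:.0f}s]", flush=True)

    conn_packed = np.array([ct.pack_offdiag(r, 6) for r in conn_reps], dtype=np.uint64)
    all_packed = np.concatenate([conn_packed, disc])
    connected_flag = np.zeros(len(all_packed), dtype=bool)
    connected_flag[: len(conn_packed)] = True

    table5 = ct.build_canon_table(5)
    print("computing decks ...", flush=True)
    decks = decks_vectorized(all_packed, table5)

    order = np.lexsort(decks.T[::-1])
    sorted_decks = decks[order]
    same = np.all(sorted_decks[1:] == sorted_decks[:-1], axis=1)
    lines = [f"total classes: {len(all_packed)} "
             f"(connected {int(connected_flag.sum())}, "
             f"disconnected {int((~connected_flag).sum())})"]
    hits = np.flatnonzero(same)
    groups: list[list[int]] = []
    current: list[int] = []
    for h in hits:
        if current and h != current[-1] + 1:
            groups.append(current)
            current = []
        if not current:
            current = [h]
        current.append(h + 1)
    if current:
        groups.append(current)
    lines.append(f"deck-collision groups: {len(groups)}")
    for grp in groups:
        members = [order[i] for i in grp]
        ids = [ct.unpack_offdiag(int(all_packed[m]), 6) for m in members]
        conn = [bool(connected_flag[m]) for m in members]
        deck = decks[members[0]].tolist()
        lines.append(f"deck {deck}: graphIDs {ids} connected {conn}")
    report = "\n".join(lines)
    print(report, flush=True)
    print(f"done in {time.time()-t0:.0f}s")
    if args.out:
        with open(args.out, "w") as fh:
            fh.write(report + "\n")
    return 0


if __name__ == "__main__":
    sys.exit(main())
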