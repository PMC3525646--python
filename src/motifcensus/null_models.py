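"""Degree-preserving random ensembles ("similar" comparison graphs).

A comparison graph shares the input network's vertex set and every vertex's
in- and out-degree.  Within that constraint the treatment of bidirectional
(reciprocal) arc pairs distinguishes five methods:

``nr``  (no regard)        — switch any two arcs; reciprocal structure drifts.
``f``   (fixed)            — bidirectional pairs are frozen in place: only
                             non-reciprocal arcs move, and moves that would
                             create a new reciprocal pair are rejected.
``gc``  (global constant)  — like ``nr`` but proposals that change the total
                             number of reciprocal pairs are rejected.
``lc``  (local constant)   — non-reciprocal arcs switch among themselves
                             (never creating reciprocal pairs) and reciprocal
                             pairs switch among themselves as undirected
                             edges, so every vertex keeps its reciprocal
                             degree.
``ulc`` (uniform local constant) — draws each comparison graph uniformly at
                             random from all simple loop-free digraphs with
                             the input's per-vertex (pure-out, pure-in,
                             reciprocal) degree profile, by configuration-
                             model stub matching with rejection.

The switching methods run one Markov chain started at the input network: a
*switch* picks two arcs ``u->v, x->y`` and replaces them by ``u->y, x->v``
provided no loop or parallel arc (or a method-forbidden reciprocal change)
results.  Each comparison graph is the chain state after a further
``ceil(switches_per_arc * m)`` proposals; the first ``burnin`` outputs are
discarded so the ensemble does not start at the input network itself.
Proposal randomness for chain segment ``j`` comes from an independent stream
seeded by ``(seed, j)``, so any worker can reproduce comparison graph ``i``
by replaying segments ``0 .. burnin+i`` without shared state.  Switching
samples from a non-uniform distribution over degree-matched graphs; only
``ulc`` is exactly uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterator

import numpy as np

from .graph_model import DirectedGraph

METHODS = ("f", "nr", "gc", "lc", "ulc")


class UlcInfeasibleError(RuntimeError):
    """Uniform sampling failed to produce a valid matching within the cap."""


@dataclass(frozen=True)
class NullModelConfig:
    method: str = "lc"
    n_comparison: int = 100
    burnin: int = 0
    switches_per_arc: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.n_comparison < 1:
            raise ValueError("n_comparison must be >= 1")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if self.switches_per_arc < 0:
            raise ValueError("switches_per_arc must be >= 0")


def reciprocal_pairs(g: DirectedGraph) -> set[frozenset[int]]:
    """The set of bidirectional edges, each as an unordered vertex pair."""
    return {frozenset((u, v)) for (u, v) in g.iter_arcs() if g.has_arc(v, u)}


def degree_profile(g: DirectedGraph) -> list[tuple[int, int, int]]:
    """Per-vertex (pure-out-degree, pure-in-degree, reciprocal-degree)."""
    prof = []
    for v in range(g.n_nodes):
        succ = g.successors(v)
        pred = g.predecessors(v)
        r = len(succ & pred)
        prof.append((len(succ) - r, len(pred) - r, r))
    return prof


class _ArcPool:
    """Arc list with O(1) uniform sampling and removal (swap-with-last)."""

    def __init__(self, arcs):
        self.items = list(arcs)
        self.pos = {a: i for i, a in enumerate(self.items)}

    def __len__(self):
        return len(self.items)

    def sample_two(self, rng) -> tuple:
        i = int(rng.integers(len(self.items)))
        j = int(rng.integers(len(self.items) - 1))
        if j >= i:
            j += 1
        return self.items[i], self.items[j]

    def replace(self, old, new) -> None:
        i = self.pos.pop(old)
        self.items[i] = new
        self.pos[new] = i


class SwitchChain:
    """Markov chain over degree-matched digraphs for one switching method."""

    def __init__(self, g: DirectedGraph, method: str):
        if method not in ("f", "nr", "gc", "lc"):
            raise ValueError(f"not a switching method: {method!r}")
        self.method = method
        self.g = g.copy()
        recips = reciprocal_pairs(g)
        if method in ("f", "lc"):
            singles = [a for a in g.iter_arcs() if frozenset(a) not in recips]
            self.singles = _ArcPool(singles)
            self.recip_edges = _ArcPool(tuple(sorted(p)) for p in recips) \
                if method == "lc" else None
        else:
            self.singles = _ArcPool(g.iter_arcs())
            self.recip_edges = None
        self.n_recip = len(recips)

    # -- proposal kinds ---------------------------------------------------

    def _try_single_swap(self, rng, forbid_new_recip: bool, keep_global_recip: bool) -> bool:
        pool = self.singles
        if len(pool) < 2:
            return False
        (u, v), (x, y) = pool.sample_two(rng)
        g = self.g
        if u == y or x == v:
            return False  # loop
        if g.has_arc(u, y) or g.has_arc(x, v):
            return False  # parallel arc
        if forbid_new_recip and (g.has_arc(y, u) or g.has_arc(v, x)):
            return False
        if keep_global_recip:
            delta = (1 if g.has_arc(y, u) else 0) + (1 if g.has_arc(v, x) else 0) \
                - (1 if g.has_arc(v, u) else 0) - (1 if g.has_arc(y, x) else 0)
            if delta != 0:
                return False
            self.n_recip += delta
        g.remove_arc(u, v)
        g.remove_arc(x, y)
        g.add_arc(u, y)
        g.add_arc(x, v)
        pool.replace((u, v), (u, y))
        pool.replace((x, y), (x, v))
        return True

    def _try_recip_swap(self, rng) -> bool:
        pool = self.recip_edges
        if pool is None or len(pool) < 2:
            return False
        (a, b), (c, d) = pool.sample_two(rng)
        # two rewirings keep one endpoint of each edge; pick one at random
        if rng.integers(2):
            e1, e2 = (a, c), (b, d)
        else:
            e1, e2 = (a, d), (b, c)
        g = self.g
        for (p, q) in (e1, e2):
            if p == q:
                return False  # loop
            if g.has_arc(p, q) or g.has_arc(q, p):
                return False  # parallel with an existing arc in either direction
        if e1 == e2 or frozenset(e1) == frozenset(e2):
            return False
        for (p, q) in ((a, b), (c, d)):
            g.remove_arc(p, q)
            g.remove_arc(q, p)
        for (p, q) in (e1, e2):
            g.add_arc(p, q)
            g.add_arc(q, p)
        pool.replace((a, b), tuple(sorted(e1)))
        pool.replace((c, d), tuple(sorted(e2)))
        return True

    def step(self, rng) -> bool:
        """One proposal; True iff it was accepted (graph mutated in place)."""
        m = self.method
        if m == "nr":
            return self._try_single_swap(rng, forbid_new_recip=False, keep_global_recip=False)
        if m == "gc":
            return self._try_single_swap(rng, forbid_new_recip=False, keep_global_recip=True)
        if m == "f":
            return self._try_single_swap(rng, forbid_new_recip=True, keep_global_recip=False)
        # lc: choose the sub-pool proportionally to how many pairs it offers
        ns = len(self.singles)
        nr = len(self.recip_edges)
        ws = ns * (ns - 1) // 2
        wr = nr * (nr - 1) // 2
        if ws + wr == 0:
            return False
        if int(rng.integers(ws + wr)) < ws:
            return self._try_single_swap(rng, forbid_new_recip=True, keep_global_recip=False)
        return self._try_recip_swap(rng)


def switch_step(g: DirectedGraph, method: str, rng) -> bool:
    """Apply one switching proposal to ``g`` in place; True iff accepted.

    Convenience wrapper building a throwaway :class:`SwitchChain`; for long
    chains, keep a :class:`SwitchChain` instead.
    """
    if g.n_arcs < 2:
        return False
    chain = SwitchChain(g, method)
    accepted = chain.step(rng)
    if accepted:
        # copy the mutated state back into the caller's graph
        for (u, v) in list(g.iter_arcs()):
            if not chain.g.has_arc(u, v):
                g.remove_arc(u, v)
        for (u, v) in chain.g.iter_arcs():
            if not g.has_arc(u, v):
                g.add_arc(u, v)
    return accepted


def _segment_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(index)]))


def generate_comparisons(g: DirectedGraph, cfg: NullModelConfig) -> Iterator[DirectedGraph]:
    """Yield the ensemble ``G_1 .. G_M`` (burnin outputs already discarded)."""
    total = cfg.burnin + cfg.n_comparison
    if cfg.method == "ulc":
        profile = degree_profile(g)
        for j in range(cfg.burnin, total):
            yield sample_uniform_lc(profile, _segment_rng(cfg.seed, j))
        return
    chain = SwitchChain(g, cfg.method)
    steps = ceil(cfg.switches_per_arc * g.n_arcs)
    for j in range(total):
        rng = _segment_rng(cfg.seed, j)
        for _ in range(steps):
            chain.step(rng)
        if j >= cfg.burnin:
            yield chain.g.copy()


def generate_comparison(g: DirectedGraph, cfg: NullModelConfig, index: int) -> DirectedGraph:
    """Reproduce comparison graph ``index`` (0-based) from ``(seed, index)`` alone.

    Replays the chain segments deterministically, so parallel workers agree
    with a serial run without sharing state.
    """
    if not 0 <= index < cfg.n_comparison:
        raise IndexError(f"comparison index {index} outside 0..{cfg.n_comparison - 1}")
    for i, cg in enumerate(generate_comparisons(g, cfg)):
        if i == index:
            return cg
    raise AssertionError("unreachable")


def sample_uniform_lc(profile: list[tuple[int, int, int]], rng,
                      max_restarts: int = 200_000) -> DirectedGraph:
    """Draw a digraph uniformly among realizations of a degree profile.

    Configuration-model variant with three stub types: pure-out stubs are
    matched to pure-in stubs by a random bijection (giving single arcs), and
    reciprocal stubs are paired by a random perfect matching (giving
    bidirectional edges).  Any matching containing a loop, a repeated arc, an
    accidental reciprocal pair among single arcs, or an overlap between a
    bidirectional edge and a single arc is rejected and redrawn wholesale.
    Every simple realization corresponds to the same number of stub matchings
    (a product of per-vertex stub factorials), so the accepted draw is
    uniform.  Raises :class:`UlcInfeasibleError` after ``max_restarts``
    rejections — dense reciprocal structure can make acceptance vanishingly
    rare, in which case a switching method is the practical fallback.
    """
    n = len(profile)
    out_stubs = np.repeat(np.arange(n), [p[0] for p in profile])
    in_stubs = np.repeat(np.arange(n), [p[1] for p in profile])
    rec_stubs = np.repeat(np.arange(n), [p[2] for p in profile])
    if len(out_stubs) != len(in_stubs):
        raise ValueError("profile is unbalanced: total pure-out != total pure-in")
    if len(rec_stubs) % 2:
        raise ValueError("profile is unrealizable: odd total reciprocal degree")
    for _ in range(max_restarts):
        heads = rng.permutation(in_stubs)
        singles = set()
        ok = True
        for u, v in zip(out_stubs.tolist(), heads.tolist()):
            if u == v or (u, v) in singles:
                ok = False
                break
            singles.add((u, v))
        if ok and any((v, u) in singles for (u, v) in singles):
            ok = False
        if ok:
            paired = rng.permutation(rec_stubs)
            edges = set()
            for i in range(0, len(paired), 2):
                p, q = int(paired[i]), int(paired[i + 1])
                if p == q:
                    ok = False
                    break
                e = (min(p, q), max(p, q))
                if e in edges or (p, q) in singles or (q, p) in singles:
                    ok = False
                    break
                edges.add(e)
        if ok:
            g = DirectedGraph(n)
            for (u, v) in singles:
                g.add_arc(u, v)
            for (p, q) in edges:
                g.add_arc(p, q)
                g.add_arc(q, p)
            return g
    raise UlcInfeasibleError(
        f"no valid uniform matching found in {max_restarts} attempts; "
        "consider a switching method (f/nr/gc/lc) for this network")
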