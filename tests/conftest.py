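import numpy as np
import pytest

from motifcensus import DirectedGraph, build_canon_table, generate_fixture
from motifcensus import canon_tables as ct


@pytest.fixture(scope="session")
def table3():
    return build_canon_table(3)


@pytest.fixture(scope="session")
def table4():
    return build_canon_table(4)


@pytest.fixture(scope="session")
def table5():
    return build_canon_table(5)


@pytest.fixture
def ffl():
    """Feed-forward loop on labels (0,1,2): 1->0, 2->0, 2->1 (graphID 38)."""
    return DirectedGraph(3, [(1, 0), (2, 0), (2, 1)])


def random_digraph(n: int, density: float, seed: int) -> DirectedGraph:
    return generate_fixture("random", n=n, density=density, seed=seed)


def random_k_digraph(k: int, rng) -> DirectedGraph:
    """A random loop-free digraph on exactly k nodes (possibly disconnected)."""
    g = DirectedGraph(k)
    for u in range(k):
        for v in range(k):
            if u != v and rng.random() < 0.4:
                g.add_arc(u, v)
    return g


def canonicalize_counts(counts: dict[int, int], k: int) -> dict[int, int]:
    """Re-key a census count dict by exhaustive canonical graphIDs."""
    keys = list(counts)
    packed = np.array([ct.pack_offdiag(key, k) for key in keys], dtype=np.uint64)
    canon = ct.canonical_ids_exhaustive(packed, k)
    out: dict[int, int] = {}
    for key, c in zip(keys, canon):
        full = ct.unpack_offdiag(int(c), k)
        out[full] = out.get(full, 0) + counts[key]
    return out
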