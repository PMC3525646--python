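"""Null models: degree conservation laws, switching behavior, ULC uniformity."""

import numpy as np
import pytest

from motifcensus import (
    DirectedGraph,
    NullModelConfig,
    SwitchChain,
    degree_profile,
    generate_comparison,
    generate_comparisons,
    reciprocal_pairs,
    sample_uniform_lc,
    switch_step,
)

from conftest import random_digraph


def three_cycle():
    return DirectedGraph(3, [(0, 1), (1, 2), (2, 0)])


def in_out_degrees(g):
    return [(g.out_degree(v), g.in_degree(v)) for v in range(g.n_nodes)]


def assert_simple(g):
    for (u, v) in g.iter_arcs():
        assert u != v


class TestSwitchStep:
    @pytest.mark.parametrize("method", ["f", "nr", "gc", "lc"])
    def test_degrees_preserved_over_many_steps(self, method):
        g = random_digraph(12, 0.3, 11)
        degrees = in_out_degrees(g)
        chain = SwitchChain(g, method)
        rng = np.random.default_rng(0)
        accepted = sum(chain.step(rng) for _ in range(500))
        assert accepted > 0  # the chain actually moves
        assert in_out_degrees(chain.g) == degrees
        assert_simple(chain.g)

    def test_three_cycle_is_frozen(self):
        # every exchange on a directed 3-cycle creates a loop or parallel arc
        g = three_cycle()
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert not switch_step(g, "nr", rng)
        assert g == three_cycle()

    def test_too_few_arcs_is_noop(self):
        g = DirectedGraph(3, [(0, 1)])
        assert not switch_step(g, "nr", np.random.default_rng(0))

    def test_lc_preserves_reciprocal_degree_per_step(self):
        g = DirectedGraph(5, [(0, 1), (1, 0), (1, 2), (2, 3), (3, 4), (4, 2), (0, 3)])
        want = [p[2] for p in degree_profile(g)]
        chain = SwitchChain(g, "lc")
        rng = np.random.default_rng(2)
        for _ in range(2000):
            chain.step(rng)
            assert [p[2] for p in degree_profile(chain.g)] == want


class TestGenerateComparison:
    # exact-uniform sampling is exercised on sparser graphs: wholesale
    # rejection has vanishing acceptance as density grows
    @pytest.mark.parametrize("method, density", [
        ("f", 0.35), ("nr", 0.35), ("gc", 0.35), ("lc", 0.35), ("ulc", 0.2)])
    def test_in_out_degrees_always_preserved(self, method, density):
        g = random_digraph(10, density, 21)
        degrees = in_out_degrees(g)
        cfg = NullModelConfig(method=method, n_comparison=10, seed=5)
        for cg in generate_comparisons(g, cfg):
            assert in_out_degrees(cg) == degrees
            assert_simple(cg)

    def test_f_freezes_reciprocal_pair_set(self):
        g = random_digraph(10, 0.4, 31)
        pairs = reciprocal_pairs(g)
        cfg = NullModelConfig(method="f", n_comparison=15, seed=6)
        for cg in generate_comparisons(g, cfg):
            assert reciprocal_pairs(cg) == pairs

    def test_gc_conserves_global_reciprocal_count(self):
        g = random_digraph(10, 0.4, 41)
        cfg = NullModelConfig(method="gc", n_comparison=15, seed=7)
        for cg in generate_comparisons(g, cfg):
            assert len(reciprocal_pairs(cg)) == len(reciprocal_pairs(g))

    @pytest.mark.parametrize("method, density", [("lc", 0.4), ("ulc", 0.2)])
    def test_lc_conserves_reciprocal_degree_profile(self, method, density):
        g = random_digraph(10, density, 51)
        want = [p[2] for p in degree_profile(g)]
        cfg = NullModelConfig(method=method, n_comparison=15, seed=8)
        for cg in generate_comparisons(g, cfg):
            assert [p[2] for p in degree_profile(cg)] == want

    def test_burnin_discards_leading_chain_outputs(self):
        g = random_digraph(10, 0.3, 61)
        full = list(generate_comparisons(g, NullModelConfig(
            method="lc", n_comparison=8, burnin=0, seed=9)))
        burned = list(generate_comparisons(g, NullModelConfig(
            method="lc", n_comparison=5, burnin=3, seed=9)))
        assert burned == full[3:]

    def test_per_index_reproducibility(self):
        g = random_digraph(10, 0.3, 71)
        cfg = NullModelConfig(method="lc", n_comparison=6, seed=10)
        serial = list(generate_comparisons(g, cfg))
        assert generate_comparison(g, cfg, 4) == serial[4]
        assert generate_comparison(g, cfg, 0) == serial[0]

    def test_zero_switches_returns_the_input(self):
        g = random_digraph(8, 0.3, 81)
        cfg = NullModelConfig(method="lc", n_comparison=3, switches_per_arc=0.0, seed=1)
        for cg in generate_comparisons(g, cfg):
            assert cg == g


class TestUniformSampler:
    def test_three_cycle_realizations_equally_likely(self):
        # the 3-cycle profile has exactly two labeled realizations (orientations)
        profile = degree_profile(three_cycle())
        rng = np.random.default_rng(3)
        hits = {}
        draws = 10_000
        for _ in range(draws):
            key = frozenset(sample_uniform_lc(profile, rng).arcs)
            hits[key] = hits.get(key, 0) + 1
        assert len(hits) == 2
        for count in hits.values():
            assert abs(count / draws - 0.5) <= 0.02

    def test_unique_realization_profile(self):
        g = DirectedGraph(2, [(0, 1), (1, 0)])
        out = sample_uniform_lc(degree_profile(g), np.random.default_rng(0))
        assert out == g

    def test_unbalanced_profile_rejected(self):
        with pytest.raises(ValueError):
            sample_uniform_lc([(1, 0, 0), (0, 0, 0)], np.random.default_rng(0))

    def test_reciprocal_profile_preserved(self):
        g = DirectedGraph(5, [(0, 1), (1, 0), (1, 2), (2, 3), (3, 1), (4, 0), (2, 4)])
        profile = degree_profile(g)
        rng = np.random.default_rng(4)
        for _ in range(200):
            assert degree_profile(sample_uniform_lc(profile, rng)) == profile


class TestConfigValidation:
    def test_bad_method(self):
        with pytest.raises(ValueError):
            NullModelConfig(method="xyz")

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            NullModelConfig(n_comparison=0)
        with pytest.raises(ValueError):
            NullModelConfig(burnin=-1)
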