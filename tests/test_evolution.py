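"""Lattice geometry, the three evolutionary operators, and the engine."""

import numpy as np
import pytest

from maefmd import (
    ModuleSet,
    Params,
    PPINetwork,
    build_strength_table,
    competition,
    crossover_alternating_chunk,
    crossover_alternating_link,
    decode,
    evolve,
    lattice_neighbors,
    link_strengths,
    mutate,
    mutation_count,
    partition_energy,
)
from .conftest import (
    ScriptedRng,
    agent_from,
    enumerate_partitions,
    random_connected_network,
)


class TestLatticeNeighbors:
    def test_corner_of_3x3_torus(self):
        assert set(lattice_neighbors(3, 1, 1)) == {(3, 1), (1, 3), (2, 1), (1, 2)}

    def test_2x2_wraparound_deduplicates(self):
        nbrs = lattice_neighbors(2, 1, 1)
        assert set(nbrs) == {(2, 1), (1, 2)}

    def test_every_cell_of_4x4_has_four_distinct_neighbors(self):
        for u in range(1, 5):
            for v in range(1, 5):
                nbrs = lattice_neighbors(4, u, v)
                assert len(nbrs) == 4 and len(set(nbrs)) == 4

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            lattice_neighbors(3, 0, 1)


class TestLinkStrengths:
    def test_breakpoints_have_zero_strength(self, toy8, toy8_table):
        agent = agent_from(toy8, "1 2 3 4 5 6 7 8")
        assert np.all(link_strengths(agent, toy8_table) == 0.0)

    def test_values_are_table_lookups(self, toy8, toy8_table):
        agent = agent_from(toy8, "6 2 7 8 5 5 2 8")
        al = link_strengths(agent, toy8_table)
        assert al[0] == pytest.approx(toy8_table.lookup("1", "6"))
        assert al[2] == pytest.approx(toy8_table.lookup("3", "7"))
        assert al[1] == 0.0 and al[7] == 0.0


class TestCompetition:
    # Printed worked example: A loses to H; Strategy 1 replaces only the
    # weakest link of H's clone, Strategy 2 every link where A is stronger.
    A = "6 2 7 8 5 5 2 8"
    H = "1 4 7 8 5 5 1 8"

    def test_strategy_one_replaces_weakest_link(self, toy8, toy8_table):
        a = agent_from(toy8, self.A)
        h = agent_from(toy8, self.H)
        assert a.energy < h.energy
        out = competition(a, h, toy8_table, p_o=1.0, rng=ScriptedRng(reals=[0.0]))
        assert out.links() == agent_from(toy8, "6 4 7 8 5 5 1 8").links()

    def test_strategy_two_replaces_all_stronger_links(self, toy8, toy8_table):
        a = agent_from(toy8, self.A)
        h = agent_from(toy8, self.H)
        out = competition(a, h, toy8_table, p_o=0.0, rng=ScriptedRng(reals=[0.5]))
        assert out.links() == agent_from(toy8, "6 4 7 8 5 5 2 8").links()

    def test_winner_survives_unchanged(self, toy8, toy8_table):
        a = agent_from(toy8, self.A)
        h = agent_from(toy8, self.H)
        out = competition(h, a, toy8_table, p_o=0.5, rng=ScriptedRng(reals=[0.0]))
        assert out is h


class TestCrossover:
    F1_LINK = "6 8 7 4 5 5 4 8"
    F2_LINK = "6 2 7 8 5 5 7 8"
    C1_LINK = "6 2 7 8 5 5 4 8"

    def test_alternating_link_reproduces_printed_child(self, toy8):
        p1 = agent_from(toy8, self.F1_LINK)
        p2 = agent_from(toy8, self.F2_LINK)
        rng = ScriptedRng(ints=[0, 2, 0, 1, 0])
        child = crossover_alternating_link(p1, p2, rng)
        assert child.links() == agent_from(toy8, self.C1_LINK).links()

    F1_CHUNK = "5 5 8 4 5 6 4 6"
    F2_CHUNK = "2 3 3 7 5 6 5 6"
    C1_CHUNK = "5 5 8 4 5 6 5 6"

    def test_alternating_chunk_reproduces_printed_child(self, toy8):
        p1 = agent_from(toy8, self.F1_CHUNK)
        p2 = agent_from(toy8, self.F2_CHUNK)
        # chunk sizes 3, 2, 2, 1 with chunks 1 and 3 from the first parent
        rng = ScriptedRng(ints=[2, 3, 0, 1, 4, 1, 0, 0, 0, 0])
        child = crossover_alternating_chunk(p1, p2, rng)
        assert child.links() == agent_from(toy8, self.C1_CHUNK).links()

    @pytest.mark.parametrize("op", [crossover_alternating_link, crossover_alternating_chunk])
    def test_identical_parents_give_identical_child(self, toy8, op):
        p = agent_from(toy8, self.F1_LINK)
        for seed in range(10):
            child = op(p, p.copy(), np.random.default_rng(seed))
            assert child.links() == p.links()

    @pytest.mark.parametrize("op", [crossover_alternating_link, crossover_alternating_chunk])
    def test_every_child_link_comes_from_a_parent(self, toy8, op):
        p1 = agent_from(toy8, self.F1_LINK)
        p2 = agent_from(toy8, self.F2_LINK)
        for seed in range(100):
            child = op(p1, p2, np.random.default_rng(seed))
            for i in range(8):
                assert child.assignment[i] in (p1.assignment[i], p2.assignment[i])


class TestMutation:
    def test_count_is_one_at_zero_stagnation(self):
        for n in (1, 8, 5000):
            assert mutation_count(n, 0, 60) == 1

    def test_count_matches_printed_toy_value(self):
        assert mutation_count(8, 30, 60) == 2  # N=8, l/R=0.5

    def test_count_monotone_in_size_and_stagnation(self):
        assert mutation_count(10000, 60, 60) >= mutation_count(8, 60, 60)
        prev = 0
        for l in range(0, 61, 5):
            cur = mutation_count(100, l, 60)
            assert cur >= prev
            prev = cur
        assert mutation_count(4, 60, 60) <= 4  # capped at N

    def test_reproduces_printed_mutant(self, toy8):
        d = agent_from(toy8, "6 2 7 8 5 5 2 8")
        rng = ScriptedRng(ints=[3, 0, 5, 2])
        m = mutate(d, 2, rng)
        assert m.links() == agent_from(toy8, "6 2 7 2 5 5 4 8").links()

    def test_only_option_is_breakpoint(self):
        from maefmd import Agent

        net = PPINetwork([("i", "j")], isolated=["k"])
        a = Agent.from_links(net, {"i": "j", "j": "j", "k": "k"})
        mutant = mutate(a, 1, ScriptedRng(ints=[0, 0]))
        assert mutant.links()["i"] == "i"

    def test_exactly_n_positions_differ(self, toy8):
        d = agent_from(toy8, "6 2 7 8 5 5 2 8")
        for seed in range(100):
            m = mutate(d, 3, np.random.default_rng(seed))
            assert int(np.sum(m.assignment != d.assignment)) == 3

    def test_mutating_more_than_n_raises(self, toy8):
        d = agent_from(toy8, "6 2 7 8 5 5 2 8")
        with pytest.raises(ValueError):
            mutate(d, 9, np.random.default_rng(0))


class TestEvolve:
    def test_single_edge_network_finds_the_pair(self):
        net = PPINetwork([("a", "b")])
        for seed in (0, 1, 2):
            res = evolve(net, None, Params(M=4, R=5, max_iter=30, epsilon=0.0, seed=seed))
            assert decode(res.best).modules == [frozenset({"a", "b"})]
            assert res.best.energy == pytest.approx(0.0)

    def test_two_triangles_reach_the_exact_optimum(self, two_triangles):
        net, truth = two_triangles
        for seed in range(10):
            res = evolve(net, None, Params(M=16, R=10, max_iter=100, epsilon=0.0, seed=seed))
            assert res.best.energy == pytest.approx(5 / 14)
            assert sorted(map(sorted, decode(res.best))) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_trace_is_monotonically_non_decreasing(self, two_triangles):
        net, _ = two_triangles
        res = evolve(net, None, Params(M=9, R=8, max_iter=60, epsilon=0.0, seed=4))
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))

    def test_bit_reproducible_with_same_seed(self, two_triangles):
        net, _ = two_triangles
        r1 = evolve(net, None, Params(M=9, R=8, max_iter=60, epsilon=0.0, seed=12))
        r2 = evolve(net, None, Params(M=9, R=8, max_iter=60, epsilon=0.0, seed=12))
        assert np.array_equal(r1.best.assignment, r2.best.assignment)
        assert r1.trace == r2.trace

    def test_non_square_population_rejected(self):
        with pytest.raises(ValueError):
            Params(M=10)

    def test_reaches_exhaustive_optimum_on_random_tiny_graph(self):
        rng = np.random.default_rng(99)
        net = random_connected_network(rng, n_max=6)
        best = max(
            partition_energy(net, ModuleSet(p)) for p in enumerate_partitions(net.node_order)
        )
        res = evolve(net, None, Params(M=25, R=30, max_iter=300, epsilon=0.0, seed=1))
        assert res.best.energy == pytest.approx(best)
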