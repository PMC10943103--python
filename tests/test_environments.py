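"""Generators, affordances, exploration sampling, edge-list format."""

import numpy as np
import networkx as nx
import pytest

from cogmap import (GraphEnvironment, add_virtual_goal, assign_edge_costs,
                    generate_challenge_graph, generate_grid,
                    generate_random_graph, generate_small_world,
                    read_edge_list, sample_exploration, write_edge_list)
from cogmap.environments import GenerationError


class TestRandomGraph:
    def test_degrees_and_connectivity(self):
        env = generate_random_graph(32, 2, 5, seed=0)
        g = env.to_networkx()
        assert nx.is_connected(g)
        degrees = dict(g.degree)
        assert min(degrees.values()) >= 2 and max(degrees.values()) <= 5
        assert env.n_o == 32 and env.n_a == 2 * len(env.edges)

    def test_infeasible_parameters_raise(self):
        with pytest.raises(GenerationError):
            generate_random_graph(2, 2, 2, seed=0)

    def test_same_seed_reproduces_edge_set(self):
        a = generate_random_graph(20, 2, 4, seed=5)
        b = generate_random_graph(20, 2, 4, seed=5)
        assert a.edges == b.edges

    def test_action_bijection_round_trip(self):
        env = generate_random_graph(12, 2, 4, seed=1)
        for k in range(env.n_a):
            u, v = env.action_endpoints(k)
            env.reset(u)
            assert env.step(k) == v

    def test_unafforded_step_impossible(self):
        env = GraphEnvironment(3, [(0, 1), (1, 2), (0, 2)])
        env.reset(0)
        missing = [k for k in range(env.n_a)
                   if env.affordances(0)[k] == 0][0]
        with pytest.raises(ValueError, match="not afforded"):
            env.step(missing)


class TestSmallWorld:
    @pytest.mark.parametrize("k,size,topology,n_edges", [
        (4, 6, "chain", 4 * 15 + 3),   # clique edges plus bridges
        (2, 2, "chain", 2 + 1),
        (3, 4, "ring", 3 * 6 + 3),
    ])
    def test_edge_counts(self, k, size, topology, n_edges):
        env = generate_small_world(k, size, topology, seed=0)
        assert env.n_o == k * size
        assert len(env.edges) == n_edges
        assert nx.is_connected(env.to_networkx())

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_small_world(1, 6)


class TestChallengeGraphs:
    def test_dead_end_pendant_tips_have_degree_one(self):
        env = generate_challenge_graph("dead_end", seed=0, backbone_len=6,
                                       n_pendants=3, pendant_len=2)
        assert env.n_o == 12
        deg = dict(env.to_networkx().degree)
        tips = [n for n, d in deg.items() if d == 1]
        assert len(tips) == 3

    def test_multi_path_has_two_disjoint_shortest_paths(self):
        env = generate_challenge_graph("multi_path", ladder_width=2, ladder_len=4)
        g = env.to_networkx()
        paths = list(nx.all_shortest_paths(g, 0, 7))  # opposite corners
        assert len(paths) >= 2
        interiors = [set(p[1:-1]) for p in paths]
        assert any(a.isdisjoint(b) for i, a in enumerate(interiors)
                   for b in interiors[i + 1:])

    def test_same_seed_identical(self):
        a = generate_challenge_graph("dead_end", seed=3)
        b = generate_challenge_graph("dead_end", seed=3)
        assert a.edges == b.edges

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_challenge_graph("dead_end", backbone_len=2)
        with pytest.raises(ValueError):
            generate_challenge_graph("multi_path", ladder_width=1)


class TestEdgeCosts:
    def test_costs_drawn_from_given_set(self):
        env = generate_random_graph(16, 2, 4, seed=2)
        w = assign_edge_costs(env, (4, 5, 6, 7), seed=3)
        assert set(w.costs.values()) <= {4, 5, 6, 7}

    def test_unit_costs_reduce_to_unweighted_affordances(self):
        env = generate_random_graph(10, 2, 4, seed=2)
        w = assign_edge_costs(env, (1,), seed=3)
        assert np.array_equal(w.afford, env.afford)

    def test_affordance_is_reciprocal_cost(self):
        w = GraphEnvironment(3, [(0, 1), (1, 2), (0, 2)],
                             costs={(0, 1): 4.0, (1, 2): 7.0, (0, 2): 7.0})
        g = w.affordances(0)
        vals = sorted(v for v in g if v > 0)
        assert np.allclose(vals, [1 / 7, 1 / 4])

    def test_non_positive_costs_rejected(self):
        env = generate_random_graph(8, 2, 3, seed=1)
        with pytest.raises(ValueError):
            assign_edge_costs(env, (0,), seed=0)


class TestVirtualGoal:
    def test_construction_counts(self):
        # 2-step binary decision tree: root 0, layer1 {1,2}, leaves {3,4,5,6}
        tree = GraphEnvironment(7, [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6)])
        aug = add_virtual_goal(tree, [3, 4, 5, 6], [1, 1, 1, 1])
        assert aug.n_o == 8
        assert len(aug.edges) == len(tree.edges) + 4

    def test_equal_rewards_give_uniform_entry_affordances(self):
        tree = GraphEnvironment(3, [(0, 1), (0, 2)])
        aug = add_virtual_goal(tree, [1, 2], [2, 2])
        entries = [aug.afford[u, k] for u in (1, 2)
                   for k, v in aug.neighbors_of(u) if v == 3]
        assert np.allclose(entries, 1.0)

    def test_entry_affordance_proportional_to_reward(self):
        tree = GraphEnvironment(3, [(0, 1), (0, 2)])
        aug = add_virtual_goal(tree, [1, 2], [1, 4])
        a1 = [aug.afford[1, k] for k, v in aug.neighbors_of(1) if v == 3][0]
        a2 = [aug.afford[2, k] for k, v in aug.neighbors_of(2) if v == 3][0]
        assert np.isclose(a1, 0.25) and np.isclose(a2, 1.0)

    def test_unknown_terminal_rejected(self):
        tree = GraphEnvironment(3, [(0, 1), (0, 2)])
        with pytest.raises(ValueError):
            add_virtual_goal(tree, [5], [1])


class TestGrid:
    def test_rect_dimensions_and_corner_affordances(self):
        env = generate_grid("rect", 4, 4)
        assert env.n_o == 16 and env.n_a == 4
        assert np.count_nonzero(env.affordances(0)) == 2      # corner
        assert np.count_nonzero(env.affordances(5)) == 4      # interior

    def test_hex_interior_affords_six(self):
        env = generate_grid("hex", 3, 3)
        assert env.n_a == 6
        center = 1 * 3 + 1
        assert np.count_nonzero(env.affordances(center)) == 6

    def test_boundary_move_blocked(self):
        env = generate_grid("rect", 3, 3)
        east_col = 2  # action index 1 is east
        env.reset(east_col)
        assert env.affordances(east_col)[1] == 0
        with pytest.raises(ValueError):
            env.step(1)

    def test_size_validation(self):
        with pytest.raises(ValueError):
            generate_grid("rect", 1, 4)
        with pytest.raises(ValueError):
            generate_grid("triangular", 3, 3)


class TestExploration:
    def test_buffer_size_and_chain_consistency(self):
        env = generate_random_graph(32, 2, 5, seed=0)
        buf = sample_exploration(env, 200, 32, seed=1)
        assert len(buf) <= 200 * 32
        assert buf.check_chain()

    def test_holdout_edges_never_traversed(self):
        env = generate_grid("rect", 4, 4)
        holdout = {(0, 1), (5, 9)}
        buf = sample_exploration(env, 22, 3, seed=2, holdout_edges=holdout)
        crossed = {tuple(sorted((i, j)))
                   for i, j in zip(buf.obs.tolist(), buf.nxt.tolist())}
        assert crossed.isdisjoint(holdout)

    def test_unreachable_cell_warns(self):
        env = generate_grid("rect", 2, 2)
        # isolate cell 0 by holding out both of its edges
        with pytest.warns(UserWarning, match="never visited"):
            sample_exploration(env, 5, 4, seed=3,
                               holdout_edges={(0, 1), (0, 2)})

    def test_seeded_sampling_reproducible(self):
        env = generate_random_graph(16, 2, 4, seed=0)
        a = sample_exploration(env, 10, 8, seed=9)
        b = sample_exploration(env, 10, 8, seed=9)
        assert np.array_equal(a.obs, b.obs) and np.array_equal(a.act, b.act)


class TestEdgeListFormat:
    def test_round_trip_unweighted(self, tmp_path):
        env = generate_random_graph(12, 2, 4, seed=4)
        path = tmp_path / "graph.tsv"
        write_edge_list(env, path)
        back = read_edge_list(path)
        assert back.edges == env.edges and back.costs is None

    def test_round_trip_weighted(self, tmp_path):
        env = assign_edge_costs(generate_random_graph(12, 2, 4, seed=4),
                                (4, 5, 6, 7), seed=5)
        path = tmp_path / "graph.tsv"
        write_edge_list(env, path)
        back = read_edge_list(path)
        assert back.costs == env.costs

    def test_reader_rejects_disconnected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("0\t1\n2\t3\n")
        with pytest.raises(ValueError, match="connected"):
            read_edge_list(path)
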