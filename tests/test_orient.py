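"""Orientation assignment (Ising ground state) tests."""

import networkx as nx
import numpy as np
import pytest

from matescaf.orient import (
    AnnealSchedule,
    assign_orientations,
    ising_energy,
    layer_sets,
    solve_component,
    solve_dp,
    solve_sa,
    split_nonreducible,
)

from .oracles import ising_minimum


def random_graph(rng, n, p=0.35, consistent=False):
    graph = nx.Graph()
    graph.add_nodes_from(f"v{i:02d}" for i in range(n))
    nodes = sorted(graph.nodes)
    planted = {v: int(rng.choice([1, -1])) for v in nodes}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = int(rng.integers(1, 9))
                sign = (
                    planted[nodes[i]] * planted[nodes[j]]
                    if consistent
                    else int(rng.choice([1, -1]))
                )
                graph.add_edge(nodes[i], nodes[j], J=sign * w)
    if not nx.is_connected(graph):
        comps = [sorted(c) for c in nx.connected_components(graph)]
        for a, b in zip(comps, comps[1:]):
            graph.add_edge(a[-1], b[0], J=int(rng.choice([1, -1])))
    return graph, planted


def oracle_minimum(graph):
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b], d["J"]) for a, b, d in graph.edges(data=True)]
    return ising_minimum(edges, len(nodes))


class TestLayerSets:
    def test_path_layers_are_singletons(self):
        graph = nx.path_graph(5)
        graph = nx.relabel_nodes(graph, {i: f"v{i}" for i in range(5)})
        layers = layer_sets(graph, start="v0")
        assert [len(z) for z in layers] == [1, 1, 1, 1, 1]

    def test_star_layers(self):
        graph = nx.star_graph(6)
        graph = nx.relabel_nodes(graph, {i: f"v{i}" for i in range(7)})
        layers = layer_sets(graph, start="v0")
        assert [len(z) for z in layers] == [1, 6]

    def test_edges_connect_adjacent_layers_only(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            graph, _ = random_graph(rng, int(rng.integers(5, 15)))
            layers = layer_sets(graph)
            level = {v: k for k, z in enumerate(layers) for v in z}
            for a, b in graph.edges:
                assert abs(level[a] - level[b]) <= 1


class TestDecomposition:
    def test_path_is_not_split(self):
        graph = nx.relabel_nodes(nx.path_graph(4), {i: f"v{i}" for i in range(4)})
        nx.set_edge_attributes(graph, 1, "J")
        parts = split_nonreducible(graph)
        assert len(parts) == 1  # degree-2 articulation vertices stay

    def test_shared_vertex_of_two_triangles_splits(self):
        graph = nx.Graph()
        for tri in (("a", "b", "v"), ("c", "d", "v")):
            for x, y in zip(tri, tri[1:] + tri[:1]):
                graph.add_edge(x, y, J=1)
        parts = split_nonreducible(graph)
        assert len(parts) == 2
        assert all("v" in part.nodes for part, _ in parts)

    def test_tree_components_are_edges_or_stars(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            tree = nx.random_labeled_tree(int(rng.integers(4, 16)), seed=int(rng.integers(1 << 30)))
            tree = nx.relabel_nodes(tree, {i: f"v{i:02d}" for i in tree.nodes})
            nx.set_edge_attributes(tree, 1, "J")
            for part, _ in split_nonreducible(tree):
                # a non-reducible tree piece is a path or a star
                degs = sorted(d for _, d in part.degree)
                assert sum(1 for d in degs if d > 2) <= 1


class TestExactSolvers:
    def test_single_satisfiable_edge(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", J=3)
        res = solve_dp(graph)
        assert res.energy == -3
        assert res.orientations["a"] == res.orientations["b"]
        assert res.violated_edges == []

    def test_frustrated_triangle(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", J=1)
        graph.add_edge("b", "c", J=1)
        graph.add_edge("a", "c", J=-1)
        for solver in (solve_dp, lambda g: solve_sa(g, seed=5)):
            res = solver(graph)
            assert res.energy == -1
            assert len(res.violated_edges) == 1

    def test_dp_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(43)
        for _ in range(60):
            graph, _ = random_graph(rng, int(rng.integers(4, 13)), p=0.3)
            try:
                res = solve_dp(graph, layer_cap=8)
            except Exception:
                continue
            assert res.energy == oracle_minimum(graph)

    def test_decompose_and_merge_preserves_optimum(self):
        rng = np.random.default_rng(44)
        for _ in range(40):
            # two random blobs sharing one articulation vertex
            g1, _ = random_graph(rng, 7, p=0.5)
            g2, _ = random_graph(rng, 7, p=0.5)
            g2 = nx.relabel_nodes(g2, {v: v.replace("v", "w") for v in g2.nodes})
            graph = nx.union(g1, g2)
            graph.add_edge("v00", "w00", J=int(rng.choice([1, -1])))
            graph = nx.relabel_nodes(graph, {"w00": "v00x"})
            res = solve_component(graph, seed=1)
            assert res.energy == oracle_minimum(graph)


class TestSimulatedAnnealing:
    def test_reaches_floor_on_consistent_graph(self):
        rng = np.random.default_rng(45)
        graph, planted = random_graph(rng, 30, p=0.2, consistent=True)
        res = solve_sa(graph, seed=7)
        assert res.energy == res.energy_min
        # recovered assignment equals the planted one up to a global flip
        signs = {res.orientations[v] * planted[v] for v in graph.nodes}
        assert len(signs) == 1

    def test_seed_determinism(self):
        rng = np.random.default_rng(46)
        graph, _ = random_graph(rng, 20, p=0.3)
        a = solve_sa(graph, AnnealSchedule(), seed=3)
        b = solve_sa(graph, AnnealSchedule(), seed=3)
        assert a.orientations == b.orientations and a.energy == b.energy

    def test_never_worse_than_start(self):
        rng = np.random.default_rng(47)
        graph, _ = random_graph(rng, 25, p=0.3)
        start = ising_energy(graph, {v: 1 for v in graph.nodes})
        assert solve_sa(graph, seed=11).energy <= start


class TestAssignOrientations:
    def test_components_solved_independently(self):
        graph = nx.Graph()
        graph.add_edge("a", "b", J=2)
        graph.add_edge("c", "d", J=-3)
        res = assign_orientations(graph)
        assert res.energy == -5
        assert res.orientations["a"] == res.orientations["b"]
        assert res.orientations["c"] != res.orientations["d"]
        # canonical tie rule: lowest-named vertex of each component is +1
        assert res.orientations["a"] == 1 and res.orientations["c"] == 1

    def test_planted_flips_are_detected(self):
        rng = np.random.default_rng(48)
        graph, planted = random_graph(rng, 25, p=0.25, consistent=True)
        flipped = []
        edges = sorted(graph.edges)
        for a, b in edges[:: max(1, len(edges) // 20)][:3]:
            graph.edges[a, b]["J"] *= -1
            flipped.append(tuple(sorted((a, b))))
        res = assign_orientations(graph, seed=2)
        signs = {res.orientations[v] * planted[v] for v in graph.nodes}
        assert len(signs) == 1  # planted assignment recovered
        assert sorted(res.violated_edges) == sorted(flipped)

    def test_zero_noise_graph_matches_truth(self):
        from matescaf.model import SOLID_MATE, Library
        from matescaf.pairgraph import build_graph, pair_constraint
        from matescaf.simdata import (
            fragment_to_contigs,
            simulate_genome,
            simulate_mate_pairs,
        )

        g = simulate_genome(50_000, seed=49)
        contigs, truth = fragment_to_contigs(g, 14, seed=50)
        lib = Library("lib", SOLID_MATE, insert=1350.0, sigma=0.0, read_length=35)
        placements, pairs = simulate_mate_pairs(truth, lib, 12_000, seed=51)
        by_read = {p.read_id: p for p in placements}
        lengths = {cid: len(s) for cid, s in contigs.items()}
        cons = [
            pair_constraint(
                by_read[p.r_read], by_read[p.f_read], lib,
                lengths[by_read[p.r_read].contig_id],
                lengths[by_read[p.f_read].contig_id],
            )
            for p in pairs
            if by_read[p.r_read].contig_id != by_read[p.f_read].contig_id
        ]
        graph, _ = build_graph(cons, lengths)
        res = assign_orientations(graph, seed=1)
        assert res.violated_edges == []
        tstrand = {
            c.contig_id: c.intervals[0].strand for c in truth.contigs.values()
        }
        for comp in nx.connected_components(graph):
            signs = {res.orientations[v] * tstrand[v] for v in comp}
            assert len(signs) == 1  # truth up to one global flip per scaffold
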