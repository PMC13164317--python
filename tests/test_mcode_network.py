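"""MCODE clustering, hub-graph construction, and topology metrics."""
import networkx as nx
import pytest

from nbhub import (
    HubParams,
    Interactome,
    MCODEParams,
    SyntheticSpec,
    build_hub_graph,
    find_complexes,
    select_hubs,
    topology_summary,
    vertex_weight,
)
from nbhub.synthetic import gen_cluster_graph


def bridge_graph():
    """K5 and K4 joined by a single bridge edge (9 nodes)."""
    g = nx.relabel_nodes(nx.complete_graph(5), {i: f"a{i}" for i in range(5)})
    g = nx.union(g, nx.relabel_nodes(nx.complete_graph(4), {i: f"b{i}" for i in range(4)}))
    g.add_edge("a0", "b0")
    return g


class TestVertexWeight:
    def test_isolated_vertex_zero(self):
        g = nx.Graph()
        g.add_node("v")
        assert vertex_weight(g, "v") == 0.0

    def test_triangle_weight_two(self):
        g = nx.complete_graph(3)
        assert all(vertex_weight(g, v) == pytest.approx(2.0) for v in g)

    def test_k4_weight_three(self):
        g = nx.complete_graph(4)
        assert all(vertex_weight(g, v) == pytest.approx(3.0) for v in g)

    def test_star_center_and_leaves(self):
        # center: closed neighborhood is the star itself, 1-core, density 1/3
        g = nx.star_graph(5)
        assert vertex_weight(g, 0) == pytest.approx(1 / 3)
        assert vertex_weight(g, 1) == 0.0  # leaf degree below cutoff

    def test_path_interior(self):
        g = nx.path_graph(10)
        assert vertex_weight(g, 5) == pytest.approx(2 / 3)

    def test_invariant_under_relabeling(self):
        g = bridge_graph()
        relabeled = nx.relabel_nodes(g, {n: f"x_{n}" for n in g})
        for node in g:
            assert vertex_weight(g, node) == pytest.approx(
                vertex_weight(relabeled, f"x_{node}")
            )


class TestFindComplexes:
    def test_empty_graph(self):
        assert find_complexes(nx.Graph()) == []

    def test_bridge_graph_gives_k5_then_k4(self):
        complexes = find_complexes(bridge_graph())
        assert len(complexes) == 2
        assert complexes[0].members == {"a0", "a1", "a2", "a3", "a4"}
        assert complexes[1].members == {"b0", "b1", "b2", "b3"}
        assert complexes[0].score > complexes[1].score

    def test_path_graph_has_no_two_core(self):
        assert find_complexes(nx.path_graph(10)) == []

    def test_complexes_verify_own_postconditions(self):
        graph, _ = gen_cluster_graph(SyntheticSpec(seed=7))
        for c in find_complexes(graph):
            sub = graph.subgraph(c.members)
            assert nx.is_connected(sub)
            assert c.seed in c.members
            assert nx.k_core(sub, k=2).number_of_nodes() > 0
            n = len(c.members)
            density = 2 * sub.number_of_edges() / (n * (n - 1)) if n > 1 else 0
            assert c.score == pytest.approx(density * n)

    def test_deterministic_output(self):
        graph, _ = gen_cluster_graph(SyntheticSpec(seed=3))
        first = find_complexes(graph)
        second = find_complexes(graph)
        assert [(c.seed, sorted(c.members)) for c in first] == [
            (c.seed, sorted(c.members)) for c in second
        ]

    def test_planted_blocks_recovered(self):
        spec = SyntheticSpec(seed=7)  # 4 blocks of 20/16/14/11, p_in=0.9, p_out=0.02
        graph, partition = gen_cluster_graph(spec)
        found = find_complexes(graph)
        assert len(found) >= 4
        for members in partition.values():
            best = max(
                len(members & c.members) / len(members | c.members) for c in found
            )
            assert best >= 0.8

    def test_triangle_block_recovered_exactly(self):
        spec = SyntheticSpec(seed=5, cluster_sizes=(3,), cluster_p_in=1.0,
                             cluster_p_out=0.0, n_cluster_background=0)
        graph, partition = gen_cluster_graph(spec)
        found = find_complexes(graph)
        assert len(found) == 1 and found[0].members == partition[0]

    def test_degenerate_equal_densities_does_not_crash(self):
        spec = SyntheticSpec(seed=9, cluster_p_in=0.05, cluster_p_out=0.05)
        graph, _ = gen_cluster_graph(spec)
        find_complexes(graph)  # no guarantee, just no crash

    def test_haircut_removes_pendants(self):
        g = nx.complete_graph(4)
        g.add_edge(0, "pendant")
        with_haircut = find_complexes(g, MCODEParams(haircut=True))
        assert with_haircut[0].members == {0, 1, 2, 3}


class TestBuildHubGraph:
    def make_table(self, cores):
        return select_hubs(cores, HubParams(k_min=2, evidence_min=2))

    def test_isolated_hubs_no_edges(self):
        cores = {
            "C1": Interactome("C1", {"A": 2, "B": 2}),
            "C2": Interactome("C2", {"A": 2, "B": 2}),
        }
        # drop the snapshots when building: no supporting pairs -> no edges
        graph = build_hub_graph(self.make_table(cores), cores, [], evidence_min=2)
        assert graph.number_of_edges() == 0
        assert {"A", "B"} <= set(graph.nodes)

    def test_boundary_evidence_included(self):
        cores = {
            "C1": Interactome("C1", {"A": 2, "B": 2}),
            "C2": Interactome("C2", {"A": 2, "B": 2}),
        }
        graph = build_hub_graph(
            self.make_table(cores), cores, cores.values(), evidence_min=2
        )
        assert graph.has_edge("C1", "A") and graph.has_edge("C2", "B")

    def test_edge_set_matches_record_scan(self, preset, preset_cores):
        table = select_hubs(preset_cores)
        graph = build_hub_graph(table, preset_cores, preset_cores.values(), 2)
        nodes = set(graph.nodes)
        expected = set()
        for core, interactome in preset_cores.items():
            for partner, evidence in interactome.partners.items():
                if core in nodes and partner in nodes and evidence >= 2:
                    expected.add(frozenset((core, partner)))
        assert {frozenset(e) for e in graph.edges} == expected


class TestTopology:
    def test_k3_clustering_and_path_length(self):
        topo = topology_summary(nx.complete_graph(3), rewires=0)
        assert topo.average_clustering == pytest.approx(1.0)
        assert topo.characteristic_path_length == pytest.approx(1.0)

    def test_p3_zero_clustering(self):
        assert topology_summary(nx.path_graph(3), rewires=0).average_clustering == 0.0

    def test_sigma_none_for_tiny_graph(self):
        assert topology_summary(nx.complete_graph(3), rewires=5).small_world_sigma is None

    def test_small_world_generator_has_sigma_above_one(self):
        # statistical check over 20 seeded small-world graphs
        sigmas = [
            topology_summary(
                nx.watts_strogatz_graph(50, 6, 0.1, seed=s), rewires=5, seed=s
            ).small_world_sigma
            for s in range(20)
        ]
        assert all(s is not None for s in sigmas)
        assert sum(s > 1 for s in sigmas) >= 19
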