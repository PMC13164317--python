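"""Hub-network construction and topology metrics.

The hub graph is a simple undirected graph over the selected hubs plus the
core proteins.  An edge is drawn between two nodes iff the pair co-occurs in
the supplied interaction data with evidence >= ``evidence_min``; when the
same pair is seen from several interactome snapshots the maximum evidence
count is kept (snapshots overlap in their underlying records, so summing
would double-count).

The topology summary reports average clustering, characteristic path length
on the largest connected component, and a small-world sigma computed against
a degree-preserving rewired ensemble:

    sigma = (C / <C_rand>) / (L / <L_rand>)

sigma > 1 indicates small-world structure (clustering well above a random
graph of identical degree sequence at comparable path length).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .hubs import HubTable
from .types import Interactome


def build_hub_graph(
    hubs: HubTable,
    cores: Mapping[str, Interactome],
    all_interactions: Iterable[Interactome],
    evidence_min: int = 2,
) -> nx.Graph:
    """Build the hub interaction graph.

    Nodes are the hub proteins plus the core (focal) proteins; node attribute
    ``core_count`` carries each hub's qualifying-core count (cores get -1 as
    a sentinel).  Edges require evidence >= evidence_min in the union of the
    supplied interactomes.  Self-loops never occur (Interactome forbids them).
    """
    graph = nx.Graph()
    core_proteins = {inter.focal for inter in cores.values()}
    for core in sorted(core_proteins):
        graph.add_node(core, core_count=-1, is_core=True)
    for record in hubs.records:
        if record.is_hub:
            graph.add_node(record.protein, core_count=record.core_count, is_core=False)
    nodes = set(graph.nodes)

    best: Dict[Tuple[str, str], int] = {}
    for interactome in all_interactions:
        if interactome.focal not in nodes:
            continue
        for partner, evidence in interactome.partners.items():
            if partner not in nodes:
                continue
            key = tuple(sorted((interactome.focal, partner)))
            best[key] = max(best.get(key, 0), evidence)
    for (u, v), evidence in best.items():
        if evidence >= evidence_min:
            graph.add_edge(u, v, evidence=evidence)
    return graph


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    average_clustering: float
    characteristic_path_length: Optional[float]
    small_world_sigma: Optional[float]


def _clustering_and_path(graph: nx.Graph) -> Tuple[float, Optional[float]]:
    c = nx.average_clustering(graph) if graph.number_of_nodes() > 0 else 0.0
    components = [graph.subgraph(cc) for cc in nx.connected_components(graph)]
    largest = max(components, key=len, default=None)
    if largest is None or largest.number_of_nodes() < 2:
        return c, None
    return c, nx.average_shortest_path_length(largest)


def topology_summary(graph: nx.Graph, rewires: int = 20, seed: int = 0) -> TopologySummary:
    """Topology metrics with a seeded degree-preserving null ensemble.

    sigma is None when the graph has < 4 nodes, no rewires are requested, or
    the rewired ensemble degenerates (zero mean clustering or path length).
    """
    if rewires < 0:
        raise ValueError("rewires must be >= 0")
    c, path_length = _clustering_and_path(graph)
    summary = TopologySummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        average_clustering=c,
        characteristic_path_length=path_length,
        small_world_sigma=None,
    )
    if graph.number_of_nodes() < 4 or graph.number_of_edges() < 2 or rewires == 0:
        return summary
    if path_length is None:
        return summary
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    n_swaps = max(1, 10 * graph.number_of_edges())
    for _ in range(rewires):
        rewired = nx.Graph(graph)
        try:
            nx.double_edge_swap(
                rewired,
                nswap=n_swaps,
                max_tries=100 * n_swaps,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except nx.NetworkXError:
            continue
        cr, lr = _clustering_and_path(rewired)
        if lr is not None:
            c_rand.append(cr)
            l_rand.append(lr)
    if not c_rand:
        return summary
    mean_c, mean_l = float(np.mean(c_rand)), float(np.mean(l_rand))
    if mean_c <= 0 or mean_l <= 0:
        return summary
    summary.small_world_sigma = (c / mean_c) / (path_length / mean_l)
    return summary
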