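"""A from-scratch MCODE (Molecular Complex Detection) implementation.

MCODE finds locally dense regions of a simple undirected graph in three
stages:

1. *Vertex weighting* — each vertex is scored by the density of the highest
   k-core of its closed neighborhood, scaled by that core's k.  Vertices of
   degree below ``degree_cutoff`` get weight 0.
2. *Complex prediction* — starting from the highest-weight unassigned vertex,
   a complex is grown outward; a neighbor joins iff its weight exceeds
   ``(1 - node_score_cutoff) x seed weight`` and lies within ``max_depth``
   of the seed.  A vertex belongs to at most one complex at this stage.
3. *Post-processing* — complexes that do not contain a ``k_core``-core are
   discarded; optional *fluff* adds boundary neighbors whose closed
   neighborhood density exceeds ``fluff_density_cutoff`` (fluffed vertices
   may be shared); optional *haircut* then removes singly connected members.

Complexes are ranked by score = density x size, descending.  All ties
(seed order, neighbor visitation, ranking) are broken lexicographically by
vertex label so identical inputs always yield identical ordered output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set

import networkx as nx


@dataclass
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = False
    fluff: bool = False
    fluff_density_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")


@dataclass
class MCODEComplex:
    members: Set[str]
    seed: str
    score: float

    def __len__(self) -> int:
        return len(self.members)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weight(graph: nx.Graph, vertex, degree_cutoff: int = 2) -> float:
    """Core-clustering weight of one vertex.

    weight = k x density of the highest k-core of the closed neighborhood;
    0 for vertices of degree < degree_cutoff.
    """
    if graph.degree(vertex) < degree_cutoff:
        return 0.0
    closed = set(graph.neighbors(vertex)) | {vertex}
    neighborhood = graph.subgraph(closed)
    core_numbers = nx.core_number(neighborhood)
    k_max = max(core_numbers.values())
    if k_max == 0:
        return 0.0
    main_core = neighborhood.subgraph(
        [v for v, k in core_numbers.items() if k >= k_max]
    )
    return k_max * _density(main_core)


def _all_weights(graph: nx.Graph, degree_cutoff: int) -> Dict:
    return {v: vertex_weight(graph, v, degree_cutoff) for v in graph.nodes}


def find_complexes(graph: nx.Graph, params: Optional[MCODEParams] = None) -> List[MCODEComplex]:
    """Run the full MCODE pipeline and return ranked complexes."""
    params = params or MCODEParams()
    if graph.number_of_nodes() == 0:
        return []
    weights = _all_weights(graph, params.degree_cutoff)

    # stage 2: greedy seeded expansion, highest weight first
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: Set = set()
    raw: List[tuple] = []  # (seed, member set)
    for seed in order:
        if seed in assigned:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            next_frontier = []
            for v in frontier:
                for w in sorted(graph.neighbors(v), key=str):
                    if w in members or w in assigned:
                        continue
                    if weights[w] > threshold:
                        members.add(w)
                        next_frontier.append(w)
            frontier = next_frontier
            depth += 1
        assigned |= members
        raw.append((seed, members))

    # stage 3: k-core filter, then optional fluff, then optional haircut
    complexes: List[MCODEComplex] = []
    for seed, members in raw:
        sub = graph.subgraph(members)
        if nx.k_core(sub, k=params.k_core).number_of_nodes() == 0:
            continue
        if params.fluff:
            extra = set()
            for v in sorted(members, key=str):
                for w in graph.neighbors(v):
                    if w in members or w in extra:
                        continue
                    closed = set(graph.neighbors(w)) | {w}
                    if _density(graph.subgraph(closed)) > params.fluff_density_cutoff:
                        extra.add(w)
            members = members | extra
            sub = graph.subgraph(members)
        if params.haircut:
            keep = {v for v in members if sub.degree(v) > 1}
            if not keep:
                continue
            members = keep
            sub = graph.subgraph(members)
            if seed not in members:
                # the seed was singly connected; promote the heaviest survivor
                seed = min(members, key=lambda v: (-weights[v], str(v)))
        score = _density(sub) * len(members)
        complexes.append(MCODEComplex(members=set(members), seed=seed, score=score))

    complexes.sort(key=lambda c: (-c.score, -len(c.members), str(c.seed)))
    return complexes
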