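"""Set algebra over interactomes and proteome lists.

Overlaps at this stage are computed on partner-symbol sets only; evidence
counts play no role here (evidence filtering belongs to hub selection).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .types import ProteinSet


def overlap(a: ProteinSet, b: ProteinSet) -> ProteinSet:
    """Intersection of two protein sets under normalized symbols."""
    return ProteinSet(name=f"{a.name}&{b.name}", members=a.members & b.members)


def union(sets: Sequence[ProteinSet], name: str = "union") -> ProteinSet:
    members: Set[str] = set()
    for s in sets:
        members |= s.members
    return ProteinSet(name=name, members=members)


def venn3(a: ProteinSet, b: ProteinSet, c: ProteinSet) -> Dict[str, Set[str]]:
    """Partition a ∪ b ∪ c into the 7 disjoint Venn regions.

    Region keys are '&'-joined sorted subsets of the input names, e.g.
    ``"A"``, ``"A&B"``, ``"A&B&C"``.  Regions are pairwise disjoint and
    their union equals a ∪ b ∪ c.
    """
    names = [a.name, b.name, c.name]
    if len(set(names)) != 3:
        raise ValueError(f"venn3 requires three distinct set names, got {names}")
    sets = {a.name: a.members, b.name: b.members, c.name: c.members}
    regions: Dict[str, Set[str]] = {}
    for r in range(1, 4):
        for subset in combinations(sorted(names), r):
            inside = set.intersection(*(sets[n] for n in subset))
            outside: Set[str] = set()
            for n in names:
                if n not in subset:
                    outside |= sets[n]
            regions["&".join(subset)] = inside - outside
    return regions


@dataclass
class OverlapMatrix:
    """Pairwise intersection counts: entry (i, j) = |set_i ∩ set_j|.

    Symmetric with |set_i| on the diagonal.
    """

    labels: List[str]
    counts: np.ndarray

    def to_rows(self) -> List[Tuple]:
        rows = []
        for i, label in enumerate(self.labels):
            rows.append((label, *self.counts[i].tolist()))
        return rows


def overlap_matrix(sets: Sequence[ProteinSet]) -> OverlapMatrix:
    """Pairwise overlap-count matrix over >= 2 named sets."""
    if len(sets) < 2:
        raise ValueError("overlap_matrix needs at least 2 sets")
    labels = [s.name for s in sets]
    if len(set(labels)) != len(labels):
        seen = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate set names: {seen}")
    n = len(sets)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(sets[i].members)
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = len(sets[i].members & sets[j].members)
    return OverlapMatrix(labels=labels, counts=counts)
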