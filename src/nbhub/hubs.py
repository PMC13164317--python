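"""Hub discovery: evidence filtering and the qualifying-core count rule.

A *hub* is a protein found in at least ``k_min`` evidence-filtered core
interactomes — partners supported by fewer than ``evidence_min`` distinct
(publication, experimental system) records are discarded before counting.
The defaults (k_min=4, evidence_min=2) encode the rationale that one or two
core associations, or single-record evidence, are too weak to indicate
genuine residency in the organelle's neighborhood.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .types import Interactome


@dataclass
class HubParams:
    k_min: int = 4
    evidence_min: int = 2
    exclude_cores_as_candidates: bool = True

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.evidence_min < 1:
            raise ValueError(f"evidence_min must be >= 1, got {self.evidence_min}")


@dataclass
class HubRecord:
    protein: str
    qualifying_cores: List[str]
    is_hub: bool

    @property
    def core_count(self) -> int:
        return len(self.qualifying_cores)


@dataclass
class HubTable:
    """Per-candidate qualifying-core counts, ordered by descending count then symbol."""

    records: List[HubRecord] = field(default_factory=list)
    params: HubParams = field(default_factory=HubParams)

    @property
    def hubs(self) -> List[str]:
        return [r.protein for r in self.records if r.is_hub]

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self) -> List[Tuple]:
        return [
            (r.protein, r.core_count, ",".join(r.qualifying_cores), r.is_hub)
            for r in self.records
        ]


def filter_by_evidence(interactome: Interactome, evidence_min: int) -> Interactome:
    """Drop partners supported by fewer than ``evidence_min`` records."""
    if evidence_min < 1:
        raise ValueError(f"evidence_min must be >= 1, got {evidence_min}")
    return Interactome(
        focal=interactome.focal,
        partners={p: c for p, c in interactome.partners.items() if c >= evidence_min},
    )


def select_hubs(cores: Mapping[str, Interactome], params: HubParams | None = None) -> HubTable:
    """Apply the hub rule across a set of core interactomes.

    Each candidate's ``core_count`` is the number of cores whose
    evidence-filtered partner set contains it; candidates with
    ``core_count >= k_min`` are hubs.  Core proteins themselves are excluded
    from the candidate universe unless ``exclude_cores_as_candidates`` is off.
    Output order is deterministic: descending core_count, then symbol.
    """
    params = params or HubParams()
    if params.k_min > len(cores):
        raise ValueError(
            f"k_min={params.k_min} exceeds the number of cores supplied ({len(cores)})"
        )
    filtered = {
        name: filter_by_evidence(inter, params.evidence_min)
        for name, inter in cores.items()
    }
    core_proteins = {inter.focal for inter in cores.values()} | set(cores)
    candidates: Dict[str, List[str]] = {}
    for core_name in sorted(filtered):
        for partner in filtered[core_name].partners:
            if params.exclude_cores_as_candidates and partner in core_proteins:
                continue
            candidates.setdefault(partner, []).append(core_name)
    records = [
        HubRecord(
            protein=protein,
            qualifying_cores=sorted(core_names),
            is_hub=len(core_names) >= params.k_min,
        )
        for protein, core_names in candidates.items()
    ]
    records.sort(key=lambda r: (-r.core_count, r.protein))
    return HubTable(records=records, params=params)


def hub_sensitivity(
    cores: Mapping[str, Interactome],
    k_range: Sequence[int],
    evidence_range: Sequence[int],
    exclude_cores_as_candidates: bool = True,
) -> List[Tuple[int, int, int]]:
    """Hub counts over a (k_min, evidence_min) grid: rows (k, evidence, n_hubs).

    Hub count is weakly decreasing in both thresholds — the scan makes the
    threshold choice inspectable instead of asserted.
    """
    if not k_range or not evidence_range:
        raise ValueError("k_range and evidence_range must be nonempty")
    rows = []
    for evidence_min in sorted(evidence_range):
        for k_min in sorted(k_range):
            params = HubParams(
                k_min=k_min,
                evidence_min=evidence_min,
                exclude_cores_as_candidates=exclude_cores_as_candidates,
            )
            rows.append((k_min, evidence_min, len(select_hubs(cores, params).hubs)))
    return rows
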