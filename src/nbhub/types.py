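"""Core in-memory containers shared by every pipeline stage.

All gene/protein identifiers are *normalized symbols*: uppercased, with
surrounding whitespace stripped.  Normalization happens once, at the I/O
boundary, so downstream set algebra can rely on plain string equality.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol (strip surrounding whitespace, uppercase)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """A single interaction evidence record (one row of an interaction table)."""

    symbol_a: str
    symbol_b: str
    experimental_system: str
    publication_id: str
    organism_a: Optional[int] = None
    organism_b: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.symbol_a or not self.symbol_b:
            raise ValueError("interaction record requires two non-empty symbols")


@dataclass
class Interactome:
    """A focal protein's partner set with per-pair evidence counts.

    ``partners`` maps each partner symbol to the number of distinct
    (publication, experimental system) records supporting the pair.
    The focal protein never appears among its own partners.
    """

    focal: str
    partners: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.focal = normalize_symbol(self.focal)
        if self.focal in self.partners:
            raise ValueError(f"self-loop: {self.focal} listed as its own partner")
        for partner, count in self.partners.items():
            if count < 1:
                raise ValueError(f"evidence count for {partner} must be >= 1, got {count}")

    @property
    def partner_set(self) -> Set[str]:
        return set(self.partners)

    def __len__(self) -> int:
        return len(self.partners)


@dataclass
class ProteinSet:
    """A named set of normalized gene symbols."""

    name: str
    members: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.members = {normalize_symbol(m) for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members


@dataclass
class GeneSetLibrary:
    """A gene-set library (GMT-style): term label -> member set, plus a universe.

    The universe defaults to the union of all term members; a user-supplied
    background replaces it wholesale.  Every term must be a non-empty subset
    of the universe.
    """

    name: str
    terms: Dict[str, Set[str]]
    universe: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.terms.values()) if self.terms else set()
        for label, members in self.terms.items():
            if not members:
                raise ValueError(f"empty term: {label!r}")
            if not members <= self.universe:
                missing = sorted(members - self.universe)[:3]
                raise ValueError(
                    f"term {label!r} has members outside the universe (e.g. {missing})"
                )

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class ScoreTable:
    """Per-protein scalar predictor scores in [0, 1].

    ``scores[protein][predictor]`` is the score; a missing predictor key is an
    explicit absence (never coerced to 0).
    """

    scores: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def get(self, protein: str, predictor: str) -> Optional[float]:
        return self.scores.get(normalize_symbol(protein), {}).get(predictor)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ResidueTrack:
    """An ordered per-residue score profile for one protein and one predictor."""

    protein: str
    predictor: str
    scores: List[float]

    def __post_init__(self) -> None:
        self.protein = normalize_symbol(self.protein)
        if len(self.scores) < 1:
            raise ValueError(f"empty residue track for {self.protein}")
        for i, s in enumerate(self.scores):
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"residue score out of [0,1] for {self.protein}/{self.predictor} "
                    f"at position {i + 1}: {s}"
                )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class PTMAnnotation:
    """Tri-state SUMO/ubiquitin flags per protein.

    Values are ``True``/``False``/``None`` (unknown).  Unknown is preserved —
    it is never silently collapsed to ``False`` in summaries.
    """

    flags: Dict[str, Dict[str, Optional[bool]]] = field(default_factory=dict)

    def get(self, protein: str, modification: str) -> Optional[bool]:
        return self.flags.get(normalize_symbol(protein), {}).get(modification)


def as_protein_set(name: str, interactome: Interactome) -> ProteinSet:
    """View an interactome's partner set as a named ProteinSet."""
    return ProteinSet(name=name, members=set(interactome.partners))
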