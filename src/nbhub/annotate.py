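"""Per-protein consensus annotation from predictor scores.

Three liquid-liquid phase separation (LLPS) calling schemes run side by side:

* single-predictor granule propensity: LLPS iff score > 0.5 (strict);
* a three-band phase-separation classifier: likely iff score > 0.61,
  non-LLPS iff score < 0.36, otherwise unlikely (both endpoints fall in the
  middle band);
* a two-predictor consensus: LLPS iff sequence-based score > 0.5 AND
  condensate-propensity score > 0.6; non-LLPS iff both fail; *controversial*
  iff exactly one passes.

Droplet roles: a protein is a *driver* iff its overall condensation
propensity pLLPS >= 0.60 (inclusive); otherwise a *client* iff it carries a
droplet-promoting region, i.e. a run of at least ``min_region_length``
consecutive residues with per-residue droplet propensity pDP >= 0.60
(inclusive).

Disorder: PPIDR is the percentage of residues with per-residue disorder
score strictly > 0.5; < 10% is highly ordered, 10-30% (boundaries included)
moderately disordered, > 30% highly disordered.

Any missing required score yields the label ``unknown`` — never a default
class — and unknown rows are excluded from summary counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from .hubs import HubTable
from .types import PTMAnnotation, ResidueTrack, ScoreTable

# canonical predictor keys in ScoreTable entries
CATGRANULE = "catgranule"
PSPHUNTER = "psphunter"
PSPREDICTOR = "pspredictor"
FUZDROP_PLLPS = "fuzdrop_pllps"

# canonical ResidueTrack predictor names
DISORDER_TRACK = "vsl2"
PDP_TRACK = "fuzdrop_pdp"

UNKNOWN = "unknown"

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def _load_pka() -> Dict[str, Tuple[float, int]]:
    table: Dict[str, Tuple[float, int]] = {}
    with resources.files("nbhub.data").joinpath("pka.tsv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            group, pka, sign = line.split("\t")
            table[group] = (float(pka), 1 if sign == "+" else -1)
    return table


PKA_TABLE = _load_pka()


@dataclass
class LLPSCall:
    catgranule_label: str = UNKNOWN       # LLPS | non-LLPS | unknown
    psphunter_label: str = UNKNOWN        # likely | unlikely | non-LLPS | unknown
    combined_label: str = UNKNOWN         # LLPS | non-LLPS | controversial | unknown
    role_label: str = UNKNOWN             # driver | client | neither | unknown


@dataclass
class DisorderCall:
    ppidr: float
    disorder_class: str


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def llps_consensus(scores: Mapping[str, float]) -> LLPSCall:
    """Apply the three LLPS schemes to one protein's predictor scores."""
    call = LLPSCall()
    cat = scores.get(CATGRANULE)
    if cat is not None:
        call.catgranule_label = "LLPS" if cat > 0.5 else "non-LLPS"
    hunter = scores.get(PSPHUNTER)
    if hunter is not None:
        if hunter > 0.61:
            call.psphunter_label = "likely"
        elif hunter < 0.36:
            call.psphunter_label = "non-LLPS"
        else:
            call.psphunter_label = "unlikely"
    psp, fuz = scores.get(PSPREDICTOR), scores.get(FUZDROP_PLLPS)
    if psp is not None and fuz is not None:
        passes = (psp > 0.5) + (fuz > 0.6)
        call.combined_label = {2: "LLPS", 1: "controversial", 0: "non-LLPS"}[passes]
    return call


def llps_role(
    pllps: Optional[float],
    pdp_track: Optional[ResidueTrack],
    min_region_length: int = 10,
) -> str:
    """Driver/client/neither assignment (see module docstring for the rule)."""
    if min_region_length < 1:
        raise ValueError("min_region_length must be >= 1")
    if pllps is None:
        return UNKNOWN
    if pllps >= 0.60:
        return "driver"
    if pdp_track is None:
        return UNKNOWN
    run = best = 0
    for score in pdp_track.scores:
        run = run + 1 if score >= 0.60 else 0
        best = max(best, run)
    return "client" if best >= min_region_length else "neither"


def ppidr(track: ResidueTrack) -> DisorderCall:
    """Percentage of predicted intrinsically disordered residues and its class."""
    disordered = sum(1 for s in track.scores if s > 0.5)
    pct = 100.0 * disordered / len(track.scores)
    if pct < 10.0:
        cls = "highly ordered"
    elif pct <= 30.0:
        cls = "moderately disordered"
    else:
        cls = "highly disordered"
    return DisorderCall(ppidr=pct, disorder_class=cls)


# ---------------------------------------------------------------------------
# physico-chemical properties
# ---------------------------------------------------------------------------

def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    for i, residue in enumerate(sequence):
        if residue not in KYTE_DOOLITTLE:
            raise ValueError(f"non-standard residue {residue!r} at position {i + 1}")
    return sequence


def gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value per residue."""
    sequence = _validate_sequence(sequence)
    return sum(KYTE_DOOLITTLE[r] for r in sequence) / len(sequence)


def charge_at_ph(sequence: str, ph: float = 7.0) -> float:
    """Net charge at the given pH by Henderson-Hasselbalch summation.

    Terms: the N-terminus, the C-terminus, and ionizable side chains
    (D, E, C, Y, H, K, R), each using the shipped pKa table.  Basic groups
    contribute +1/(1 + 10^(pH - pKa)), acidic groups -1/(1 + 10^(pKa - pH)).
    """
    sequence = _validate_sequence(sequence)
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH must lie in [0, 14], got {ph}")

    def group_charge(group: str) -> float:
        pka, sign = PKA_TABLE[group]
        if sign > 0:
            return 1.0 / (1.0 + 10.0 ** (ph - pka))
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    charge = group_charge("nterm") + group_charge("cterm")
    for residue in sequence:
        if residue in PKA_TABLE:
            charge += group_charge(residue)
    return charge


# ---------------------------------------------------------------------------
# the hub annotation table
# ---------------------------------------------------------------------------

_SUMMARY_KEYS = (
    "n_llps_catgranule",
    "n_llps_psphunter",
    "n_llps_combined",
    "n_controversial",
    "n_driver",
    "n_client",
    "n_driver_or_client",
    "n_highly_ordered",
    "n_moderately_disordered",
    "n_highly_disordered",
    "n_disordered",
    "n_sumo",
    "n_ubiquitin",
)


def annotate_hubs(
    hubs: HubTable,
    scores: ScoreTable,
    tracks: Mapping[Tuple[str, str], ResidueTrack],
    ptm: PTMAnnotation,
    sequences: Optional[Mapping[str, str]] = None,
    disorder_predictor: str = DISORDER_TRACK,
    pdp_predictor: str = PDP_TRACK,
    min_region_length: int = 10,
    ph: float = 7.0,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Build the per-hub annotation table and its category summary.

    One row per hub with all calls; a missing input yields ``unknown`` for
    the affected label and the row is then excluded from that category's
    summary count.  ``n_disordered`` counts moderately + highly disordered
    (fully or partially disordered proteins).
    """
    hub_proteins = hubs.hubs
    if not hub_proteins:
        raise ValueError("hub set is empty; nothing to annotate")
    sequences = sequences or {}
    rows: List[dict] = []
    for protein in hub_proteins:
        entry = scores.scores.get(protein, {})
        call = llps_consensus(entry)
        call.role_label = llps_role(
            entry.get(FUZDROP_PLLPS),
            tracks.get((protein, pdp_predictor)),
            min_region_length=min_region_length,
        )
        disorder_track = tracks.get((protein, disorder_predictor))
        if disorder_track is not None:
            disorder = ppidr(disorder_track)
            ppidr_value, disorder_class = disorder.ppidr, disorder.disorder_class
        else:
            ppidr_value, disorder_class = float("nan"), UNKNOWN
        sequence = sequences.get(protein)
        rows.append(
            {
                "protein": protein,
                "catgranule_label": call.catgranule_label,
                "psphunter_label": call.psphunter_label,
                "combined_label": call.combined_label,
                "role_label": call.role_label,
                "ppidr": ppidr_value,
                "disorder_class": disorder_class,
                "sumo": ptm.get(protein, "sumo"),
                "ubiquitin": ptm.get(protein, "ubiquitin"),
                "gravy": gravy(sequence) if sequence else float("nan"),
                "charge": charge_at_ph(sequence, ph) if sequence else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    summary = {key: 0 for key in _SUMMARY_KEYS}
    for row in rows:
        summary["n_llps_catgranule"] += row["catgranule_label"] == "LLPS"
        summary["n_llps_psphunter"] += row["psphunter_label"] == "likely"
        summary["n_llps_combined"] += row["combined_label"] == "LLPS"
        summary["n_controversial"] += row["combined_label"] == "controversial"
        summary["n_driver"] += row["role_label"] == "driver"
        summary["n_client"] += row["role_label"] == "client"
        summary["n_driver_or_client"] += row["role_label"] in ("driver", "client")
        summary["n_highly_ordered"] += row["disorder_class"] == "highly ordered"
        summary["n_moderately_disordered"] += row["disorder_class"] == "moderately disordered"
        summary["n_highly_disordered"] += row["disorder_class"] == "highly disordered"
        summary["n_disordered"] += row["disorder_class"] in (
            "moderately disordered",
            "highly disordered",
        )
        summary["n_sumo"] += row["sumo"] is True
        summary["n_ubiquitin"] += row["ubiquitin"] is True
    return table, summary
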