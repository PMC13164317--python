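"""Seeded generators for every pipeline input, with planted ground truth.

Every generator is a pure function of (spec, seed): the same spec always
yields byte-identical files and an identical ground-truth ledger.  The
default spec mirrors the shape of the study design the pipeline implements:
10 core interactomes, 61 planted hubs among 500 decoys, a 4-block planted
cluster graph, one planted enriched term, and per-protein predictor scores
sampled on the correct side of every documented classification threshold.

Planted structure
-----------------
* *hubs* appear in >= k_min cores, every such pair supported by >=
  evidence_min distinct (publication, experimental system) records;
* *decoys* violate at least one of the two conditions — either they reach
  too few cores, or they reach enough cores but with sub-threshold evidence
  in all but <= k_min - 1 of them; the ledger records which;
* duplicate evidence rows are emitted deliberately to exercise
  distinct-record counting;
* symbols are synthetic (HUB001, DEC001, CORE01, BG0001 ...) so nothing can
  accidentally depend on real gene identity.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np

from . import io as nbio
from .types import (
    GeneSetLibrary,
    InteractionRecord,
    Interactome,
    PTMAnnotation,
    ProteinSet,
    ResidueTrack,
    ScoreTable,
)

_SYSTEMS = (
    "Two-hybrid",
    "Affinity Capture-MS",
    "Reconstituted Complex",
    "Co-fractionation",
)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults mirror the target shape."""

    seed: int = 42
    # interactomes / hub benchmark
    n_cores: int = 10
    n_planted_hubs: int = 61
    n_decoys: int = 500
    n_background_per_core: int = 60
    k_min: int = 4
    evidence_min: int = 2
    evidence_geom_p: float = 0.6        # extra-record tail: most pairs 2-3 records
    duplicate_row_rate: float = 0.2
    # proteome lists
    nb_proteome_size: int = 205
    cajal_proteome_size: int = 100
    aging_list_size: int = 120
    # cluster benchmark
    cluster_sizes: Tuple[int, ...] = (20, 16, 14, 11)
    cluster_p_in: float = 0.9
    cluster_p_out: float = 0.02
    n_cluster_background: int = 15
    # gene-set library benchmark
    n_terms: int = 30
    term_size_range: Tuple[int, int] = (10, 40)
    geneset_universe_size: int = 500
    query_size: int = 20
    planted_effect: float = 0.8         # fraction of the query inside the planted term
    # tracks / scores
    track_length_range: Tuple[int, int] = (80, 300)
    min_region_length: int = 10

    def __post_init__(self) -> None:
        if self.n_planted_hubs < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        if self.k_min > self.n_cores:
            raise ValueError(
                f"infeasible spec: k_min={self.k_min} > n_cores={self.n_cores}"
            )


def _core_names(spec: SyntheticSpec) -> List[str]:
    return [f"CORE{i + 1:02d}" for i in range(spec.n_cores)]


def _sample_evidence(rng: np.random.Generator, spec: SyntheticSpec, minimum: int) -> int:
    """Truncated-geometric evidence count >= minimum (long right tail)."""
    return minimum + int(rng.geometric(spec.evidence_geom_p)) - 1


# ---------------------------------------------------------------------------
# interactomes
# ---------------------------------------------------------------------------

def gen_interactomes(
    spec: SyntheticSpec,
) -> Tuple[Dict[str, Dict[str, int]], Dict]:
    """Generate per-core partner/evidence maps and the ground-truth ledger.

    Returns ``(core -> {partner: evidence}, ledger)``.  The ledger records
    the planted hub list and, for every decoy, its qualifying cores and
    which hub condition it violates.
    """
    rng = np.random.default_rng(spec.seed)
    cores = _core_names(spec)
    hubs = [f"HUB{i + 1:03d}" for i in range(spec.n_planted_hubs)]
    decoys = [f"DEC{i + 1:03d}" for i in range(spec.n_decoys)]
    partner_maps: Dict[str, Dict[str, int]] = {c: {} for c in cores}

    # cores interact among themselves (the organelle scaffold is dense)
    for i, a in enumerate(cores):
        for b in cores[i + 1 :]:
            if rng.random() < 0.5:
                evidence = _sample_evidence(rng, spec, spec.evidence_min)
                partner_maps[a][b] = evidence
                partner_maps[b][a] = evidence

    ledger: Dict = {
        "planted_hubs": list(hubs),
        "n_planted_hubs": len(hubs),
        "decoys": {},
        "core_names": cores,
    }

    for hub in hubs:
        n_qualifying = int(rng.integers(spec.k_min, spec.n_cores + 1))
        qualifying = sorted(
            rng.choice(cores, size=n_qualifying, replace=False).tolist()
        )
        for core in qualifying:
            partner_maps[core][hub] = _sample_evidence(rng, spec, spec.evidence_min)
        # optional sub-threshold appearances elsewhere
        for core in cores:
            if core not in qualifying and rng.random() < 0.2:
                partner_maps[core][hub] = 1

    for decoy in decoys:
        violation = str(rng.choice(["few_cores", "low_evidence"]))
        if violation == "few_cores":
            n_qualifying = int(rng.integers(0, spec.k_min))
            qualifying = sorted(
                rng.choice(cores, size=n_qualifying, replace=False).tolist()
            )
            for core in qualifying:
                partner_maps[core][decoy] = _sample_evidence(rng, spec, spec.evidence_min)
            if n_qualifying == 0:  # must appear somewhere to be a candidate
                core = str(rng.choice(cores))
                partner_maps[core][decoy] = 1
        else:
            # reaches >= k_min cores, but nearly all with single-record evidence
            n_cores_touched = int(rng.integers(spec.k_min, spec.n_cores + 1))
            touched = sorted(
                rng.choice(cores, size=n_cores_touched, replace=False).tolist()
            )
            n_qualifying = int(rng.integers(0, spec.k_min))
            qualifying = touched[:n_qualifying]
            for core in touched:
                if core in qualifying:
                    partner_maps[core][decoy] = _sample_evidence(
                        rng, spec, spec.evidence_min
                    )
                else:
                    partner_maps[core][decoy] = 1
        ledger["decoys"][decoy] = {
            "violation": violation,
            "qualifying_cores": qualifying,
        }

    # per-core private background partners (each appears in exactly one core,
    # so none can ever satisfy the multi-core hub condition)
    bg_counter = 0
    for core in cores:
        for _ in range(spec.n_background_per_core):
            bg_counter += 1
            partner_maps[core][f"BG{bg_counter:04d}"] = _sample_evidence(rng, spec, 1)

    ledger["n_partners_per_core"] = {c: len(partner_maps[c]) for c in cores}
    return partner_maps, ledger


def records_from_partner_map(
    focal: str,
    partners: Mapping[str, int],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> List[InteractionRecord]:
    """Expand a partner/evidence map into individual evidence rows.

    Each pair yields exactly ``evidence`` distinct (publication, system)
    records; some rows are then emitted twice and directions are shuffled,
    so distinct-record counting (not row counting) is required to recover
    the evidence values.
    """
    records: List[InteractionRecord] = []
    for partner in sorted(partners):
        evidence = partners[partner]
        for i in range(evidence):
            a, b = (focal, partner) if rng.random() < 0.5 else (partner, focal)
            record = InteractionRecord(
                symbol_a=a,
                symbol_b=b,
                experimental_system=_SYSTEMS[i % len(_SYSTEMS)],
                publication_id=f"PUB:{focal}:{partner}:{i + 1}",
                organism_a=9606,
                organism_b=9606,
            )
            records.append(record)
            if rng.random() < spec.duplicate_row_rate:
                records.append(record)  # deliberate duplicate row
    return records


# ---------------------------------------------------------------------------
# proteome and aging lists
# ---------------------------------------------------------------------------

def gen_protein_lists(
    spec: SyntheticSpec,
    partner_maps: Mapping[str, Dict[str, int]],
) -> Tuple[Dict[str, ProteinSet], Dict]:
    """Generate the organelle/Cajal proteome lists and two aging gene lists.

    The aging lists are seeded with part of the first-two-core overlap so
    the three-way intersection is nonempty, as in real senescence databases.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cores = _core_names(spec)
    all_partners = sorted(set().union(*(set(m) for m in partner_maps.values())))
    nb_proteome = ProteinSet(
        "nb_proteome",
        set(rng.choice(all_partners, size=min(spec.nb_proteome_size, len(all_partners)), replace=False).tolist()),
    )
    cajal = ProteinSet(
        "cajal_proteome",
        set(rng.choice(all_partners, size=min(spec.cajal_proteome_size, len(all_partners)), replace=False).tolist()),
    )
    shared = sorted(set(partner_maps[cores[0]]) & set(partner_maps[cores[1]]))
    aging_sets = {}
    for name, offset in (("cellage", 2), ("genage", 3)):
        rng_list = np.random.default_rng(spec.seed + offset)
        from_shared = rng_list.choice(
            shared, size=min(len(shared) // 3, spec.aging_list_size // 2), replace=False
        ).tolist()
        n_rest = spec.aging_list_size - len(from_shared)
        rest_pool = sorted(set(all_partners) - set(shared))
        from_rest = rng_list.choice(
            rest_pool, size=min(n_rest, len(rest_pool)), replace=False
        ).tolist()
        aging_sets[name] = ProteinSet(name, set(from_shared) | set(from_rest))
    lists = {"nb_proteome": nb_proteome, "cajal_proteome": cajal, **aging_sets}
    ledger = {
        "overlap_core1_core2": len(shared),
        "aging_overlap": len(
            set(shared) & (aging_sets["cellage"].members | aging_sets["genage"].members)
        ),
        "list_sizes": {name: len(s) for name, s in lists.items()},
    }
    return lists, ledger


# ---------------------------------------------------------------------------
# cluster benchmark graph
# ---------------------------------------------------------------------------

def gen_cluster_graph(spec: SyntheticSpec) -> Tuple[nx.Graph, Dict[int, Set[str]]]:
    """Planted-partition benchmark: dense blocks over a sparse background.

    Returns the graph and the planted partition block -> member set.
    Background nodes belong to no block (key -1 is not used; they are simply
    absent from the partition).
    """
    rng = np.random.default_rng(spec.seed + 10)
    nodes: List[str] = []
    partition: Dict[int, Set[str]] = {}
    counter = 0
    for block_id, size in enumerate(spec.cluster_sizes):
        members = set()
        for _ in range(size):
            counter += 1
            name = f"M{counter:04d}"
            nodes.append(name)
            members.add(name)
        partition[block_id] = members
    for _ in range(spec.n_cluster_background):
        counter += 1
        nodes.append(f"M{counter:04d}")

    block_of = {name: bid for bid, members in partition.items() for name in members}
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same_block = block_of.get(a) is not None and block_of.get(a) == block_of.get(b)
            p = spec.cluster_p_in if same_block else spec.cluster_p_out
            if rng.random() < p:
                graph.add_edge(a, b)
    return graph, partition


# ---------------------------------------------------------------------------
# gene-set library benchmark
# ---------------------------------------------------------------------------

def gen_geneset_library(
    spec: SyntheticSpec,
    planted: bool = True,
    seed: Optional[int] = None,
    universe: Optional[List[str]] = None,
    query: Optional[ProteinSet] = None,
) -> Tuple[GeneSetLibrary, ProteinSet, Optional[str]]:
    """A library with (optionally) one term enriched in the returned query.

    With ``planted=True`` a fraction ``planted_effect`` of the query is
    placed inside the term ``T_PLANTED``; all other terms are uniform draws,
    so the planted term should dominate the ranking.  With ``planted=False``
    everything is a uniform draw (the null used for calibration checks).
    A caller may supply its own gene universe and/or query set; by default a
    synthetic universe G0001.. is created and the query sampled from it.
    """
    rng = np.random.default_rng(spec.seed + 20 if seed is None else seed)
    if universe is None:
        universe = [f"G{i + 1:04d}" for i in range(spec.geneset_universe_size)]
    universe = sorted(universe)
    if query is None:
        query = ProteinSet(
            "query",
            set(rng.choice(universe, size=spec.query_size, replace=False).tolist()),
        )
    elif not query.members <= set(universe):
        raise ValueError("query must be a subset of the supplied universe")
    terms: Dict[str, Set[str]] = {}
    lo, hi = spec.term_size_range
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"T{t + 1:03d}"] = set(rng.choice(universe, size=size, replace=False).tolist())
    planted_label: Optional[str] = None
    if planted:
        planted_label = "T_PLANTED"
        n_inside = max(1, int(round(spec.planted_effect * len(query.members))))
        inside = rng.choice(sorted(query.members), size=n_inside, replace=False).tolist()
        outside_pool = sorted(set(universe) - query.members)
        size = int(rng.integers(lo, hi + 1))
        padding = rng.choice(
            outside_pool, size=max(0, size - n_inside), replace=False
        ).tolist()
        terms[planted_label] = set(inside) | set(padding)
    library = GeneSetLibrary(name="synthetic", terms=terms, universe=set(universe))
    return library, query, planted_label


# ---------------------------------------------------------------------------
# predictor scores, residue tracks, PTM flags, sequences
# ---------------------------------------------------------------------------

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _sample_track(
    rng: np.random.Generator,
    length: int,
    n_high: int,
    contiguous: bool,
    high_range=(0.62, 0.98),
    low_range=(0.02, 0.44),
) -> List[float]:
    """A track with exactly n_high values above threshold, placed contiguously
    (one run) or scattered with every run shorter than the region minimum."""
    scores = rng.uniform(*low_range, size=length)
    if n_high > 0:
        if contiguous:
            start = int(rng.integers(0, length - n_high + 1))
            positions = range(start, start + n_high)
        else:
            positions = rng.choice(length, size=n_high, replace=False)
        for p in positions:
            scores[p] = rng.uniform(*high_range)
    return [round(float(s), 4) for s in scores]


def gen_tracks_and_scores(
    spec: SyntheticSpec,
    proteins: List[str],
) -> Tuple[ScoreTable, Dict[Tuple[str, str], ResidueTrack], PTMAnnotation, Dict[str, str], Dict]:
    """Plant per-protein annotation labels and realize them as scores.

    For each protein a label is drawn per category and scores are sampled on
    the matching side of every documented threshold (with a comfortable
    margin, so float round-trips cannot flip a label).  The ledger records
    the intended labels and the per-category counts that the annotation
    stage must reproduce.
    """
    from .annotate import (
        CATGRANULE,
        FUZDROP_PLLPS,
        PDP_TRACK,
        DISORDER_TRACK,
        PSPHUNTER,
        PSPREDICTOR,
    )

    rng = np.random.default_rng(spec.seed + 30)
    scores = ScoreTable()
    tracks: Dict[Tuple[str, str], ResidueTrack] = {}
    ptm = PTMAnnotation()
    sequences: Dict[str, str] = {}
    labels: Dict[str, Dict[str, str]] = {}
    lo_len, hi_len = spec.track_length_range

    for protein in proteins:
        entry: Dict[str, float] = {}
        planted: Dict[str, str] = {}

        # single-predictor granule scheme
        if rng.random() < 0.64:
            entry[CATGRANULE] = round(float(rng.uniform(0.55, 0.98)), 4)
            planted["catgranule_label"] = "LLPS"
        else:
            entry[CATGRANULE] = round(float(rng.uniform(0.02, 0.45)), 4)
            planted["catgranule_label"] = "non-LLPS"

        # three-band scheme
        band = rng.choice(["likely", "unlikely", "non-LLPS"], p=[0.55, 0.25, 0.2])
        ranges = {"likely": (0.65, 0.98), "unlikely": (0.40, 0.58), "non-LLPS": (0.02, 0.32)}
        entry[PSPHUNTER] = round(float(rng.uniform(*ranges[band])), 4)
        planted["psphunter_label"] = str(band)

        # droplet role drives the condensation-propensity score
        role = str(rng.choice(["driver", "client", "neither"], p=[0.5, 0.35, 0.15]))
        length = int(rng.integers(lo_len, hi_len + 1))
        if role == "driver":
            entry[FUZDROP_PLLPS] = round(float(rng.uniform(0.64, 0.95)), 4)
            # droplet-promoting regions may or may not exist; irrelevant for the label
            n_high = int(rng.integers(0, spec.min_region_length))
            tracks[(protein, PDP_TRACK)] = ResidueTrack(
                protein, PDP_TRACK, _sample_track(rng, length, n_high, contiguous=False)
            )
        elif role == "client":
            entry[FUZDROP_PLLPS] = round(float(rng.uniform(0.05, 0.55)), 4)
            run = int(rng.integers(spec.min_region_length, spec.min_region_length + 15))
            tracks[(protein, PDP_TRACK)] = ResidueTrack(
                protein, PDP_TRACK, _sample_track(rng, length, min(run, length), contiguous=True)
            )
        else:
            entry[FUZDROP_PLLPS] = round(float(rng.uniform(0.05, 0.55)), 4)
            n_high = int(rng.integers(0, min(spec.min_region_length, length)))
            tracks[(protein, PDP_TRACK)] = ResidueTrack(
                protein, PDP_TRACK, _sample_track(rng, length, n_high, contiguous=False)
            )
        planted["role_label"] = role

        # two-predictor consensus: the condensation score is already fixed by
        # the role, so the consensus label follows from the sequence predictor
        fuz_passes = entry[FUZDROP_PLLPS] > 0.6
        if rng.random() < 0.62:
            entry[PSPREDICTOR] = round(float(rng.uniform(0.55, 0.98)), 4)
            psp_passes = True
        else:
            entry[PSPREDICTOR] = round(float(rng.uniform(0.02, 0.45)), 4)
            psp_passes = False
        planted["combined_label"] = {2: "LLPS", 1: "controversial", 0: "non-LLPS"}[
            int(fuz_passes) + int(psp_passes)
        ]

        # disorder class via an exactly-placed count of disordered residues
        disorder_class = str(
            rng.choice(
                ["highly ordered", "moderately disordered", "highly disordered"],
                p=[0.07, 0.23, 0.70],
            )
        )
        n_low_max = int(np.ceil(0.1 * length)) - 1          # pct < 10
        n_mod_max = int(np.floor(0.3 * length))             # pct <= 30
        if disorder_class == "highly ordered":
            n_dis = int(rng.integers(0, max(1, n_low_max + 1)))
        elif disorder_class == "moderately disordered":
            n_dis = int(rng.integers(max(0, int(np.ceil(0.1 * length))), n_mod_max + 1))
        else:
            n_dis = int(rng.integers(n_mod_max + 1, length + 1))
        tracks[(protein, DISORDER_TRACK)] = ResidueTrack(
            protein,
            DISORDER_TRACK,
            _sample_track(rng, length, n_dis, contiguous=False,
                          high_range=(0.55, 0.98), low_range=(0.02, 0.45)),
        )
        planted["disorder_class"] = disorder_class

        # tri-state PTM flags
        sumo = rng.choice(["true", "false", "unknown"], p=[0.7, 0.2, 0.1])
        ub = rng.choice(["true", "false", "unknown"], p=[0.25, 0.65, 0.1])
        ptm.flags[protein] = {
            "sumo": {"true": True, "false": False, "unknown": None}[str(sumo)],
            "ubiquitin": {"true": True, "false": False, "unknown": None}[str(ub)],
        }
        planted["sumo"] = str(sumo)
        planted["ubiquitin"] = str(ub)

        sequences[protein] = "".join(
            rng.choice(list(_AMINO_ACIDS), size=int(rng.integers(50, 200)))
        )
        scores.scores[protein] = entry
        labels[protein] = planted

    counts = {
        "n_llps_catgranule": sum(l["catgranule_label"] == "LLPS" for l in labels.values()),
        "n_llps_psphunter": sum(l["psphunter_label"] == "likely" for l in labels.values()),
        "n_llps_combined": sum(l["combined_label"] == "LLPS" for l in labels.values()),
        "n_controversial": sum(l["combined_label"] == "controversial" for l in labels.values()),
        "n_driver": sum(l["role_label"] == "driver" for l in labels.values()),
        "n_client": sum(l["role_label"] == "client" for l in labels.values()),
        "n_driver_or_client": sum(
            l["role_label"] in ("driver", "client") for l in labels.values()
        ),
        "n_highly_ordered": sum(l["disorder_class"] == "highly ordered" for l in labels.values()),
        "n_moderately_disordered": sum(
            l["disorder_class"] == "moderately disordered" for l in labels.values()
        ),
        "n_highly_disordered": sum(
            l["disorder_class"] == "highly disordered" for l in labels.values()
        ),
        "n_disordered": sum(
            l["disorder_class"] in ("moderately disordered", "highly disordered")
            for l in labels.values()
        ),
        "n_sumo": sum(l["sumo"] == "true" for l in labels.values()),
        "n_ubiquitin": sum(l["ubiquitin"] == "true" for l in labels.values()),
    }
    ledger = {"labels": labels, "annotation_counts": counts}
    return scores, tracks, ptm, sequences, ledger


# ---------------------------------------------------------------------------
# the full preset
# ---------------------------------------------------------------------------

def simulate(spec: SyntheticSpec, outdir: Path | str) -> Dict:
    """Emit every pipeline input file plus ``ledger.json`` under ``outdir``.

    Layout::

        outdir/
          cores/CORE01.txt ... CORE10.txt   (TAB3-style interaction tables)
          nb_proteome.txt cajal_proteome.txt cellage.txt genage.txt
          library.gmt
          scores.tsv tracks.tsv ptm.tsv sequences.fasta
          ledger.json
    """
    outdir = Path(outdir)
    (outdir / "cores").mkdir(parents=True, exist_ok=True)

    partner_maps, hub_ledger = gen_interactomes(spec)
    record_rng = np.random.default_rng(spec.seed + 40)
    for core in sorted(partner_maps):
        records = records_from_partner_map(core, partner_maps[core], spec, record_rng)
        nbio.write_interaction_table(outdir / "cores" / f"{core}.txt", core, records)

    lists, list_ledger = gen_protein_lists(spec, partner_maps)
    for name, protein_set in lists.items():
        nbio.write_protein_list(outdir / f"{name}.txt", protein_set)

    # the library spans the full interactome symbol universe, with the
    # planted term enriched in the planted hub set
    symbol_universe = sorted(
        set().union(*(set(m) for m in partner_maps.values())) | set(partner_maps)
    )
    library, query, planted_label = gen_geneset_library(
        spec,
        universe=symbol_universe,
        query=ProteinSet("planted_hubs", set(hub_ledger["planted_hubs"])),
    )
    nbio.write_gmt(outdir / "library.gmt", library)

    # annotation inputs cover the planted hubs (the pipeline's annotation targets)
    scores, tracks, ptm, sequences, annotation_ledger = gen_tracks_and_scores(
        spec, hub_ledger["planted_hubs"]
    )
    with (outdir / "scores.tsv").open("w") as fh:
        fh.write("#protein\tpredictor\tscore\n")
        for protein in sorted(scores.scores):
            for predictor in sorted(scores.scores[protein]):
                fh.write(f"{protein}\t{predictor}\t{scores.scores[protein][predictor]:g}\n")
    nbio.write_residue_tracks(outdir / "tracks.tsv", tracks)
    nbio.write_ptm_table(outdir / "ptm.tsv", ptm)
    nbio.write_fasta(outdir / "sequences.fasta", sequences)

    ledger = {
        **hub_ledger,
        **list_ledger,
        **annotation_ledger,
        "planted_term": planted_label,
        "enrichment_query": sorted(query.members),
        "spec": asdict(spec),
    }
    with (outdir / "ledger.json").open("w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # a ready-to-run pipeline config pointing at the generated files
    config_lines = ["cores:"]
    for core in sorted(partner_maps):
        config_lines.append(f"  {core}: cores/{core}.txt")
    config_lines += [
        "proteome_lists:",
        *(f"  {name}: {name}.txt" for name in sorted(lists)),
        "gmt: library.gmt",
        "scores: scores.tsv",
        "tracks: tracks.tsv",
        "ptm: ptm.tsv",
        "fasta: sequences.fasta",
        "overlap_pair: [CORE01, CORE02]",
        "aging_lists: [cellage, genage]",
        f"hub: {{k_min: {spec.k_min}, evidence_min: {spec.evidence_min}}}",
        f"min_region_length: {spec.min_region_length}",
        f"seed: {spec.seed}",
    ]
    (outdir / "config.yaml").write_text("\n".join(config_lines) + "\n")
    return ledger
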