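"""End-to-end orchestration: one config in, every stage output plus a run report.

Stage order: read inputs -> interactome overlaps (pairwise matrix, focal-pair
overlap, three-way aging Venn) -> hub selection -> hub network + MCODE
clustering + topology -> enrichment (global, per-cluster, aging subset) ->
per-hub annotation.  Every output is written in sorted order and the JSON
report has sorted keys, so a rerun with the same inputs, config and seed is
byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import __version__
from . import io as nbio
from .annotate import annotate_hubs
from .enrich import enrich
from .hubs import HubParams, hub_sensitivity, select_hubs
from .mcode import MCODEComplex, MCODEParams, find_complexes
from .network import build_hub_graph, topology_summary
from .overlap import overlap, overlap_matrix, union, venn3
from .types import GeneSetLibrary, ProteinSet, as_protein_set


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    cores: Dict[str, str]
    proteome_lists: Dict[str, str] = field(default_factory=dict)
    gmt: Optional[str] = None
    scores: Optional[str] = None
    tracks: Optional[str] = None
    ptm: Optional[str] = None
    fasta: Optional[str] = None
    overlap_pair: Optional[Tuple[str, str]] = None
    aging_lists: Tuple[str, str] = ("cellage", "genage")
    hub: HubParams = field(default_factory=HubParams)
    mcode: MCODEParams = field(default_factory=MCODEParams)
    enrich_top: int = 10
    min_region_length: int = 10
    ph: float = 7.0
    rewires: int = 20
    taxon_filter: Optional[int] = None
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if len(self.cores) < 2:
            raise ValueError("config needs at least two core interactome files")
        if self.overlap_pair is None:
            self.overlap_pair = tuple(list(self.cores)[:2])
        for label, path in self.iter_input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"config references missing file for {label}: {path}")

    def iter_input_paths(self):
        for name, path in self.cores.items():
            yield f"core {name}", path
        for name, path in self.proteome_lists.items():
            yield f"list {name}", path
        for label in ("gmt", "scores", "tracks", "ptm", "fasta"):
            path = getattr(self, label)
            if path is not None:
                yield label, path

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        base = Path(path).parent
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)

        def resolve(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        cores = {k: resolve(v) for k, v in raw.get("cores", {}).items()}
        lists = {k: resolve(v) for k, v in raw.get("proteome_lists", {}).items()}
        kwargs = dict(
            cores=cores,
            proteome_lists=lists,
            gmt=resolve(raw.get("gmt")),
            scores=resolve(raw.get("scores")),
            tracks=resolve(raw.get("tracks")),
            ptm=resolve(raw.get("ptm")),
            fasta=resolve(raw.get("fasta")),
        )
        if "overlap_pair" in raw:
            kwargs["overlap_pair"] = tuple(raw["overlap_pair"])
        if "aging_lists" in raw:
            kwargs["aging_lists"] = tuple(raw["aging_lists"])
        if "hub" in raw:
            kwargs["hub"] = HubParams(**raw["hub"])
        if "mcode" in raw:
            kwargs["mcode"] = MCODEParams(**raw["mcode"])
        for key in ("enrich_top", "min_region_length", "ph", "rewires", "seed", "outdir", "taxon_filter"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def per_cluster_enrichment(
    complexes: List[MCODEComplex],
    library: GeneSetLibrary,
    top: int = 10,
) -> List[dict]:
    """enrich() applied to every complex; untestable complexes are recorded,
    not fatal."""
    out = []
    for rank, complex_ in enumerate(complexes, start=1):
        entry = {"rank": rank, "seed": complex_.seed, "size": len(complex_.members)}
        query = ProteinSet(f"cluster_{rank}", set(complex_.members))
        try:
            results = enrich(query, library, top=top)
        except ValueError:
            entry["note"] = "no testable genes"
            entry["top_terms"] = []
        else:
            entry["top_terms"] = [
                {"term": r.term, "p_value": r.p_value, "adjusted_p": r.adjusted_p, "k": r.k}
                for r in results
            ]
        out.append(entry)
    return out


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return decorator


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage, write all outputs under ``config.outdir``, return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "hub": asdict(config.hub),
            "mcode": asdict(config.mcode),
            "enrich_top": config.enrich_top,
            "min_region_length": config.min_region_length,
            "ph": config.ph,
            "rewires": config.rewires,
            "overlap_pair": list(config.overlap_pair),
            "evidence_interpretation": (
                "evidence = number of distinct (publication, experimental system) "
                "records per pair"
            ),
            "combined_score_note": (
                "combined score standardizes the overlap count against the "
                "hypergeometric null (not a rank-calibrated z)"
            ),
            "hub_graph_edges": "union of all loaded snapshots, max evidence per pair",
        },
        "stages": [],
        "counts": {},
    }

    # ---- inputs ----
    @_stage("read inputs")
    def read_inputs():
        cores = {
            name: nbio.read_interaction_table(path, focal=name, taxon_filter=config.taxon_filter)
            for name, path in config.cores.items()
        }
        lists = {
            name: nbio.read_protein_list(path, name=name)
            for name, path in config.proteome_lists.items()
        }
        library = nbio.read_gmt(config.gmt) if config.gmt else None
        scores = nbio.read_score_table(config.scores) if config.scores else None
        tracks = nbio.read_residue_tracks(config.tracks) if config.tracks else {}
        ptm = nbio.read_ptm_table(config.ptm) if config.ptm else None
        sequences = nbio.read_fasta(config.fasta) if config.fasta else {}
        return cores, lists, library, scores, tracks, ptm, sequences

    cores, lists, library, scores, tracks, ptm, sequences = read_inputs()
    report["counts"]["n_partners_per_core"] = {n: len(i) for n, i in sorted(cores.items())}
    report["stages"].append({"stage": "read inputs", "n_cores": len(cores), "n_lists": len(lists)})

    # ---- overlaps ----
    @_stage("overlap analysis")
    def overlaps():
        name_a, name_b = config.overlap_pair
        set_a = as_protein_set(name_a, cores[name_a])
        set_b = as_protein_set(name_b, cores[name_b])
        shared = overlap(set_a, set_b)
        all_sets = [as_protein_set(n, cores[n]) for n in sorted(cores)] + [
            lists[n] for n in sorted(lists)
        ]
        matrix = overlap_matrix(all_sets)
        venn = None
        if all(name in lists for name in config.aging_lists):
            venn = venn3(lists[config.aging_lists[0]], lists[config.aging_lists[1]], shared)
        return shared, matrix, venn

    shared, matrix, venn = overlaps()
    nbio.write_tsv(
        outdir / "overlap_matrix.tsv", ["set", *matrix.labels], matrix.to_rows()
    )
    report["counts"]["overlap_size"] = len(shared)
    aging_overlap_size = None
    if venn is not None:
        rows = [
            (region, len(members), ",".join(sorted(members)))
            for region, members in sorted(venn.items())
        ]
        nbio.write_tsv(outdir / "venn_aging.tsv", ("region", "size", "members"), rows)
        aging_union = lists[config.aging_lists[0]].members | lists[config.aging_lists[1]].members
        aging_overlap_size = len(shared.members & aging_union)
        report["counts"]["aging_overlap_size"] = aging_overlap_size
    report["stages"].append({"stage": "overlap analysis", "overlap_size": len(shared)})

    # ---- hubs ----
    @_stage("hub selection")
    def hub_stage():
        table = select_hubs(cores, config.hub)
        grid = hub_sensitivity(
            cores,
            k_range=range(1, len(cores) + 1),
            evidence_range=(1, 2, 3),
            exclude_cores_as_candidates=config.hub.exclude_cores_as_candidates,
        )
        return table, grid

    hub_table, sensitivity = hub_stage()
    nbio.write_tsv(
        outdir / "hubs.tsv",
        ("protein", "core_count", "qualifying_cores", "is_hub"),
        hub_table.to_rows(),
    )
    nbio.write_tsv(outdir / "hub_sensitivity.tsv", ("k_min", "evidence_min", "n_hubs"), sensitivity)
    report["counts"]["n_hubs"] = len(hub_table.hubs)
    report["stages"].append({"stage": "hub selection", "n_hubs": len(hub_table.hubs)})

    # ---- network, clustering, topology ----
    @_stage("hub network")
    def network_stage():
        graph = build_hub_graph(hub_table, cores, cores.values(), config.hub.evidence_min)
        complexes = find_complexes(graph, config.mcode)
        topo = topology_summary(graph, rewires=config.rewires, seed=config.seed)
        return graph, complexes, topo

    graph, complexes, topo = network_stage()
    nbio.write_graphml(outdir / "hub_network.graphml", graph)
    nbio.write_edge_list(outdir / "hub_network_edges.tsv", graph)
    nbio.write_tsv(
        outdir / "complexes.tsv",
        ("rank", "seed", "score", "size", "members"),
        [
            (i + 1, c.seed, f"{c.score:.6f}", len(c.members), ",".join(sorted(c.members)))
            for i, c in enumerate(complexes)
        ],
    )
    report["counts"]["n_network_nodes"] = graph.number_of_nodes()
    report["counts"]["n_network_edges"] = graph.number_of_edges()
    report["counts"]["n_complexes"] = len(complexes)
    report["topology"] = {
        "average_clustering": topo.average_clustering,
        "characteristic_path_length": topo.characteristic_path_length,
        "small_world_sigma": topo.small_world_sigma,
    }
    report["stages"].append({"stage": "hub network", "n_complexes": len(complexes)})

    # ---- enrichment ----
    if library is not None:
        @_stage("enrichment")
        def enrichment_stage():
            sections: Dict[str, object] = {}
            try:
                hub_results = enrich(
                    ProteinSet("hubs", set(hub_table.hubs)), library, top=config.enrich_top
                )
            except ValueError:
                sections["hubs"] = "no testable genes"
                hub_results = []
            sections["per_cluster"] = per_cluster_enrichment(
                complexes, library, top=config.enrich_top
            )
            aging_results = []
            if aging_overlap_size:
                aging_union = (
                    lists[config.aging_lists[0]].members
                    | lists[config.aging_lists[1]].members
                )
                try:
                    aging_results = enrich(
                        ProteinSet("aging_overlap", shared.members & aging_union),
                        library,
                        top=config.enrich_top,
                    )
                except ValueError:
                    sections["aging"] = "no testable genes"
            return sections, hub_results, aging_results

        sections, hub_results, aging_results = enrichment_stage()
        rows = [
            (r.term, r.k, r.n, r.K, r.N, f"{r.p_value:.6g}", f"{r.adjusted_p:.6g}",
             f"{r.odds_ratio:.6g}", f"{r.combined_score:.6g}", ",".join(sorted(r.overlap_members)))
            for r in hub_results
        ]
        nbio.write_tsv(
            outdir / "enrichment_hubs.tsv",
            ("term", "k", "n", "K", "N", "p_value", "adjusted_p", "odds_ratio",
             "combined_score", "overlap"),
            rows,
        )
        cluster_rows = []
        for entry in sections["per_cluster"]:
            for t in entry["top_terms"]:
                cluster_rows.append(
                    (entry["rank"], entry["seed"], t["term"], f"{t['p_value']:.6g}",
                     f"{t['adjusted_p']:.6g}", t["k"])
                )
        nbio.write_tsv(
            outdir / "enrichment_clusters.tsv",
            ("cluster_rank", "cluster_seed", "term", "p_value", "adjusted_p", "k"),
            cluster_rows,
        )
        report["counts"]["top_hub_term"] = hub_results[0].term if hub_results else None
        report["stages"].append({"stage": "enrichment", "n_hub_terms": len(hub_results)})

    # ---- annotation ----
    if scores is not None and ptm is not None and hub_table.hubs:
        @_stage("annotation")
        def annotation_stage():
            return annotate_hubs(
                hub_table,
                scores,
                tracks,
                ptm,
                sequences=sequences,
                min_region_length=config.min_region_length,
                ph=config.ph,
            )

        annotation_table, summary = annotation_stage()
        annotation_table.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        report["counts"]["annotation_summary"] = summary
        report["stages"].append({"stage": "annotation", "n_annotated": len(annotation_table)})
    elif not hub_table.hubs:
        report["stages"].append({"stage": "annotation", "note": "0 hubs, nothing to annotate"})

    nbio.write_json_report(outdir / "report.json", report)
    return report
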