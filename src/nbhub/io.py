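"""Readers and writers for every pipeline input and output format.

Inputs
------
* interaction tables — tab-delimited, BioGRID TAB3-style dialect: a header
  line whose columns are matched case-insensitively (``official symbol``
  interactor A/B, ``experimental system``, ``publication``; organism columns
  optional), every other column passed through untouched;
* plain-text gene-symbol lists (one per line, ``#`` comments);
* GMT gene-set libraries;
* per-protein predictor score tables, per-residue score tracks, PTM flags.

Outputs are TSV tables, a JSON run report, GraphML, and an edge-list TSV.
All writers iterate in sorted order so identical inputs produce identical
bytes.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .types import (
    GeneSetLibrary,
    InteractionRecord,
    Interactome,
    PTMAnnotation,
    ProteinSet,
    ResidueTrack,
    ScoreTable,
    normalize_symbol,
)

logger = logging.getLogger("nbhub")


class TableFormatError(ValueError):
    """A tabular input violates the documented dialect."""


class ScoreRangeError(ValueError):
    """A predictor score falls outside [0, 1]."""


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

_COLUMN_PATTERNS = {
    "symbol_a": ("official symbol", "a"),
    "symbol_b": ("official symbol", "b"),
    "experimental_system": ("experimental system",),
    "publication_id": ("publication",),
}
_ORGANISM_PATTERNS = {
    "organism_a": ("organism", "a"),
    "organism_b": ("organism", "b"),
}


def _locate_columns(header: Sequence[str]) -> Dict[str, int]:
    """Map record fields to column indices by case-insensitive substring match."""
    lowered = [h.strip().lower() for h in header]

    def find(patterns: Tuple[str, ...]) -> Optional[int]:
        for i, name in enumerate(lowered):
            if len(patterns) == 1:
                if patterns[0] in name:
                    return i
            # trailing single-letter pattern disambiguates interactor A vs B:
            # it must be the final token of the column name
            elif patterns[0] in name and name.endswith(patterns[-1]):
                return i
        return None

    columns: Dict[str, int] = {}
    for field_name, patterns in _COLUMN_PATTERNS.items():
        idx = find(patterns)
        if idx is None:
            raise TableFormatError(
                f"required column matching {patterns!r} missing from header"
            )
        columns[field_name] = idx
    for field_name, patterns in _ORGANISM_PATTERNS.items():
        idx = find(patterns)
        if idx is not None:
            columns[field_name] = idx
    return columns


def parse_interaction_records(path: Path | str) -> List[InteractionRecord]:
    """Parse a TAB3-style table into raw records (symbols normalized)."""
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise TableFormatError(f"{path}: empty file, no header")
        columns = _locate_columns(header_line.rstrip("\n").split("\t"))
        records: List[InteractionRecord] = []
        for raw in fh:
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")

            def get(key: str) -> Optional[str]:
                idx = columns.get(key)
                if idx is None or idx >= len(fields):
                    return None
                return fields[idx]

            org_a = get("organism_a")
            org_b = get("organism_b")
            records.append(
                InteractionRecord(
                    symbol_a=normalize_symbol(get("symbol_a") or ""),
                    symbol_b=normalize_symbol(get("symbol_b") or ""),
                    experimental_system=(get("experimental_system") or "").strip(),
                    publication_id=(get("publication_id") or "").strip(),
                    organism_a=int(org_a) if org_a and org_a.strip().isdigit() else None,
                    organism_b=int(org_b) if org_b and org_b.strip().isdigit() else None,
                )
            )
    return records


def interactome_from_records(
    records: Iterable[InteractionRecord],
    focal: str,
    taxon_filter: Optional[int] = None,
) -> Interactome:
    """Collapse evidence records into an Interactome for one focal protein.

    The evidence count of a partner is the number of *distinct*
    (publication, experimental system) records supporting the pair, so
    duplicated rows never inflate it.  Self-interactions are dropped, records
    not involving the focal protein are ignored, and if ``taxon_filter`` is
    given any record with either organism outside it is excluded.
    """
    focal = normalize_symbol(focal)
    evidence: Dict[str, set] = {}
    for rec in records:
        if taxon_filter is not None:
            if (rec.organism_a is not None and rec.organism_a != taxon_filter) or (
                rec.organism_b is not None and rec.organism_b != taxon_filter
            ):
                continue
        if focal == rec.symbol_a:
            partner = rec.symbol_b
        elif focal == rec.symbol_b:
            partner = rec.symbol_a
        else:
            continue
        if partner == focal:
            continue  # self-loop
        evidence.setdefault(partner, set()).add(
            (rec.publication_id, rec.experimental_system)
        )
    return Interactome(focal=focal, partners={p: len(s) for p, s in evidence.items()})


def read_interaction_table(
    path: Path | str,
    focal: str,
    taxon_filter: Optional[int] = None,
) -> Interactome:
    """Read a TAB3-style interaction table into an Interactome for ``focal``."""
    records = parse_interaction_records(path)
    interactome = interactome_from_records(records, focal, taxon_filter)
    if not interactome.partners:
        logger.warning(
            "focal protein %s has no partners in %s", normalize_symbol(focal), path
        )
    return interactome


def write_interaction_table(path: Path | str, focal: str, records: Iterable[InteractionRecord]) -> None:
    """Write records in the TAB3-style dialect (sorted, byte-stable)."""
    rows = sorted(
        records,
        key=lambda r: (r.symbol_a, r.symbol_b, r.publication_id, r.experimental_system),
    )
    with Path(path).open("w") as fh:
        fh.write(
            "Official Symbol Interactor A\tOfficial Symbol Interactor B\t"
            "Experimental System\tPublication Source\t"
            "Organism Interactor A\tOrganism Interactor B\n"
        )
        for r in rows:
            fh.write(
                f"{r.symbol_a}\t{r.symbol_b}\t{r.experimental_system}\t"
                f"{r.publication_id}\t{r.organism_a or ''}\t{r.organism_b or ''}\n"
            )


# ---------------------------------------------------------------------------
# gene lists and gene-set libraries
# ---------------------------------------------------------------------------

def read_protein_list(path: Path | str, name: Optional[str] = None) -> ProteinSet:
    """Read a one-symbol-per-line list; ``#`` lines are comments.

    Symbols are normalized and deduplicated; the read-vs-kept counts are
    logged so silent collapses are visible.
    """
    path = Path(path)
    read_count = 0
    members = set()
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            read_count += 1
            members.add(normalize_symbol(line))
    if read_count == 0:
        logger.warning("protein list %s is empty", path)
    logger.info("read %d symbols from %s, kept %d unique", read_count, path, len(members))
    return ProteinSet(name=name or path.stem, members=members)


def write_protein_list(path: Path | str, protein_set: ProteinSet) -> None:
    with Path(path).open("w") as fh:
        for symbol in sorted(protein_set.members):
            fh.write(symbol + "\n")


def read_gmt(path: Path | str, universe: Optional[Iterable[str]] = None) -> GeneSetLibrary:
    """Read a GMT library: ``term<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    terms: Dict[str, set] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            label = fields[0].strip()
            members = {normalize_symbol(m) for m in fields[2:] if m.strip()}
            if not members:
                raise TableFormatError(f"{path}:{lineno}: term {label!r} has no members")
            terms[label] = members
    return GeneSetLibrary(
        name=path.stem,
        terms=terms,
        universe={normalize_symbol(g) for g in universe} if universe else set(),
    )


def write_gmt(path: Path | str, library: GeneSetLibrary) -> None:
    with Path(path).open("w") as fh:
        for label in sorted(library.terms):
            members = "\t".join(sorted(library.terms[label]))
            fh.write(f"{label}\t{library.name}\t{members}\n")


# ---------------------------------------------------------------------------
# predictor scores, residue tracks, PTM flags
# ---------------------------------------------------------------------------

def read_score_table(path: Path | str) -> ScoreTable:
    """Read ``protein<TAB>predictor<TAB>score`` rows; scores must lie in [0,1]."""
    path = Path(path)
    table = ScoreTable()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TableFormatError(f"{path}:{lineno}: expected 3 fields")
            protein, predictor, score_str = fields
            protein = normalize_symbol(protein)
            try:
                score = float(score_str)
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-numeric score") from exc
            if not 0.0 <= score <= 1.0:
                raise ScoreRangeError(
                    f"score out of [0,1] for protein {protein}, predictor {predictor}: {score}"
                )
            table.scores.setdefault(protein, {})[predictor] = score
    return table


def read_residue_tracks(path: Path | str) -> Dict[Tuple[str, str], ResidueTrack]:
    """Read ``protein<TAB>predictor<TAB>comma-joined scores`` rows."""
    path = Path(path)
    tracks: Dict[Tuple[str, str], ResidueTrack] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TableFormatError(f"{path}:{lineno}: expected 3 fields")
            protein, predictor, scores_str = fields
            try:
                scores = [float(s) for s in scores_str.split(",") if s.strip()]
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: non-numeric track value") from exc
            try:
                track = ResidueTrack(protein=protein, predictor=predictor, scores=scores)
            except ValueError as exc:
                raise ScoreRangeError(f"{path}:{lineno}: {exc}") from exc
            tracks[(track.protein, predictor)] = track
    return tracks


def write_residue_tracks(path: Path | str, tracks: Mapping[Tuple[str, str], ResidueTrack]) -> None:
    with Path(path).open("w") as fh:
        for key in sorted(tracks):
            t = tracks[key]
            fh.write(f"{t.protein}\t{t.predictor}\t{','.join(f'{s:g}' for s in t.scores)}\n")


_TRI_STATE = {"true": True, "false": False, "unknown": None, "1": True, "0": False, "": None}


def read_ptm_table(path: Path | str) -> PTMAnnotation:
    """Read ``protein<TAB>sumo<TAB>ubiquitin`` rows with true/false/unknown flags."""
    path = Path(path)
    annotation = PTMAnnotation()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise TableFormatError(f"{path}:{lineno}: expected 3 fields")
            protein, sumo_str, ub_str = fields
            flags = {}
            for mod, value in (("sumo", sumo_str), ("ubiquitin", ub_str)):
                key = value.strip().lower()
                if key not in _TRI_STATE:
                    raise TableFormatError(
                        f"{path}:{lineno}: bad {mod} flag {value!r} (true/false/unknown)"
                    )
                flags[mod] = _TRI_STATE[key]
            annotation.flags[normalize_symbol(protein)] = flags
    return annotation


def write_ptm_table(path: Path | str, annotation: PTMAnnotation) -> None:
    def fmt(v: Optional[bool]) -> str:
        return "unknown" if v is None else ("true" if v else "false")

    with Path(path).open("w") as fh:
        for protein in sorted(annotation.flags):
            flags = annotation.flags[protein]
            fh.write(f"{protein}\t{fmt(flags.get('sumo'))}\t{fmt(flags.get('ubiquitin'))}\n")


def read_fasta(path: Path | str) -> Dict[str, str]:
    """Minimal FASTA reader: header token -> uppercased sequence."""
    sequences: Dict[str, str] = {}
    current: Optional[str] = None
    chunks: List[str] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    sequences[current] = "".join(chunks)
                current = normalize_symbol(line[1:].split()[0])
                chunks = []
            elif current is not None:
                chunks.append(line.upper())
    if current is not None:
        sequences[current] = "".join(chunks)
    return sequences


def write_fasta(path: Path | str, sequences: Mapping[str, str], width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# pipeline outputs
# ---------------------------------------------------------------------------

def write_tsv(path: Path | str, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_json_report(path: Path | str, report: Mapping) -> None:
    """Write the run report with stable key order (byte-stable contract)."""
    with Path(path).open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_graphml(path: Path | str, graph: nx.Graph) -> None:
    """GraphML export with nodes/edges inserted in sorted order."""
    ordered = nx.Graph()
    for node in sorted(graph.nodes):
        ordered.add_node(node, **graph.nodes[node])
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        ordered.add_edge(u, v, **graph.edges[u, v])
    nx.write_graphml(ordered, str(path))


def read_graphml(path: Path | str) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(path: Path | str, graph: nx.Graph) -> None:
    rows = []
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        rows.append((u, v, graph.edges[u, v].get("evidence", "")))
    write_tsv(path, ("protein_a", "protein_b", "evidence"), rows)
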