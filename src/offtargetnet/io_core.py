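"""Domain types and readers/writers for the flat-file snapshots.

The pipeline consumes pre-exported snapshots instead of querying live
services: a drug→protein-target table, an undirected binary PPI edge list at
the UniProt-accession level, a protein→GO-term annotation table, a
gene→(disease, score) table, and a per-protein proteoform-event table.  All
files are UTF-8 TSV with a required header row; lines starting with ``#``
are comments and are skipped.

Protein nodes are keyed by accession string only (snapshots are assumed
pre-mapped to one identifier space); comparisons are case-sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .exceptions import MissingNodeError, SnapshotFormatError, UsageError

#: Protein identifiers are bare accession strings (e.g. ``"P30556"``).
ProteinID = str

#: UniProt feature classes recognised as post-translational-modification
#: event categories.  Unknown categories are rejected at parse time.
PTM_CATEGORIES: frozenset[str] = frozenset(
    {
        "modified_residue",
        "glycosylation",
        "disulfide_bond",
        "chain",
        "cross_link",
        "lipidation",
        "signal",
        "initiator_methionine",
        "transit_peptide",
        "peptide",
        "propeptide",
    }
)

#: Event kinds accepted in the proteoform TSV: one row per event.
_PROTEOFORM_KINDS = PTM_CATEGORIES | {"allelic_variant", "splice_transcript"}

#: Default organism filter applied when building human networks.
DEFAULT_ORGANISM = "HUMAN"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugRecord:
    """Identity of one drug: id, display name, optional SMILES and group.

    ``group`` is a label used to collapse a family of drugs (e.g. a drug
    class sharing one receptor) into a single group node when a network is
    built with ``collapse_groups=True``.
    """

    drug_id: str
    name: str
    smiles: str | None = None
    group: str | None = None


@dataclass(frozen=True)
class DrugTargetRow:
    drug_id: str
    target: ProteinID
    organism: str


@dataclass
class DrugTargetTable:
    """Drug→protein-target relation plus the resolvable drug records."""

    rows: tuple[DrugTargetRow, ...]
    drugs: dict[str, DrugRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            key = (row.drug_id, row.target)
            if key in seen:
                raise SnapshotFormatError(f"duplicate (drug, target) pair: {key}")
            seen.add(key)
            if row.drug_id not in self.drugs:
                raise SnapshotFormatError(
                    f"drug_id {row.drug_id!r} has no DrugRecord"
                )

    @property
    def drug_ids(self) -> set[str]:
        return {r.drug_id for r in self.rows}

    def targets_of(self, drug_id: str, organism: str | None = None) -> set[ProteinID]:
        """Targets of one drug, optionally restricted to one organism."""
        return {
            r.target
            for r in self.rows
            if r.drug_id == drug_id and (organism is None or r.organism == organism)
        }

    def drugs_binding(self, protein: ProteinID, organism: str | None = None) -> set[str]:
        """All drug ids with a binds row to ``protein``."""
        return {
            r.drug_id
            for r in self.rows
            if r.target == protein and (organism is None or r.organism == organism)
        }


class Interactome:
    """Undirected binary PPI graph over protein accessions.

    Self-pairs (a protein interacting with itself, i.e. a dimer) are stored
    as edges but flagged: downstream first-neighbor logic excludes them,
    since a protein is not its own first neighbor.  Edges deduplicate under
    unordered comparison, so adding (A,B) and (B,A) yields one edge.
    """

    def __init__(
        self,
        edges: Iterable[tuple[ProteinID, ProteinID]] = (),
        nodes: Iterable[ProteinID] = (),
    ) -> None:
        self._g = nx.Graph()
        for n in nodes:
            self.add_node(n)
        for a, b in edges:
            self.add_edge(a, b)

    # -- construction -----------------------------------------------------
    def add_node(self, node: ProteinID) -> None:
        if not node:
            raise SnapshotFormatError("empty protein accession")
        self._g.add_node(node)

    def add_edge(self, a: ProteinID, b: ProteinID) -> None:
        self.add_node(a)
        self.add_node(b)
        self._g.add_edge(a, b)

    # -- queries ----------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        """Live networkx view of the interactome (self-loops included)."""
        return self._g

    @property
    def nodes(self) -> set[ProteinID]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[ProteinID, ProteinID]]:
        """Edges as canonically ordered pairs; self-pairs appear as (a, a)."""
        return {(a, b) if a <= b else (b, a) for a, b in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, node: ProteinID) -> bool:
        return self._g.has_node(node)

    def has_edge(self, a: ProteinID, b: ProteinID) -> bool:
        return self._g.has_edge(a, b)

    def has_self_pair(self, node: ProteinID) -> bool:
        return self._g.has_edge(node, node)

    def self_pairs(self) -> set[ProteinID]:
        return {a for a, b in self._g.edges if a == b}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class AnnotationTable:
    """Protein/gene → set of annotation term ids, with term labels.

    Every term occurring in ``rows`` has an entry in ``term_names`` (the
    reader defaults a missing label to the term id itself).
    """

    rows: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.rows.items():
            for t in terms:
                self.term_names.setdefault(t, t)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.rows.values():
            out |= terms
        return out

    def genes_with(self, term: str) -> set[str]:
        return {g for g, terms in self.rows.items() if term in terms}


@dataclass(frozen=True)
class DiseaseRow:
    gene: str
    disease: str
    score: float


@dataclass
class DiseaseTable:
    """Gene–disease association rows with scores in [0, 1]."""

    rows: tuple[DiseaseRow, ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.rows:
            if not 0.0 <= r.score <= 1.0:
                raise SnapshotFormatError(
                    f"disease score out of [0,1] for ({r.gene}, {r.disease}): {r.score}"
                )
            key = (r.gene, r.disease)
            if key in seen:
                raise SnapshotFormatError(f"duplicate (gene, disease) pair: {key}")
            seen.add(key)

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.rows}

    def rows_for(self, genes: Iterable[str]) -> list[DiseaseRow]:
        wanted = set(genes)
        return [r for r in self.rows if r.gene in wanted]


@dataclass(frozen=True)
class ProteoformRecord:
    """Per-protein proteoform evidence: PTM events + variant/splice counts."""

    ptm_events: tuple[tuple[str, str], ...] = ()
    allelic_variant_count: int = 0
    splice_transcript_count: int = 0

    def __post_init__(self) -> None:
        for cat, _ in self.ptm_events:
            if cat not in PTM_CATEGORIES:
                raise SnapshotFormatError(f"unknown PTM category: {cat!r}")
        if self.allelic_variant_count < 0 or self.splice_transcript_count < 0:
            raise SnapshotFormatError("proteoform counts must be non-negative")

    @property
    def total(self) -> int:
        return (
            len(self.ptm_events)
            + self.allelic_variant_count
            + self.splice_transcript_count
        )


@dataclass
class ProteoformTable:
    rows: dict[ProteinID, ProteoformRecord]

    def record(self, protein: ProteinID) -> ProteoformRecord:
        try:
            return self.rows[protein]
        except KeyError:
            raise MissingNodeError(f"protein {protein!r} not in proteoform table") from None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise SnapshotFormatError(f"{path}: empty file (header row required)") from None
    for col in required:
        if col not in df.columns:
            raise SnapshotFormatError(f"{path}: missing required column {col!r}")
    return df


def read_drug_targets(path: str | Path) -> tuple[list[DrugRecord], DrugTargetTable]:
    """Read a drug→target TSV (columns: drug_id, drug_name, target_accession,
    organism, optional smiles, optional group).

    Duplicate (drug, target) rows raise a warning and keep the first
    occurrence.  Row order of the file does not affect the result: rows are
    stored sorted by (drug_id, target, organism).
    """
    df = _read_tsv(path, ["drug_id", "drug_name", "target_accession", "organism"])
    records: dict[str, DrugRecord] = {}
    rows: list[DrugTargetRow] = []
    seen: set[tuple[str, str]] = set()
    for raw in df.itertuples(index=False):
        drug_id = raw.drug_id.strip()
        target = raw.target_accession.strip()
        if not drug_id or not target:
            raise SnapshotFormatError(f"{path}: empty drug_id or target_accession")
        key = (drug_id, target)
        if key in seen:
            warnings.warn(
                f"{path}: duplicate (drug, target) row {key}; first kept", stacklevel=2
            )
            continue
        seen.add(key)
        if drug_id not in records:
            smiles = getattr(raw, "smiles", "") or None
            group = getattr(raw, "group", "") or None
            records[drug_id] = DrugRecord(
                drug_id=drug_id, name=raw.drug_name.strip(), smiles=smiles, group=group
            )
        rows.append(DrugTargetRow(drug_id, target, raw.organism.strip()))
    rows.sort(key=lambda r: (r.drug_id, r.target, r.organism))
    table = DrugTargetTable(rows=tuple(rows), drugs=dict(records))
    return list(records.values()), table


def read_ppi_edges(path: str | Path) -> Interactome:
    """Read an undirected PPI edge list (two accession columns per row).

    (A,B) and (B,A) deduplicate to one edge; (A,A) is retained as a
    self-pair.  A data row with fewer than two fields raises a format error
    naming the offending line number.
    """
    path = Path(path)
    net = Interactome()
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # header row: column names, not an edge
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise SnapshotFormatError(
                    f"{path}:{lineno}: expected two accession fields, got {line!r}"
                )
            net.add_edge(fields[0].strip(), fields[1].strip())
    return net


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a protein→term TSV (columns: protein_id, term_id, optional term_name)."""
    df = _read_tsv(path, ["protein_id", "term_id"])
    rows: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for raw in df.itertuples(index=False):
        gene, term = raw.protein_id.strip(), raw.term_id.strip()
        if not gene or not term:
            raise SnapshotFormatError(f"{path}: empty protein_id or term_id")
        rows.setdefault(gene, set()).add(term)
        label = getattr(raw, "term_name", "") or term
        names.setdefault(term, label)
    return AnnotationTable(rows=rows, term_names=names)


def read_diseases(path: str | Path) -> DiseaseTable:
    """Read a gene→(disease, score) TSV (columns: gene_id, disease, score)."""
    df = _read_tsv(path, ["gene_id", "disease", "score"])
    rows: list[DiseaseRow] = []
    seen: set[tuple[str, str]] = set()
    for raw in df.itertuples(index=False):
        try:
            score = float(raw.score)
        except ValueError:
            raise SnapshotFormatError(
                f"{path}: non-numeric score {raw.score!r} for gene {raw.gene_id!r}"
            ) from None
        key = (raw.gene_id.strip(), raw.disease.strip())
        if key in seen:
            warnings.warn(f"{path}: duplicate (gene, disease) row {key}; first kept",
                          stacklevel=2)
            continue
        seen.add(key)
        rows.append(DiseaseRow(key[0], key[1], score))
    rows.sort(key=lambda r: (r.gene, r.disease))
    return DiseaseTable(rows=tuple(rows))


def read_proteoforms(path: str | Path) -> ProteoformTable:
    """Read a proteoform-event TSV: one row per event.

    Columns: protein_id, category, optional description.  ``category`` is a
    PTM feature class, ``allelic_variant``, or ``splice_transcript``; the
    latter two are tallied into the per-protein counts.
    """
    df = _read_tsv(path, ["protein_id", "category"])
    ptms: dict[str, list[tuple[str, str]]] = {}
    allelic: dict[str, int] = {}
    splice: dict[str, int] = {}
    for raw in df.itertuples(index=False):
        protein, cat = raw.protein_id.strip(), raw.category.strip()
        if cat not in _PROTEOFORM_KINDS:
            raise SnapshotFormatError(
                f"{path}: unknown proteoform category {cat!r} for {protein!r}"
            )
        if cat == "allelic_variant":
            allelic[protein] = allelic.get(protein, 0) + 1
        elif cat == "splice_transcript":
            splice[protein] = splice.get(protein, 0) + 1
        else:
            desc = getattr(raw, "description", "") or ""
            ptms.setdefault(protein, []).append((cat, desc))
        # ensure every mentioned protein gets a record
        ptms.setdefault(protein, ptms.get(protein, []))
    rows = {
        p: ProteoformRecord(
            ptm_events=tuple(ptms.get(p, [])),
            allelic_variant_count=allelic.get(p, 0),
            splice_transcript_count=splice.get(p, 0),
        )
        for p in set(ptms) | set(allelic) | set(splice)
    }
    return ProteoformTable(rows=rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_tsv(
    path: str | Path,
    header: list[str],
    rows: Iterable[Iterable[object]],
    comments: Iterable[str] = (),
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_drug_targets(
    records: Iterable[DrugRecord], table: DrugTargetTable, path: str | Path,
    comments: Iterable[str] = (),
) -> None:
    recs = {r.drug_id: r for r in records}
    rows = [
        (
            r.drug_id,
            recs[r.drug_id].name,
            r.target,
            r.organism,
            recs[r.drug_id].smiles or "",
            recs[r.drug_id].group or "",
        )
        for r in sorted(table.rows, key=lambda r: (r.drug_id, r.target))
    ]
    _write_tsv(
        path,
        ["drug_id", "drug_name", "target_accession", "organism", "smiles", "group"],
        rows,
        comments,
    )


def write_ppi_edges(net: Interactome, path: str | Path,
                    comments: Iterable[str] = ()) -> None:
    _write_tsv(path, ["protein_a", "protein_b"], sorted(net.edges), comments)


def write_annotations(table: AnnotationTable, path: str | Path,
                      comments: Iterable[str] = ()) -> None:
    rows = [
        (gene, term, table.term_names.get(term, term))
        for gene in sorted(table.rows)
        for term in sorted(table.rows[gene])
    ]
    _write_tsv(path, ["protein_id", "term_id", "term_name"], rows, comments)


def write_diseases(table: DiseaseTable, path: str | Path,
                   comments: Iterable[str] = ()) -> None:
    rows = [(r.gene, r.disease, repr(r.score)) for r in table.rows]
    _write_tsv(path, ["gene_id", "disease", "score"], rows, comments)


def write_proteoforms(table: ProteoformTable, path: str | Path,
                      comments: Iterable[str] = ()) -> None:
    rows: list[tuple[str, str, str]] = []
    for protein in sorted(table.rows):
        rec = table.rows[protein]
        for cat, desc in rec.ptm_events:
            rows.append((protein, cat, desc))
        rows.extend((protein, "allelic_variant", "") for _ in range(rec.allelic_variant_count))
        rows.extend((protein, "splice_transcript", "") for _ in range(rec.splice_transcript_count))
    _write_tsv(path, ["protein_id", "category", "description"], rows, comments)


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("SIF", "GraphML")


def write_network(net, path: str | Path, format: str = "SIF") -> None:  # noqa: A002
    """Export a protein–drug network as SIF or GraphML.

    SIF rows are ``source<TAB>relation<TAB>target`` with relation in
    {binds, ppi}; binds rows put the drug first.  GraphML carries node type
    and drug group as attributes and is the lossless round-trip format.
    """
    fmt = format.lower()
    if fmt not in ("sif", "graphml"):
        raise UsageError(f"unknown network format {format!r}; use SIF or GraphML")
    g = net.graph
    if fmt == "sif":
        lines: list[str] = []
        for a, b, data in g.edges(data=True):
            etype = data.get("edge_type", "ppi")
            if etype == "binds":
                # drug endpoint first
                if g.nodes[a].get("node_type") in _DRUG_TYPES:
                    src, dst = a, b
                else:
                    src, dst = b, a
            else:
                src, dst = (a, b) if a <= b else (b, a)
            lines.append(f"{src}\t{etype}\t{dst}")
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        with open(path, "w", encoding="utf-8") as fh:
            for line in sorted(lines):
                fh.write(line + "\n")
            for n in sorted(isolated):
                fh.write(f"{n}\n")
    else:
        out = nx.Graph()
        for n, data in g.nodes(data=True):
            out.add_node(n, **{k: v for k, v in data.items() if v is not None})
        for a, b, data in g.edges(data=True):
            out.add_edge(a, b, **data)
        nx.write_graphml(out, str(path))


_DRUG_TYPES = {"focal_drug", "drug_group", "other_drug", "drug"}


def read_network(path: str | Path, format: str = "SIF"):  # noqa: A002
    """Re-read a network written by :func:`write_network`.

    GraphML restores node/edge attributes exactly.  SIF restores the node
    and typed-edge multisets; node types are inferred coarsely (sources of
    ``binds`` rows become ``drug`` nodes, everything else ``protein``).
    """
    from .network_build import ProteinDrugNetwork

    fmt = format.lower()
    if fmt not in ("sif", "graphml"):
        raise UsageError(f"unknown network format {format!r}; use SIF or GraphML")
    g = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(str(path))
        for n, data in raw.nodes(data=True):
            g.add_node(n, **data)
        for a, b, data in raw.edges(data=True):
            g.add_edge(a, b, **data)
        return ProteinDrugNetwork(graph=g)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                g.add_node(fields[0], node_type="protein")
            elif len(fields) == 3:
                src, rel, dst = fields
                if rel not in ("binds", "ppi"):
                    raise SnapshotFormatError(f"{path}:{lineno}: unknown relation {rel!r}")
                g.add_edge(src, dst, edge_type=rel)
                if rel == "binds":
                    g.nodes[src]["node_type"] = "drug"
            else:
                raise SnapshotFormatError(
                    f"{path}:{lineno}: SIF rows have 1 or 3 fields, got {len(fields)}"
                )
    for n in g.nodes:
        g.nodes[n].setdefault("node_type", "protein")
    return ProteinDrugNetwork(graph=g)
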