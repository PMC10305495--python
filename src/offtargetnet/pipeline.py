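"""One-shot analysis pipeline and input validation.

``run_pipeline`` strings all stages together: build a protein–drug
network per focal drug group, compute topology metrics, compare all group
pairs by first-neighbor Jaccard, run term over-representation per group's
protein set, pool proteoform breakdowns, and rank gene–disease
associations — writing SIF/GraphML networks, TSV tables, and a run
manifest.  Outputs are deterministic: identical inputs and parameters
yield byte-identical bundles, and every table carries the manifest hash
in a header comment line.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation_profiles import (
    DiseaseRanking,
    PtmBreakdown,
    ptm_breakdown,
    top_diseases,
)
from .enrichment import EnrichmentResult, enrich, format_fold
from .exceptions import OffTargetNetError, UndefinedResultError, UsageError
from .io_core import (
    read_annotations,
    read_diseases,
    read_drug_targets,
    read_ppi_edges,
    read_proteoforms,
    write_network,
)
from .network_build import ProteinDrugNetwork, build_protein_drug_network
from .network_metrics import graph_summary, node_metrics
from .similarity import NeighborComparison, neighbor_jaccard

_INPUT_KEYS = ("drug_targets", "ppi", "annotations", "diseases", "proteoforms")


class StageError(OffTargetNetError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    inputs: dict[str, str]
    checksums: dict[str, str]
    parameters: dict
    seed: int | None
    version: str = __version__

    def canonical_json(self) -> str:
        return json.dumps(
            {
                "inputs": self.inputs,
                "checksums": self.checksums,
                "parameters": self.parameters,
                "seed": self.seed,
                "version": self.version,
            },
            sort_keys=True,
        )

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    manifest: RunManifest
    networks: dict[str, ProteinDrugNetwork] = field(default_factory=dict)
    comparisons: list[NeighborComparison] = field(default_factory=list)
    enrichment: dict[str, list[EnrichmentResult]] = field(default_factory=dict)
    breakdowns: dict[str, PtmBreakdown | None] = field(default_factory=dict)
    disease_rankings: dict[str, DiseaseRanking] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _group_spec(value) -> tuple[list[str], frozenset[str]]:
    """A group is either a plain drug list or {'drugs': [...],
    'extra_targets': [...]}."""
    if isinstance(value, dict):
        return list(value.get("drugs", [])), frozenset(value.get("extra_targets", []))
    return list(value), frozenset()


def _check_config(config: dict) -> None:
    inputs = config.get("inputs", {})
    missing = [k for k in _INPUT_KEYS if k not in inputs]
    if missing:
        raise UsageError(f"config missing input paths: {', '.join(missing)}")
    groups = config.get("groups", {})
    if len(groups) < 2:
        raise UsageError("config must name at least 2 focal drug groups")


def validate_inputs(config: dict) -> list[tuple[str, str]]:
    """Cross-file referential checks, reported without running the
    pipeline.  Returns (level, message) diagnostics where level is
    ``error`` or ``warning``."""
    _check_config(config)
    inputs = config["inputs"]
    organism = config.get("organism", "HUMAN")
    diags: list[tuple[str, str]] = []

    _, dt = read_drug_targets(inputs["drug_targets"])
    interactome = read_ppi_edges(inputs["ppi"])
    annotations = read_annotations(inputs["annotations"])
    diseases = read_diseases(inputs["diseases"])
    proteoforms = read_proteoforms(inputs["proteoforms"])

    for label, value in sorted(config["groups"].items()):
        drugs, extra = _group_spec(value)
        if not drugs:
            diags.append(("error", f"group {label!r} names no drugs"))
        for d in drugs:
            if d not in dt.drugs:
                diags.append(("error", f"group {label!r}: drug {d!r} not in drug-target table"))
                continue
            for t in sorted(dt.targets_of(d, organism=organism)):
                if not interactome.has_node(t):
                    diags.append(
                        ("error", f"group {label!r}: target {t} of drug {d} absent from PPI file")
                    )
        for t in sorted(extra):
            if not interactome.has_node(t):
                diags.append(("error", f"group {label!r}: extra target {t} absent from PPI file"))

    nodes = interactome.nodes
    for name, ids in (
        ("annotation", set(annotations.rows)),
        ("disease", diseases.genes),
        ("proteoform", set(proteoforms.rows)),
    ):
        overlap = len(ids & nodes)
        if ids and overlap == 0:
            diags.append(
                ("warning", f"{name} table shares no identifiers with the interactome "
                            f"({len(ids)} ids checked)")
            )
        elif len(ids) > overlap:
            diags.append(
                ("warning", f"{name} table: {len(ids) - overlap} ids not in the interactome")
            )
    return diags


def _write_table(path: Path, header: list[str], rows, manifest_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: dict, outdir: str | Path) -> PipelineReport:
    """Execute build → metrics → comparisons → enrichment → proteoforms →
    diseases on the configured snapshot and write the report bundle."""
    _check_config(config)
    inputs = config["inputs"]
    organism = config.get("organism", "HUMAN")
    collapse = bool(config.get("collapse_groups", False))
    alpha = float(config.get("alpha", 0.05))
    include_targets = bool(config.get("include_targets_in_comparison", True))
    aggregation = config.get("disease_aggregation", "max")
    normalized = bool(config.get("normalized_centrality", False))
    top_k = int(config.get("top_diseases", 10))

    outdir = Path(outdir)
    (outdir / "networks").mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        inputs={k: str(inputs[k]) for k in _INPUT_KEYS},
        checksums={k: _sha256(inputs[k]) for k in _INPUT_KEYS},
        parameters={
            "organism": organism,
            "collapse_groups": collapse,
            "alpha": alpha,
            "include_targets_in_comparison": include_targets,
            "disease_aggregation": aggregation,
            "normalized_centrality": normalized,
            "top_diseases": top_k,
            "groups": {
                label: {"drugs": _group_spec(v)[0],
                        "extra_targets": sorted(_group_spec(v)[1])}
                for label, v in sorted(config["groups"].items())
            },
        },
        seed=config.get("seed"),
    )
    mhash = manifest.hash
    report = PipelineReport(manifest=manifest)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("ingest"):
        _, dt = read_drug_targets(inputs["drug_targets"])
        interactome = read_ppi_edges(inputs["ppi"])
        annotations = read_annotations(inputs["annotations"])
        diseases = read_diseases(inputs["diseases"])
        proteoforms = read_proteoforms(inputs["proteoforms"])

    labels = sorted(config["groups"])
    with stage("build"):
        for label in labels:
            drugs, extra = _group_spec(config["groups"][label])
            net = build_protein_drug_network(
                interactome,
                dt,
                set(drugs),
                collapse_groups=collapse,
                organism=organism,
                extra_targets=extra,
            )
            report.networks[label] = net
            sif = outdir / "networks" / f"{label}.sif"
            gml = outdir / "networks" / f"{label}.graphml"
            write_network(net, sif, format="SIF")
            write_network(net, gml, format="GraphML")
            report.outputs[f"network_sif_{label}"] = sif
            report.outputs[f"network_graphml_{label}"] = gml

    with stage("metrics"):
        for label in labels:
            net = report.networks[label]
            rows = [
                (m.node, m.degree, f"{m.betweenness:.6g}", f"{m.closeness:.6g}")
                for m in node_metrics(net, normalized=normalized)
            ]
            summ = graph_summary(net)
            path = outdir / f"metrics_{label}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(f"# manifest: {mhash}\n")
                for k, v in sorted(vars(summ).items()):
                    fh.write(f"# {k}: {v}\n")
                fh.write("node\tdegree\tbetweenness\tcloseness\n")
                for row in rows:
                    fh.write("\t".join(str(x) for x in row) + "\n")
            report.outputs[f"metrics_{label}"] = path

    with stage("compare"):
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                cmp_a = report.networks[la].comparison_set(include_targets)
                cmp_b = report.networks[lb].comparison_set(include_targets)
                report.comparisons.append(
                    neighbor_jaccard(cmp_a, cmp_b, la, lb, empty_as_zero=True)
                )
        report.comparisons.sort(key=lambda c: (c.label_a, c.label_b))
        path = outdir / "neighbor_comparisons.tsv"
        _write_table(
            path,
            ["drug_a", "drug_b", "shared_m11", "unique_a_m10", "unique_b_m01",
             "jaccard", "jaccard_distance"],
            (c.formatted() for c in report.comparisons),
            mhash,
        )
        report.outputs["comparisons"] = path

    with stage("enrichment"):
        background = interactome.nodes
        for label in labels:
            study = set(report.networks[label].comparison_set(include_targets)) & background
            results = (
                enrich(study, annotations, background, alpha=alpha) if study else []
            )
            report.enrichment[label] = results
            path = outdir / f"enrichment_{label}.tsv"
            _write_table(
                path,
                ["term", "label", "k", "n", "K", "N", "fold_enrichment", "p", "fdr",
                 "displayed"],
                (
                    (r.term, r.label, r.k, r.n, r.K, r.N,
                     format_fold(r.fold_enrichment), f"{r.p:.6g}", f"{r.q:.6g}",
                     int(r.displayed))
                    for r in results
                ),
                mhash,
            )
            report.outputs[f"enrichment_{label}"] = path

    with stage("proteoforms"):
        for label in labels:
            proteins = report.networks[label].protein_nodes & set(proteoforms.rows)
            try:
                breakdown = ptm_breakdown(proteoforms, proteins) if proteins else None
            except UndefinedResultError:
                breakdown = None
            report.breakdowns[label] = breakdown
            path = outdir / f"proteoforms_{label}.tsv"
            rows = (
                [
                    (cat, breakdown.counts[cat], f"{breakdown.percentages[cat]:.2f}")
                    for cat in breakdown.counts
                ]
                if breakdown
                else []
            )
            _write_table(path, ["category", "count", "percent"], rows, mhash)
            report.outputs[f"proteoforms_{label}"] = path

    with stage("diseases"):
        import warnings as _warnings

        for label in labels:
            genes = report.networks[label].protein_nodes
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                ranking = top_diseases(diseases, genes, k=top_k, aggregate=aggregation)
            report.disease_rankings[label] = ranking
            path = outdir / f"diseases_{label}.tsv"
            _write_table(
                path,
                ["disease", "score", "supporting_genes"],
                (
                    (e.disease, f"{e.score:.6g}", ",".join(e.genes))
                    for e in ranking.entries
                ),
                mhash,
            )
            report.outputs[f"diseases_{label}"] = path

    with stage("manifest"):
        path = outdir / "run_manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(manifest.canonical_json())
            fh.write("\n")
        report.outputs["manifest"] = path

    return report
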