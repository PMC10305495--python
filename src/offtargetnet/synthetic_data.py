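"""Seeded generators for synthetic drug/interactome snapshots.

Every pipeline stage is testable without any database download: the
generators emit a drug→target table, a PPI interactome, GO-style
annotations, a disease table, proteoform events, and SMILES strings, with
the ground truth (true neighbor sets, planted enriched term, planted top
disease, planted neighbor overlap, per-protein proteoform totals) recorded
at generation time so downstream results can be checked exactly.

The interactome grows by preferential attachment (each new node attaches
to m existing nodes with probability proportional to degree+1), producing
the right-skewed, hub-dominated degree distribution characteristic of real
protein interactomes; a configurable fraction of nodes receive self-pairs
to emulate dimers.  The drug table mirrors the structure of a drug class:
several drugs sharing one hub receptor (some with a personal second
target) plus singleton drugs elsewhere.  Neighbor overlap between one
planted pair of drugs is constructed exactly — two fresh target nodes
wired to a shared pool and private pools of chosen sizes — rather than
sampled, so the expected Jaccard counts are exact set arithmetic.

All randomness flows from one integer seed through per-component
substreams; reruns are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigError
from .io_core import (
    AnnotationTable,
    DiseaseRow,
    DiseaseTable,
    DrugRecord,
    DrugTargetRow,
    DrugTargetTable,
    Interactome,
    ProteoformRecord,
    ProteoformTable,
    write_annotations,
    write_diseases,
    write_drug_targets,
    write_ppi_edges,
    write_proteoforms,
)

_PTM_WEIGHTS_DEFAULT: dict[str, float] = {
    "modified_residue": 0.45,
    "chain": 0.12,
    "glycosylation": 0.10,
    "disulfide_bond": 0.09,
    "cross_link": 0.06,
    "signal": 0.04,
    "peptide": 0.04,
    "lipidation": 0.03,
    "initiator_methionine": 0.03,
    "propeptide": 0.02,
    "transit_peptide": 0.02,
}

_SMILES_POOL = (
    "CCO", "CCC", "CCN", "CC(C)O", "c1ccccc1", "CC(=O)O", "CCCC",
    "CCOC", "CC(C)C", "c1ccncc1", "CC(N)C(=O)O", "C1CCCCC1",
)


@dataclass
class SimConfig:
    """All knobs of the synthetic snapshot, fully determined by ``seed``."""

    seed: int = 0
    # interactome
    n_proteins: int = 1000
    attachment_m: int = 3
    self_pair_fraction: float = 0.05
    # drugs
    n_drugs: int = 40
    class_size: int = 6
    n_class_second_targets: int = 2
    include_nonhuman_row: bool = True
    # planted neighbor overlap between one drug pair
    neighbor_overlap: float = 0.5
    overlap_union_size: int = 40
    # annotations
    n_terms: int = 50
    term_rate: float = 0.05
    planted_term: str = "GO:9999999"
    planted_fold: float = 5.0
    planted_study_size: int = 20
    # proteoforms
    ptm_event_rate: float = 4.0
    ptm_category_weights: dict[str, float] = field(
        default_factory=lambda: dict(_PTM_WEIGHTS_DEFAULT)
    )
    allelic_rate: float = 1.5
    splice_rate: float = 2.5
    # diseases
    n_diseases: int = 30
    diseases_per_gene: float = 2.0
    disease_beta_a: float = 2.0
    disease_beta_b: float = 5.0
    planted_disease: str = "planted index disease"

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.n_drugs <= 0 or self.n_terms <= 0:
            raise ConfigError("counts must be positive")
        if self.attachment_m < 1 or self.attachment_m >= self.n_proteins:
            raise ConfigError("need 1 <= attachment_m < n_proteins")
        if not 0.0 <= self.self_pair_fraction <= 1.0:
            raise ConfigError("self_pair_fraction must lie in [0, 1]")
        if not 0.0 <= self.neighbor_overlap <= 1.0:
            raise ConfigError("neighbor_overlap must lie in [0, 1]")
        if self.overlap_union_size < 1 or self.overlap_union_size > self.n_proteins:
            raise ConfigError("overlap_union_size must be in [1, n_proteins]")
        if self.class_size + 2 > self.n_drugs:
            raise ConfigError("n_drugs must cover the class plus the overlap pair")
        if self.class_size + self.n_class_second_targets + 2 > self.n_proteins:
            raise ConfigError("more requested targets than proteins")
        if not 0.0 < self.term_rate < 1.0:
            raise ConfigError("term_rate must lie in (0, 1)")
        if self.planted_fold < 1.0:
            raise ConfigError("planted_fold must be >= 1 (1 means no planting)")
        weights = self.ptm_category_weights
        if any(w < 0 for w in weights.values()):
            raise ConfigError("PTM category weights must be non-negative")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ConfigError("PTM category weights must sum to 1")


@dataclass
class GroundTruth:
    """Generation-time bookkeeping for exact downstream checks."""

    self_pair_nodes: frozenset[str] = frozenset()
    hub_target: str | None = None
    target_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    neighbor_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    comparison_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    overlap_pair: tuple[str, str] | None = None
    expected_overlap_counts: dict[str, tuple[int, int, int]] = field(
        default_factory=dict
    )
    planted_term: str | None = None
    planted_study: frozenset[str] | None = None
    planted_counts: tuple[int, int, int, int] | None = None  # (k, n, K, N)
    achieved_fold: float | None = None
    planted_disease: str | None = None
    planted_gene: str | None = None
    proteoform_totals: dict[str, int] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(**{**asdict_shallow(self), **{
            k: v for k, v in asdict_shallow(other).items() if v not in (None, {}, frozenset())
        }})
        return out

    def to_json_dict(self) -> dict:
        def conv(v):
            if isinstance(v, frozenset):
                return sorted(v)
            if isinstance(v, dict):
                return {str(k): conv(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {k: conv(v) for k, v in asdict_shallow(self).items()}


def asdict_shallow(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _protein_name(i: int) -> str:
    return f"P{i:06d}"


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_interactome(cfg: SimConfig) -> tuple[Interactome, GroundTruth]:
    """Preferential-attachment interactome with optional self-pairs.

    With ``attachment_m == 1`` the non-self edges form a tree.  Fully
    determined by the seed.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    n, m = cfg.n_proteins, cfg.attachment_m
    names = [_protein_name(i + 1) for i in range(n)]
    net = Interactome(nodes=names[:m])
    degrees = np.zeros(n, dtype=float)
    for i in range(m, n):
        weights = degrees[:i] + 1.0
        targets = rng.choice(i, size=m, replace=False, p=weights / weights.sum())
        for t in targets:
            net.add_edge(names[i], names[int(t)])
            degrees[i] += 1
            degrees[int(t)] += 1
    n_self = int(round(cfg.self_pair_fraction * n))
    self_nodes: list[str] = []
    if n_self:
        chosen = rng.choice(n, size=n_self, replace=False)
        self_nodes = [names[int(i)] for i in sorted(chosen)]
        for s in self_nodes:
            net.add_edge(s, s)
    return net, GroundTruth(self_pair_nodes=frozenset(self_nodes))


def _adjacency(interactome: Interactome) -> dict[str, set[str]]:
    # independent edge-list scan (generator bookkeeping, not first_neighbors)
    adj: dict[str, set[str]] = {n: set() for n in interactome.nodes}
    for a, b in interactome.edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def simulate_drug_targets(
    cfg: SimConfig, interactome: Interactome
) -> tuple[list[DrugRecord], DrugTargetTable, GroundTruth]:
    """Drug class on the hub receptor plus singletons and the planted
    overlap pair.

    The class drugs all bind the top-degree protein (the hub); the first
    ``n_class_second_targets`` members get a personal second target.  Two
    extra drugs bind two *fresh* target nodes that are wired into the
    interactome against shared/private neighbor pools so the pair's
    neighbor overlap is exact by construction (mutates ``interactome`` by
    adding those nodes and edges).  Remaining drugs are singletons on
    random proteins.
    """
    cfg.validate()
    if interactome.n_nodes == 0:
        raise ConfigError("interactome is empty")
    rng = _rng(cfg, 2)
    base_nodes = sorted(interactome.nodes)
    adj0 = _adjacency(interactome)
    hub = max(base_nodes, key=lambda p: (len(adj0[p]), p))

    # --- planted overlap pair: exact shared/private pools
    s = int(round(cfg.neighbor_overlap * cfg.overlap_union_size))
    priv = cfg.overlap_union_size - s
    ua, ub = priv - priv // 2, priv // 2
    pool_candidates = [p for p in base_nodes if p != hub]
    pool = [
        pool_candidates[int(i)]
        for i in rng.choice(len(pool_candidates), size=cfg.overlap_union_size,
                            replace=False)
    ]
    shared, priv_a, priv_b = pool[:s], pool[s:s + ua], pool[s + ua:]
    ta, tb = "Q900001", "Q900002"
    for x in shared + priv_a:
        interactome.add_edge(ta, x)
    for x in shared + priv_b:
        interactome.add_edge(tb, x)
    if not shared + priv_a:
        interactome.add_node(ta)
    if not shared + priv_b:
        interactome.add_node(tb)

    # --- drug roster
    n_singletons = cfg.n_drugs - cfg.class_size - 2
    records: list[DrugRecord] = []
    rows: list[DrugTargetRow] = []
    second_targets = [
        p for p in base_nodes if p != hub
    ]
    second_pick = rng.choice(len(second_targets),
                             size=cfg.n_class_second_targets, replace=False)
    singleton_pick = rng.choice(len(base_nodes), size=max(n_singletons, 0),
                                replace=True)

    def drug_id(i: int) -> str:
        return f"D{i:03d}"

    idx = 1
    class_ids: list[str] = []
    for j in range(cfg.class_size):
        did = drug_id(idx)
        records.append(
            DrugRecord(did, f"classdrug-{j + 1}",
                       smiles=_SMILES_POOL[idx % len(_SMILES_POOL)],
                       group="classA")
        )
        rows.append(DrugTargetRow(did, hub, "HUMAN"))
        if j < cfg.n_class_second_targets:
            rows.append(
                DrugTargetRow(did, second_targets[int(second_pick[j])], "HUMAN")
            )
        class_ids.append(did)
        idx += 1
    da, db = drug_id(idx), drug_id(idx + 1)
    records.append(DrugRecord(da, "overlap-a",
                              smiles=_SMILES_POOL[idx % len(_SMILES_POOL)]))
    rows.append(DrugTargetRow(da, ta, "HUMAN"))
    records.append(DrugRecord(db, "overlap-b",
                              smiles=_SMILES_POOL[(idx + 1) % len(_SMILES_POOL)]))
    rows.append(DrugTargetRow(db, tb, "HUMAN"))
    idx += 2
    for j in range(max(n_singletons, 0)):
        did = drug_id(idx)
        records.append(DrugRecord(did, f"singleton-{j + 1}",
                                  smiles=_SMILES_POOL[idx % len(_SMILES_POOL)]))
        rows.append(DrugTargetRow(did, base_nodes[int(singleton_pick[j])], "HUMAN"))
        idx += 1
    if cfg.include_nonhuman_row:
        # a viral-target row, excluded from human network builds
        rows.append(DrugTargetRow(class_ids[0], "R1AB0001", "SARS-CoV-2"))

    rows.sort(key=lambda r: (r.drug_id, r.target, r.organism))
    table = DrugTargetTable(rows=tuple(rows),
                            drugs={r.drug_id: r for r in records})

    # --- ground truth by direct edge-list scan
    adj = _adjacency(interactome)
    gt = GroundTruth(hub_target=hub, overlap_pair=(da, db))
    for rec in records:
        targets = frozenset(
            r.target for r in rows
            if r.drug_id == rec.drug_id and r.organism == "HUMAN"
        )
        nbrs: set[str] = set()
        for t in targets:
            nbrs |= adj[t]
        gt.target_sets[rec.drug_id] = targets
        gt.neighbor_sets[rec.drug_id] = frozenset(nbrs - targets)
        gt.comparison_sets[rec.drug_id] = frozenset(nbrs | targets)
    set_a, set_b = gt.neighbor_sets[da], gt.neighbor_sets[db]
    gt.expected_overlap_counts["neighbors_only"] = (
        len(set_a & set_b), len(set_a - set_b), len(set_b - set_a)
    )
    cmp_a, cmp_b = gt.comparison_sets[da], gt.comparison_sets[db]
    gt.expected_overlap_counts["with_targets"] = (
        len(cmp_a & cmp_b), len(cmp_a - cmp_b), len(cmp_b - cmp_a)
    )
    assert gt.expected_overlap_counts["neighbors_only"] == (s, ua, ub)
    return records, table, gt


def simulate_annotations(
    cfg: SimConfig,
    proteins: list[str],
    study_set: frozenset[str] | None = None,
) -> tuple[AnnotationTable, GroundTruth]:
    """Uniform background term assignment with one optionally planted
    enriched term.

    Background terms annotate each protein independently at
    ``term_rate``.  When ``planted_fold > 1`` the planted term is given
    exactly k study hits and K_out non-study hits chosen so the study
    set's fold enrichment meets the requested fold (up to integer
    rounding); ``planted_fold == 1`` plants nothing (the null model).
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    names = sorted(proteins)
    N = len(names)
    if N == 0:
        raise ConfigError("no proteins to annotate")
    rows: dict[str, set[str]] = {p: set() for p in names}
    term_names: dict[str, str] = {}
    for i in range(cfg.n_terms):
        term = f"GO:{i + 1:07d}"
        term_names[term] = f"molecular-function-{i + 1:03d}"
        mask = rng.random(N) < cfg.term_rate
        for p, hit in zip(names, mask):
            if hit:
                rows[p].add(term)

    gt = GroundTruth()
    if cfg.planted_fold > 1.0:
        if study_set is None:
            pick = rng.choice(N, size=min(cfg.planted_study_size, N), replace=False)
            study = frozenset(names[int(i)] for i in pick)
        else:
            study = frozenset(study_set)
            stray = study - set(names)
            if stray:
                raise ConfigError(f"study genes not among proteins: {sorted(stray)[:3]}")
        n = len(study)
        if cfg.planted_fold * n >= N:
            raise ConfigError(
                f"fold {cfg.planted_fold} unachievable: fold*n={cfg.planted_fold * n} >= N={N}"
            )
        non_study = sorted(set(names) - study)
        k_out = int(round(cfg.term_rate * len(non_study)))
        k = int(round(cfg.planted_fold * n * k_out / (N - cfg.planted_fold * n)))
        if not 1 <= k <= n:
            raise ConfigError(
                f"planted hit count k={k} outside [1, n={n}]; adjust sizes"
            )
        term = cfg.planted_term
        term_names[term] = "planted-function"
        study_sorted = sorted(study)
        for i in rng.choice(n, size=k, replace=False):
            rows[study_sorted[int(i)]].add(term)
        for i in rng.choice(len(non_study), size=k_out, replace=False):
            rows[non_study[int(i)]].add(term)
        K = k + k_out
        gt.planted_term = term
        gt.planted_study = study
        gt.planted_counts = (k, n, K, N)
        gt.achieved_fold = (k / n) / (K / N)
    table = AnnotationTable(rows=rows, term_names=term_names)
    return table, gt


def simulate_proteoforms(
    cfg: SimConfig, proteins: list[str]
) -> tuple[ProteoformTable, GroundTruth]:
    """Multinomial PTM categories plus Poisson allelic/splice counts per
    protein, with the per-protein totals recorded."""
    cfg.validate()
    rng = _rng(cfg, 4)
    cats = sorted(cfg.ptm_category_weights)
    weights = np.array([cfg.ptm_category_weights[c] for c in cats])
    weights = weights / weights.sum()
    rows: dict[str, ProteoformRecord] = {}
    totals: dict[str, int] = {}
    for p in sorted(proteins):
        n_events = int(rng.poisson(cfg.ptm_event_rate))
        drawn = rng.choice(len(cats), size=n_events, p=weights)
        events = tuple((cats[int(i)], f"{cats[int(i)]} event") for i in drawn)
        allelic = int(rng.poisson(cfg.allelic_rate))
        splice = int(rng.poisson(cfg.splice_rate))
        rows[p] = ProteoformRecord(
            ptm_events=events,
            allelic_variant_count=allelic,
            splice_transcript_count=splice,
        )
        totals[p] = n_events + allelic + splice
    return ProteoformTable(rows=rows), GroundTruth(proteoform_totals=totals)


def simulate_diseases(
    cfg: SimConfig, genes: list[str], planted_gene: str | None = None
) -> tuple[DiseaseTable, GroundTruth]:
    """Beta-distributed association scores capped below the planted
    disease's score, so the planted disease dominates any ranking that
    includes the planted gene."""
    cfg.validate()
    rng = _rng(cfg, 5)
    catalog = [f"disease-{i + 1:02d}" for i in range(cfg.n_diseases)]
    names = sorted(genes)
    rows: list[DiseaseRow] = []
    for g in names:
        n_d = min(int(rng.poisson(cfg.diseases_per_gene)), cfg.n_diseases)
        if n_d == 0:
            continue
        picks = rng.choice(cfg.n_diseases, size=n_d, replace=False)
        scores = rng.beta(cfg.disease_beta_a, cfg.disease_beta_b, size=n_d) * 0.9
        rows.extend(
            DiseaseRow(g, catalog[int(i)], float(s))
            for i, s in zip(picks, scores)
        )
    planted_gene = planted_gene if planted_gene is not None else names[0]
    rows.append(DiseaseRow(planted_gene, cfg.planted_disease, 0.95))
    rows.sort(key=lambda r: (r.gene, r.disease))
    table = DiseaseTable(rows=tuple(rows))
    return table, GroundTruth(
        planted_disease=cfg.planted_disease, planted_gene=planted_gene
    )


# ---------------------------------------------------------------------------
# snapshot bundle
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSnapshot:
    config: SimConfig
    interactome: Interactome
    drug_records: list[DrugRecord]
    drug_targets: DrugTargetTable
    annotations: AnnotationTable
    diseases: DiseaseTable
    proteoforms: ProteoformTable
    groups: dict[str, list[str]]
    ground_truth: GroundTruth


def simulate_snapshot(cfg: SimConfig) -> SyntheticSnapshot:
    """Generate the full consistent snapshot suite.

    The enriched term is planted inside the drug class's target∪neighbor
    set and the top disease on the class's hub receptor, so both surface
    at rank 1 when the pipeline analyses the ``drug-class`` group.
    """
    cfg.validate()
    interactome, gt_net = simulate_interactome(cfg)
    records, dt, gt_drugs = simulate_drug_targets(cfg, interactome)
    gt = gt_net.merged_with(gt_drugs)

    class_ids = sorted(
        r.drug_id for r in records if r.group == "classA"
    )
    da, db = gt.overlap_pair
    groups = {"drug-class": class_ids, "pair-a": [da], "pair-b": [db]}
    class_proteins: set[str] = set()
    for d in class_ids:
        class_proteins |= gt.comparison_sets[d]
    gt.comparison_sets["drug-class"] = frozenset(class_proteins)
    gt.target_sets["drug-class"] = frozenset().union(
        *(gt.target_sets[d] for d in class_ids)
    )
    gt.neighbor_sets["drug-class"] = frozenset(
        class_proteins - gt.target_sets["drug-class"]
    )
    gt.comparison_sets["pair-a"] = gt.comparison_sets[da]
    gt.comparison_sets["pair-b"] = gt.comparison_sets[db]
    gt.neighbor_sets["pair-a"] = gt.neighbor_sets[da]
    gt.neighbor_sets["pair-b"] = gt.neighbor_sets[db]

    proteins = sorted(interactome.nodes)
    annotations, gt_ann = simulate_annotations(
        cfg, proteins, study_set=gt.comparison_sets["drug-class"]
    )
    proteoforms, gt_pf = simulate_proteoforms(cfg, proteins)
    diseases, gt_dis = simulate_diseases(cfg, proteins, planted_gene=gt.hub_target)
    gt = gt.merged_with(gt_ann).merged_with(gt_pf).merged_with(gt_dis)
    return SyntheticSnapshot(
        config=cfg,
        interactome=interactome,
        drug_records=records,
        drug_targets=dt,
        annotations=annotations,
        diseases=diseases,
        proteoforms=proteoforms,
        groups=groups,
        ground_truth=gt,
    )


def write_snapshot(snap: SyntheticSnapshot, outdir: str | Path) -> dict[str, Path]:
    """Write the snapshot as the TSV suite + ground-truth JSON + a ready
    pipeline configuration; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drug_targets": outdir / "drug_targets.tsv",
        "ppi": outdir / "ppi_edges.tsv",
        "annotations": outdir / "annotations.tsv",
        "diseases": outdir / "diseases.tsv",
        "proteoforms": outdir / "proteoforms.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "pipeline_config": outdir / "pipeline_config.json",
    }
    write_drug_targets(snap.drug_records, snap.drug_targets, paths["drug_targets"])
    write_ppi_edges(snap.interactome, paths["ppi"])
    write_annotations(snap.annotations, paths["annotations"])
    write_diseases(snap.diseases, paths["diseases"])
    write_proteoforms(snap.proteoforms, paths["proteoforms"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(snap.ground_truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    config = {
        "inputs": {
            k: str(paths[k])
            for k in ("drug_targets", "ppi", "annotations", "diseases", "proteoforms")
        },
        "groups": snap.groups,
        "organism": "HUMAN",
        "collapse_groups": False,
        "alpha": 0.05,
        "include_targets_in_comparison": True,
        "disease_aggregation": "max",
        "top_diseases": 10,
        "seed": snap.config.seed,
    }
    with open(paths["pipeline_config"], "w", encoding="utf-8") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
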