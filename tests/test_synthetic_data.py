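"""Seeded snapshot generators: determinism, planted structure, realism."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from offtargetnet.exceptions import ConfigError
from offtargetnet.network_build import build_protein_drug_network, first_neighbors
from offtargetnet.similarity import neighbor_jaccard
from offtargetnet.synthetic_data import (
    SimConfig,
    simulate_annotations,
    simulate_diseases,
    simulate_drug_targets,
    simulate_interactome,
    simulate_proteoforms,
    simulate_snapshot,
)


class TestInteractomeGenerator:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=5, n_proteins=150, n_drugs=10, overlap_union_size=20)
        a, _ = simulate_interactome(cfg)
        b, _ = simulate_interactome(cfg)
        assert a == b

    def test_m1_gives_tree_plus_self_pairs(self):
        cfg = SimConfig(seed=2, n_proteins=80, attachment_m=1, n_drugs=10,
                        overlap_union_size=10)
        net, gt = simulate_interactome(cfg)
        plain = [(a, b) for a, b in net.edges if a != b]
        assert len(plain) == cfg.n_proteins - 1
        assert net.n_edges == cfg.n_proteins - 1 + len(gt.self_pair_nodes)
        g = nx.Graph(plain)
        assert nx.is_connected(g) and nx.is_tree(g)

    def test_zero_self_pair_fraction(self):
        cfg = SimConfig(seed=3, n_proteins=60, self_pair_fraction=0.0, n_drugs=10,
                        overlap_union_size=10)
        net, gt = simulate_interactome(cfg)
        assert net.self_pairs() == set() and gt.self_pair_nodes == frozenset()

    def test_degree_distribution_right_skewed(self):
        cfg = SimConfig(seed=1, n_proteins=300, n_drugs=10, overlap_union_size=10)
        net, _ = simulate_interactome(cfg)
        degs = sorted(len(list(net.graph.neighbors(n))) for n in net.nodes)
        assert degs[-1] >= 3 * degs[len(degs) // 2]

    def test_invalid_attachment_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_proteins=5, attachment_m=5, n_drugs=3,
                      overlap_union_size=2, class_size=1).validate()


class TestDrugTargetGenerator:
    @pytest.fixture
    def ecosystem(self):
        cfg = SimConfig(seed=8, n_proteins=200, n_drugs=14, overlap_union_size=30,
                        neighbor_overlap=0.5)
        inter, _ = simulate_interactome(cfg)
        records, dt, gt = simulate_drug_targets(cfg, inter)
        return cfg, inter, records, dt, gt

    def test_class_members_share_hub_neighbor_sets(self, ecosystem):
        cfg, inter, records, dt, gt = ecosystem
        class_ids = [r.drug_id for r in records if r.group == "classA"]
        assert len(class_ids) == cfg.class_size
        # members without a second target share identical true neighbor sets
        plain = [d for d in class_ids if len(gt.target_sets[d]) == 1]
        sets = {gt.neighbor_sets[d] for d in plain}
        assert len(sets) == 1

    def test_planted_overlap_counts_are_exact(self, ecosystem):
        cfg, inter, records, dt, gt = ecosystem
        da, db = gt.overlap_pair
        m11, m10, m01 = gt.expected_overlap_counts["neighbors_only"]
        assert m11 + m10 + m01 == cfg.overlap_union_size
        assert m11 == round(cfg.neighbor_overlap * cfg.overlap_union_size)
        cmp = neighbor_jaccard(
            set(gt.neighbor_sets[da]), set(gt.neighbor_sets[db])
        )
        assert (cmp.m11, cmp.m10, cmp.m01) == (m11, m10, m01)
        assert cmp.jaccard == pytest.approx(
            cfg.neighbor_overlap, abs=1 / cfg.overlap_union_size
        )

    def test_full_overlap_forces_identical_sets(self):
        cfg = SimConfig(seed=8, n_proteins=150, n_drugs=10, overlap_union_size=20,
                        neighbor_overlap=1.0)
        inter, _ = simulate_interactome(cfg)
        _, _, gt = simulate_drug_targets(cfg, inter)
        m11, m10, m01 = gt.expected_overlap_counts["neighbors_only"]
        assert (m10, m01) == (0, 0) and m11 == 20

    def test_ground_truth_matches_pipeline_extraction(self, ecosystem):
        """The generator's recorded neighbor sets equal what the real
        builder extracts from the emitted files' contents."""
        cfg, inter, records, dt, gt = ecosystem
        for rec in records:
            net = build_protein_drug_network(inter, dt, {rec.drug_id})
            assert net.comparison_set(True) == gt.comparison_sets[rec.drug_id]
            assert frozenset(net.nodes_of_type("neighbor")) == gt.neighbor_sets[rec.drug_id]

    def test_nonhuman_row_present_but_filtered(self, ecosystem):
        cfg, inter, records, dt, gt = ecosystem
        organisms = {r.organism for r in dt.rows}
        assert organisms == {"HUMAN", "SARS-CoV-2"}
        viral = [r for r in dt.rows if r.organism != "HUMAN"]
        assert all(not inter.has_node(r.target) for r in viral)


class TestAnnotationGenerator:
    def test_planted_counts_meet_requested_fold(self):
        cfg = SimConfig(seed=11, n_proteins=400, n_terms=40, planted_fold=5.0,
                        planted_study_size=20, n_drugs=10, overlap_union_size=20)
        proteins = [f"P{i:04d}" for i in range(400)]
        table, gt = simulate_annotations(cfg, proteins)
        k, n, K, N = gt.planted_counts
        assert len(table.genes_with(gt.planted_term)) == K
        assert len(table.genes_with(gt.planted_term) & gt.planted_study) == k
        assert gt.achieved_fold == pytest.approx((k / n) / (K / N))
        assert gt.achieved_fold == pytest.approx(cfg.planted_fold, rel=0.15)

    def test_fold_one_plants_nothing(self):
        cfg = SimConfig(seed=12, n_proteins=200, planted_fold=1.0, n_drugs=10,
                        overlap_union_size=20)
        proteins = [f"P{i}" for i in range(200)]
        table, gt = simulate_annotations(cfg, proteins)
        assert gt.planted_term is None
        assert cfg.planted_term not in table.terms

    def test_unachievable_fold_rejected(self):
        cfg = SimConfig(seed=1, n_proteins=60, planted_fold=5.0,
                        planted_study_size=20, n_drugs=10, overlap_union_size=10)
        with pytest.raises(ConfigError):
            simulate_annotations(cfg, [f"P{i}" for i in range(60)])

    def test_determinism(self):
        cfg = SimConfig(seed=13, n_proteins=200, n_drugs=10, overlap_union_size=20)
        proteins = [f"P{i}" for i in range(200)]
        a, _ = simulate_annotations(cfg, proteins)
        b, _ = simulate_annotations(cfg, proteins)
        assert a.rows == b.rows


class TestProteoformGenerator:
    def test_one_hot_weights_give_single_category(self):
        weights = {"glycosylation": 1.0}
        cfg = SimConfig(seed=3, ptm_category_weights=weights, n_drugs=10,
                        overlap_union_size=20)
        table, _ = simulate_proteoforms(cfg, [f"P{i}" for i in range(30)])
        cats = {c for rec in table.rows.values() for c, _ in rec.ptm_events}
        assert cats <= {"glycosylation"}

    def test_determinism(self):
        cfg = SimConfig(seed=3, n_drugs=10, overlap_union_size=20)
        proteins = [f"P{i}" for i in range(30)]
        a, _ = simulate_proteoforms(cfg, proteins)
        b, _ = simulate_proteoforms(cfg, proteins)
        assert a.rows == b.rows

    def test_category_frequencies_converge_to_weights(self):
        """Pooled frequencies at ~10k events stay within 3 sigma binomial
        error of the configured weights."""
        cfg = SimConfig(seed=21, ptm_event_rate=4.0, n_drugs=10,
                        overlap_union_size=20)
        proteins = [f"P{i:05d}" for i in range(2500)]
        table, gt = simulate_proteoforms(cfg, proteins)
        counts: dict[str, int] = {}
        for rec in table.rows.values():
            for cat, _ in rec.ptm_events:
                counts[cat] = counts.get(cat, 0) + 1
        total = sum(counts.values())
        assert total > 8000
        for cat, w in cfg.ptm_category_weights.items():
            sigma = np.sqrt(w * (1 - w) / total)
            assert abs(counts.get(cat, 0) / total - w) <= 3 * sigma


class TestDiseaseGenerator:
    def test_planted_disease_dominates(self):
        cfg = SimConfig(seed=14, n_drugs=10, overlap_union_size=20)
        genes = [f"G{i}" for i in range(40)]
        table, gt = simulate_diseases(cfg, genes, planted_gene="G3")
        planted_rows = [r for r in table.rows if r.disease == gt.planted_disease]
        assert len(planted_rows) == 1 and planted_rows[0].gene == "G3"
        assert all(
            r.score < planted_rows[0].score
            for r in table.rows
            if r.disease != gt.planted_disease
        )

    def test_determinism(self):
        cfg = SimConfig(seed=15, n_drugs=10, overlap_union_size=20)
        genes = [f"G{i}" for i in range(40)]
        assert simulate_diseases(cfg, genes)[0] == simulate_diseases(cfg, genes)[0]


class TestSnapshot:
    def test_snapshot_internally_consistent(self):
        cfg = SimConfig(seed=17, n_proteins=500, n_drugs=16, overlap_union_size=30,
                        planted_fold=3.0)
        snap = simulate_snapshot(cfg)
        gt = snap.ground_truth
        # planted study is exactly the drug class's comparison set
        assert gt.planted_study == gt.comparison_sets["drug-class"]
        assert gt.planted_gene == gt.hub_target
        # recorded sets agree with direct first-neighbor queries
        for d in snap.groups["drug-class"]:
            nbrs = set()
            for t in gt.target_sets[d]:
                nbrs |= first_neighbors(snap.interactome, t).neighbors
            assert frozenset(nbrs - gt.target_sets[d]) == gt.neighbor_sets[d]
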