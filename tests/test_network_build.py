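"""First-neighbor extraction and protein–drug network assembly."""

from __future__ import annotations

import numpy as np
import pytest

from offtargetnet.exceptions import MissingNodeError, UsageError
from offtargetnet.io_core import (
    DrugRecord,
    DrugTargetRow,
    DrugTargetTable,
    Interactome,
)
from offtargetnet.network_build import (
    build_protein_drug_network,
    first_neighbors,
    merge_focal_targets,
    target_subnetwork,
)

from .oracles import brute_neighbors
from .conftest import random_graph


class TestFirstNeighbors:
    def test_path_midpoint(self):
        net = Interactome(edges=[("A", "B"), ("B", "C")])
        assert first_neighbors(net, "B").neighbors == {"A", "C"}

    def test_self_pair_adds_no_neighbor(self):
        net = Interactome(edges=[("A", "A")])
        assert first_neighbors(net, "A").neighbors == frozenset()

    def test_missing_target_names_accession(self):
        with pytest.raises(MissingNodeError, match="P999"):
            first_neighbors(Interactome(nodes=["A"]), "P999")

    def test_matches_exhaustive_edge_scan_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            nodes, edges = random_graph(rng, n_max=50, p=0.1, self_pairs=True)
            net = Interactome(nodes=nodes, edges=edges)
            hub = max(nodes, key=lambda n: len(brute_neighbors(edges, n)))
            assert first_neighbors(net, hub).neighbors == brute_neighbors(edges, hub)


class TestTargetSubnetwork:
    def test_ten_node_eighteen_edge_neighborhood(self):
        """A single target with 9 neighbors whose induced edges (including
        neighbor–neighbor edges and dimers) number 18."""
        nbrs = [f"N{i}" for i in range(1, 10)]
        edges = [("T", n) for n in nbrs]                      # 9 target edges
        edges += [(nbrs[i], nbrs[i + 1]) for i in range(7)]   # 7 neighbor edges
        edges += [("T", "T"), ("N1", "N1")]                   # 2 dimers
        edges += [("OUT1", "OUT2")]                           # excluded
        sub = target_subnetwork(Interactome(edges=edges), {"T"})
        assert (sub.n_nodes, sub.n_edges) == (10, 18)

    def test_isolated_target(self):
        sub = target_subnetwork(Interactome(nodes=["T"]), {"T"})
        assert (sub.n_nodes, sub.n_edges) == (1, 0)

    def test_star_center_recovers_whole_star(self):
        edges = [("C", f"L{i}") for i in range(5)]
        sub = target_subnetwork(Interactome(edges=edges), {"C"})
        assert sub.nodes == {"C", "L0", "L1", "L2", "L3", "L4"}
        assert sub.n_edges == 5

    def test_missing_targets_all_listed(self):
        with pytest.raises(MissingNodeError, match="PX.*PY"):
            target_subnetwork(Interactome(nodes=["A"]), {"PX", "PY", "A"})


class TestBuildNetwork:
    def test_toy_construction_by_definition(self, toy_interactome):
        dt = DrugTargetTable(
            rows=(
                DrugTargetRow("D1", "T", "HUMAN"),
                DrugTargetRow("D2", "N1", "HUMAN"),
            ),
            drugs={"D1": DrugRecord("D1", "a"), "D2": DrugRecord("D2", "b")},
        )
        net = build_protein_drug_network(toy_interactome, dt, {"D1"})
        assert set(net.graph.nodes) == {"D1", "T", "N1", "N2", "D2"}
        assert net.edges_of_type("binds") == {("D1", "T"), ("D2", "N1")}
        assert net.edges_of_type("ppi") == {("N1", "T"), ("N2", "T")}
        assert net.node_type("T") == "target"
        assert net.node_type("N1") == "neighbor"
        assert net.node_type("D2") == "other_drug"

    def test_group_collapse_keeps_edge_count(self, toy_interactome, toy_drug_table):
        plain = build_protein_drug_network(
            toy_interactome, toy_drug_table, {"D1", "D1b"}, collapse_groups=False
        )
        collapsed = build_protein_drug_network(
            toy_interactome, toy_drug_table, {"D1", "D1b"}, collapse_groups=True
        )
        assert "classA" in collapsed.graph.nodes
        assert "D1" not in collapsed.graph.nodes
        assert collapsed.node_type("classA") == "drug_group"
        # both focal drugs bind the same target, so the collapsed binds
        # edge multiset has one fewer edge than two parallel ones
        assert collapsed.graph.number_of_edges() == plain.graph.number_of_edges() - 1

    def test_empty_focal_set_is_usage_error(self, toy_interactome, toy_drug_table):
        with pytest.raises(UsageError):
            build_protein_drug_network(toy_interactome, toy_drug_table, set())

    def test_focal_drug_without_human_target_errors(self, toy_interactome):
        dt = DrugTargetTable(
            rows=(DrugTargetRow("D1", "T", "MOUSE"),),
            drugs={"D1": DrugRecord("D1", "one")},
        )
        with pytest.raises(UsageError, match="HUMAN"):
            build_protein_drug_network(toy_interactome, dt, {"D1"})

    def test_organism_filter_excludes_nonhuman_rows(self, toy_interactome):
        dt = DrugTargetTable(
            rows=(
                DrugTargetRow("D1", "T", "HUMAN"),
                DrugTargetRow("D1", "VIRALP", "SARS-CoV-2"),
            ),
            drugs={"D1": DrugRecord("D1", "one")},
        )
        net = build_protein_drug_network(toy_interactome, dt, {"D1"})
        assert "VIRALP" not in net.graph.nodes

    def test_build_deterministic_and_row_order_invariant(self, toy_interactome):
        rows = (
            DrugTargetRow("D1", "T", "HUMAN"),
            DrugTargetRow("D2", "N1", "HUMAN"),
        )
        drugs = {"D1": DrugRecord("D1", "a"), "D2": DrugRecord("D2", "b")}
        n1 = build_protein_drug_network(
            toy_interactome, DrugTargetTable(rows=rows, drugs=drugs), {"D1", "D2"}
        )
        n2 = build_protein_drug_network(
            toy_interactome,
            DrugTargetTable(rows=tuple(reversed(rows)), drugs=drugs),
            {"D2", "D1"},
        )
        assert n1 == n2

    def test_enlarging_focal_set_is_monotone(self, toy_interactome, toy_drug_table):
        small = build_protein_drug_network(toy_interactome, toy_drug_table, {"D1"})
        large = build_protein_drug_network(
            toy_interactome, toy_drug_table, {"D1", "D2"}
        )
        assert set(small.graph.nodes) <= set(large.graph.nodes)
        assert set(small.graph.edges) <= set(large.graph.edges)

    def test_summary_counts(self, toy_interactome, toy_drug_table):
        # D1b also binds T, so it enters as an other_drug node
        net = build_protein_drug_network(toy_interactome, toy_drug_table, {"D1"})
        s = net.summary()
        assert s["n_nodes"] == 6 and s["n_edges"] == 5
        assert s["n_target"] == 1 and s["n_neighbor"] == 2
        assert s["n_other_drug"] == 2


class TestMergeFocalTargets:
    def test_idempotent_on_present_target(self, toy_interactome, toy_drug_table):
        base = build_protein_drug_network(toy_interactome, toy_drug_table, {"D1"})
        merged = merge_focal_targets(base, "T", toy_interactome, toy_drug_table)
        assert merged == base

    def test_isolated_bound_target_adds_two_nodes_one_edge(
        self, toy_interactome, toy_drug_table
    ):
        inter = Interactome(edges=[("T", "N1"), ("T", "N2"), ("N1", "X")])
        inter.add_node("ISO")
        dt = DrugTargetTable(
            rows=(
                DrugTargetRow("D1", "T", "HUMAN"),
                DrugTargetRow("D3", "ISO", "HUMAN"),
            ),
            drugs={"D1": DrugRecord("D1", "a"), "D3": DrugRecord("D3", "c")},
        )
        base = build_protein_drug_network(inter, dt, {"D1"})
        merged = merge_focal_targets(base, "ISO", inter, dt)
        assert merged.graph.number_of_nodes() == base.graph.number_of_nodes() + 2
        assert merged.graph.number_of_edges() == base.graph.number_of_edges() + 1
        assert merged.node_type("ISO") == "target"

    def test_merge_equals_rebuild_on_synthetic_data(self):
        """merge(build(X), t) must equal build with the enlarged extra-
        target set, on generated ecosystems."""
        from offtargetnet.synthetic_data import (
            SimConfig,
            simulate_drug_targets,
            simulate_interactome,
        )

        for seed in (0, 1, 2):
            cfg = SimConfig(seed=seed, n_proteins=120, n_drugs=10,
                            overlap_union_size=20)
            inter, _ = simulate_interactome(cfg)
            _, dt, gt = simulate_drug_targets(cfg, inter)
            focal = {gt.overlap_pair[0]}
            extra = sorted(inter.nodes)[5]
            base = build_protein_drug_network(inter, dt, focal)
            merged = merge_focal_targets(base, extra, inter, dt)
            rebuilt = build_protein_drug_network(
                inter, dt, focal, extra_targets=frozenset({extra})
            )
            assert merged == rebuilt
            assert merged.provenance == rebuilt.provenance
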