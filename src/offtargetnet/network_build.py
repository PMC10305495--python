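"""Protein–drug network assembly.

Drug targets are projected into the binary PPI interactome; the proteins
they physically interact with (their first neighbors) are the off-target
candidate set.  A protein–drug network combines the focal drugs, their
targets, the targets' first neighbors, every other drug binding any of
those proteins, ``binds`` edges from drugs to bound proteins, and the full
induced PPI subgraph among the included proteins (neighbor–neighbor edges
and self-pairs included).

Expansion is strictly one hop: neighbors of neighbors are never pulled in.
Drugs connect only to proteins — there are no drug–drug edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .exceptions import MissingNodeError, SnapshotFormatError, UsageError
from .io_core import DEFAULT_ORGANISM, DrugTargetTable, Interactome, ProteinID

NODE_TYPES = ("focal_drug", "drug_group", "target", "neighbor", "other_drug")
PROTEIN_TYPES = frozenset({"target", "neighbor", "protein"})
DRUG_TYPES = frozenset({"focal_drug", "drug_group", "other_drug", "drug"})


@dataclass(frozen=True)
class NeighborSet:
    """First neighbors of one target: the proteins sharing a PPI edge with
    it, the target itself excluded (a self-pair adds no neighbor)."""

    target: ProteinID
    neighbors: frozenset[ProteinID]

    def __post_init__(self) -> None:
        if self.target in self.neighbors:
            raise ValueError("target cannot be its own first neighbor")


class ProteinDrugNetwork:
    """Heterogeneous graph of drugs and proteins with typed nodes/edges.

    Node attribute ``node_type`` is one of :data:`NODE_TYPES` (plus the
    coarse ``drug``/``protein`` labels used when re-reading SIF exports);
    edge attribute ``edge_type`` is ``binds`` (drug–protein) or ``ppi``
    (protein–protein).  ``provenance`` records how the network was built.
    """

    def __init__(self, graph: nx.Graph | None = None,
                 provenance: dict | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.provenance = dict(provenance or {})
        self._check()

    def _check(self) -> None:
        for a, b, data in self.graph.edges(data=True):
            etype = data.get("edge_type")
            ta = self.graph.nodes[a].get("node_type")
            tb = self.graph.nodes[b].get("node_type")
            if etype == "binds":
                if not (
                    (ta in DRUG_TYPES and tb in PROTEIN_TYPES)
                    or (tb in DRUG_TYPES and ta in PROTEIN_TYPES)
                ):
                    raise SnapshotFormatError(
                        f"binds edge {a}–{b} must connect a drug to a protein"
                    )
            elif etype == "ppi":
                if ta not in PROTEIN_TYPES or tb not in PROTEIN_TYPES:
                    raise SnapshotFormatError(
                        f"ppi edge {a}–{b} must connect two proteins"
                    )

    # -- accessors --------------------------------------------------------
    def node_type(self, node: str) -> str:
        try:
            return self.graph.nodes[node]["node_type"]
        except KeyError:
            raise MissingNodeError(f"node {node!r} not in network") from None

    def nodes_of_type(self, *types: str) -> set[str]:
        return {
            n for n, d in self.graph.nodes(data=True) if d.get("node_type") in types
        }

    @property
    def protein_nodes(self) -> set[str]:
        return self.nodes_of_type(*PROTEIN_TYPES)

    @property
    def drug_nodes(self) -> set[str]:
        return self.nodes_of_type(*DRUG_TYPES)

    def edges_of_type(self, etype: str) -> set[tuple[str, str]]:
        return {
            (a, b) if a <= b else (b, a)
            for a, b, d in self.graph.edges(data=True)
            if d.get("edge_type") == etype
        }

    def comparison_set(self, include_targets: bool = True) -> frozenset[str]:
        """Protein set used for neighbor-overlap comparison between
        networks: first neighbors, optionally unioned with the targets."""
        if include_targets:
            return frozenset(self.nodes_of_type("neighbor", "target"))
        return frozenset(self.nodes_of_type("neighbor"))

    def summary(self) -> dict[str, int]:
        """Node/edge counts; edges reported both with and without
        self-pairs since conventions differ on whether dimers count."""
        self_pairs = sum(1 for a, b in self.graph.edges if a == b)
        counts = {t: len(self.nodes_of_type(t)) for t in NODE_TYPES}
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "n_edges_excluding_self": self.graph.number_of_edges() - self_pairs,
            "n_self_pairs": self_pairs,
            **{f"n_{t}": v for t, v in counts.items()},
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinDrugNetwork):
            return NotImplemented
        return nx.utils.graphs_equal(self.graph, other.graph)

    def __repr__(self) -> str:
        s = self.summary()
        return f"ProteinDrugNetwork(n_nodes={s['n_nodes']}, n_edges={s['n_edges']})"


def first_neighbors(interactome: Interactome, target: ProteinID) -> NeighborSet:
    """All proteins sharing a PPI edge with ``target``, excluding itself."""
    if not interactome.has_node(target):
        raise MissingNodeError(f"target {target!r} not in interactome")
    nbrs = frozenset(n for n in interactome.graph.neighbors(target) if n != target)
    return NeighborSet(target=target, neighbors=nbrs)


def target_subnetwork(
    interactome: Interactome, targets: set[ProteinID]
) -> Interactome:
    """Induced PPI subgraph on the targets and their first neighbors.

    All edges among the included nodes are retained, including
    neighbor–neighbor edges and self-pairs.
    """
    missing = sorted(t for t in targets if not interactome.has_node(t))
    if missing:
        raise MissingNodeError(f"targets not in interactome: {', '.join(missing)}")
    included: set[ProteinID] = set(targets)
    for t in targets:
        included |= first_neighbors(interactome, t).neighbors
    sub = Interactome(nodes=sorted(included))
    for a, b in interactome.edges:
        if a in included and b in included:
            sub.add_edge(a, b)
    return sub


def build_protein_drug_network(
    interactome: Interactome,
    dt: DrugTargetTable,
    focal_drugs: set[str],
    collapse_groups: bool = False,
    organism: str | None = DEFAULT_ORGANISM,
    extra_targets: frozenset[ProteinID] = frozenset(),
) -> ProteinDrugNetwork:
    """Assemble the protein–drug network around a set of focal drugs.

    Included nodes: the focal drugs (collapsed to one node per group label
    when ``collapse_groups`` is set), their targets plus ``extra_targets``,
    the targets' first neighbors, and every other drug in ``dt`` binding
    any included protein.  Only drug→target rows matching ``organism``
    (default HUMAN) enter the build; pass ``organism=None`` to disable the
    filter.
    """
    if not focal_drugs:
        raise UsageError("focal drug set is empty")
    unknown = sorted(d for d in focal_drugs if d not in dt.drugs)
    if unknown:
        raise MissingNodeError(f"focal drugs not in drug-target table: {', '.join(unknown)}")

    focal_targets: dict[str, set[ProteinID]] = {}
    for d in sorted(focal_drugs):
        targets = dt.targets_of(d, organism=organism)
        if not targets:
            raise UsageError(
                f"focal drug {d!r} has no target for organism {organism!r}"
            )
        focal_targets[d] = targets

    target_set: set[ProteinID] = set(extra_targets)
    for targets in focal_targets.values():
        target_set |= targets
    missing = sorted(t for t in target_set if not interactome.has_node(t))
    if missing:
        raise MissingNodeError(f"targets not in interactome: {', '.join(missing)}")

    neighbor_set: set[ProteinID] = set()
    for t in sorted(target_set):
        neighbor_set |= first_neighbors(interactome, t).neighbors
    proteins = target_set | neighbor_set

    clash = proteins & set(dt.drugs)
    if clash:
        raise SnapshotFormatError(
            f"identifiers used as both drug and protein: {sorted(clash)}"
        )

    g = nx.Graph()
    for p in sorted(proteins):
        g.add_node(p, node_type="target" if p in target_set else "neighbor")
    for a, b in sorted(interactome.edges):
        if a in proteins and b in proteins:
            g.add_edge(a, b, edge_type="ppi")

    # focal drug nodes (optionally collapsed per group label)
    focal_node_of: dict[str, str] = {}
    for d in sorted(focal_drugs):
        group = dt.drugs[d].group
        if collapse_groups and group:
            focal_node_of[d] = group
            if not g.has_node(group):
                g.add_node(group, node_type="drug_group", group=group)
        else:
            focal_node_of[d] = d
            g.add_node(d, node_type="focal_drug", group=group)
    for d in sorted(focal_drugs):
        node = focal_node_of[d]
        for t in sorted(dt.targets_of(d, organism=organism) & proteins):
            g.add_edge(node, t, edge_type="binds")

    # other drugs binding any included protein
    for p in sorted(proteins):
        for d in sorted(dt.drugs_binding(p, organism=organism)):
            if d in focal_drugs:
                continue
            if not g.has_node(d):
                g.add_node(d, node_type="other_drug", group=dt.drugs[d].group)
            g.add_edge(d, p, edge_type="binds")

    provenance = {
        "focal_drugs": tuple(sorted(focal_drugs)),
        "extra_targets": tuple(sorted(extra_targets)),
        "collapse_groups": collapse_groups,
        "organism": organism,
    }
    return ProteinDrugNetwork(graph=g, provenance=provenance)


def merge_focal_targets(
    base: ProteinDrugNetwork,
    extra_target: ProteinID,
    interactome: Interactome,
    dt: DrugTargetTable,
) -> ProteinDrugNetwork:
    """Union ``base`` with one extra target's neighborhood and its drugs.

    Adds the target, its first neighbors, all induced PPI edges touching
    the newly included proteins, and binds edges for every drug binding a
    newly included protein.  Idempotent when the target (typed as target)
    is already included; equivalent to rebuilding from scratch with the
    enlarged extra-target set.
    """
    if not interactome.has_node(extra_target):
        raise MissingNodeError(f"target {extra_target!r} not in interactome")
    organism = base.provenance.get("organism", DEFAULT_ORGANISM)

    g = base.graph.copy()
    old_proteins = {
        n for n, d in g.nodes(data=True) if d.get("node_type") in PROTEIN_TYPES
    }
    new_nbrs = first_neighbors(interactome, extra_target).neighbors
    new_proteins = ({extra_target} | new_nbrs) - old_proteins

    if g.has_node(extra_target):
        g.nodes[extra_target]["node_type"] = "target"
    else:
        g.add_node(extra_target, node_type="target")
    for p in sorted(new_proteins - {extra_target}):
        g.add_node(p, node_type="neighbor")

    # induced ppi edges touching at least one newly added protein
    proteins = old_proteins | new_proteins | {extra_target}
    for p in sorted(new_proteins | {extra_target}):
        for q in interactome.graph.neighbors(p):
            if q in proteins:
                g.add_edge(p, q, edge_type="ppi")

    # drugs binding newly included proteins (and binds edges from already
    # present drugs to those proteins)
    focal = set(base.provenance.get("focal_drugs", ()))
    collapse = base.provenance.get("collapse_groups", False)
    for p in sorted(new_proteins | {extra_target}):
        for d in sorted(dt.drugs_binding(p, organism=organism)):
            if d in focal:
                node = dt.drugs[d].group if (collapse and dt.drugs[d].group) else d
            else:
                node = d
                if not g.has_node(d):
                    g.add_node(d, node_type="other_drug", group=dt.drugs[d].group)
            if g.has_node(node):
                g.add_edge(node, p, edge_type="binds")

    provenance = dict(base.provenance)
    extra = set(provenance.get("extra_targets", ())) | {extra_target}
    provenance["extra_targets"] = tuple(sorted(extra))
    return ProteinDrugNetwork(graph=g, provenance=provenance)
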