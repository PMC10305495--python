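"""Topological statistics of interactomes and protein–drug networks.

All distances treat the network as unweighted and undirected; ``binds``
and ``ppi`` edges are equally traversable.  Self-pairs contribute to a
node's degree (once by default, configurable to twice) but are ignored by
every shortest-path quantity.  Diameter and radius of a disconnected
network are computed on its largest connected component and reported
together with the component count so the restriction is visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import networkx as nx

from .exceptions import MissingNodeError, UndefinedResultError, UsageError
from .io_core import Interactome, ProteinID
from .network_build import first_neighbors


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    degree: int
    betweenness: float
    closeness: float


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    n_self_pairs: int
    diameter: int
    radius: int
    component_count: int


def _as_graph(net) -> nx.Graph:
    """Accept an Interactome, ProteinDrugNetwork, or bare nx.Graph."""
    if isinstance(net, nx.Graph):
        return net
    return net.graph


def _without_self_loops(g: nx.Graph) -> nx.Graph:
    loops = list(nx.selfloop_edges(g))
    if not loops:
        return g
    h = g.copy()
    h.remove_edges_from(loops)
    return h


def degree(net, node: str, self_pair_counts: int = 1) -> int:
    """Incident edge count; a self-pair contributes ``self_pair_counts``
    (1 by default — "interacts with itself" counted once — or 2)."""
    g = _as_graph(net)
    if not g.has_node(node):
        raise MissingNodeError(f"node {node!r} not in network")
    d = g.degree(node)
    if g.has_edge(node, node):  # networkx counts a self-loop as 2
        d += self_pair_counts - 2
    return d


def betweenness(net, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness centrality, self-pairs ignored.

    Unnormalized values are pair counts (each unordered pair counted
    once); ``normalized=True`` applies the 2/((n-1)(n-2)) scaling.
    """
    g = _without_self_loops(_as_graph(net))
    return dict(nx.betweenness_centrality(g, normalized=normalized))


def closeness(net) -> dict[str, float]:
    """Closeness centrality with the component-size scaling for
    disconnected graphs: (r/sum of distances) * (r/(n-1)) where r is the
    number of nodes reachable from the node (itself excluded).  An
    isolated node scores 0.
    """
    g = _without_self_loops(_as_graph(net))
    return dict(nx.closeness_centrality(g, wf_improved=True))


def _largest_component(g: nx.Graph) -> set[str]:
    # deterministic tie-break: largest size, then lexicographically
    # smallest sorted node tuple
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    return set(comps[0])


def diameter_radius(net) -> tuple[int, int]:
    """Eccentricity extrema over the largest connected component."""
    g = _without_self_loops(_as_graph(net))
    if g.number_of_nodes() == 0:
        raise UsageError("diameter/radius undefined for an empty network")
    sub = g.subgraph(_largest_component(g))
    ecc = nx.eccentricity(sub)
    return max(ecc.values()), min(ecc.values())


def graph_summary(net) -> GraphSummary:
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise UsageError("summary undefined for an empty network")
    d, r = diameter_radius(net)
    return GraphSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_self_pairs=nx.number_of_selfloops(g),
        diameter=d,
        radius=r,
        component_count=nx.number_connected_components(_without_self_loops(g)),
    )


def node_metrics(net, normalized: bool = False,
                 self_pair_counts: int = 1) -> list[NodeMetrics]:
    """Degree, betweenness, and closeness for every node, sorted by id."""
    g = _as_graph(net)
    btw = betweenness(net, normalized=normalized)
    clo = closeness(net)
    return [
        NodeMetrics(
            node=n,
            degree=degree(net, n, self_pair_counts=self_pair_counts),
            betweenness=btw[n],
            closeness=clo[n],
        )
        for n in sorted(g.nodes)
    ]


def mean_neighbor_degree(
    interactome: Interactome, target: ProteinID, self_pair_counts: int = 1
) -> float:
    """Arithmetic mean of the full-interactome degrees of a target's first
    neighbors.  Degrees are measured in the whole interactome, not a
    subnetwork; a target with no neighbors raises rather than returning 0.
    """
    nbrs = first_neighbors(interactome, target).neighbors
    if not nbrs:
        raise UndefinedResultError(
            f"target {target!r} has no first neighbors; mean degree undefined"
        )
    return fmean(
        degree(interactome, n, self_pair_counts=self_pair_counts) for n in nbrs
    )
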