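"""Significant-pair graph: degrees, connected components, hub candidates.

Selected miRNA pairs form an undirected graph (one node per miRNA, one edge
per selected pair).  Nodes of high degree — miRNAs co-expressed and
co-shifted with many partners — are hub candidates.  Because "hub" has no
universally agreed degree cutoff, the report flags *all* nodes at or above a
configurable degree threshold and separately marks the maximum-degree node of
each multi-edge component as its center, rather than baking in an editorial
choice of which high-degree nodes to name.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .pairs import PairStat

__all__ = ["PairGraph", "HubReport", "build_graph", "hub_report", "write_edge_list"]


@dataclass(frozen=True)
class PairGraph:
    """Undirected graph of selected pairs with per-node degrees."""

    graph: nx.Graph

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))

    @property
    def degrees(self) -> dict[str, int]:
        return {n: int(d) for n, d in sorted(self.graph.degree)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class HubReport:
    """Connected components, degrees and hub candidates of a pair graph.

    ``hubs`` lists every node with degree >= the threshold; ``centers`` the
    maximum-degree node of each component with more than one edge
    (lexicographic tie-break, so the report is deterministic).
    """

    components: tuple[tuple[str, ...], ...]
    degrees: dict[str, int]
    hubs: tuple[str, ...]
    centers: tuple[str, ...]
    min_degree: int

    def summary(self) -> str:
        lines = [
            f"{len(self.degrees)} nodes, "
            f"{sum(self.degrees.values()) // 2} edges, "
            f"{len(self.components)} connected component(s)",
        ]
        for comp in self.components:
            degs = ", ".join(f"{n}({self.degrees[n]})" for n in comp)
            lines.append(f"  component: {degs}")
        lines.append(
            f"hub candidates (degree >= {self.min_degree}): "
            + (", ".join(self.hubs) if self.hubs else "none")
        )
        lines.append("component centers: " + (", ".join(self.centers) if self.centers else "none"))
        return "\n".join(lines)


def build_graph(selected: list[PairStat]) -> PairGraph:
    """One node per distinct miRNA, one edge per selected pair.

    Edge attributes carry the pair's combined z and p.  A pair whose two
    members are the same id is rejected (self-loops are meaningless here);
    duplicate pairs collapse onto one edge.
    """
    g = nx.Graph()
    for p in selected:
        if p.mirna1 == p.mirna2:
            raise ValueError(f"pair with identical members: {p.mirna1!r}")
        g.add_edge(p.mirna1, p.mirna2, z=p.z, p_z=p.p_z)
    return PairGraph(graph=g)


def hub_report(g: PairGraph, min_degree: int = 3) -> HubReport:
    """Enumerate components and flag hub candidates of the pair graph."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    degrees = g.degrees
    components = tuple(
        tuple(sorted(comp))
        for comp in sorted(nx.connected_components(g.graph), key=lambda c: sorted(c)[0])
    )
    hubs = tuple(n for n in sorted(degrees) if degrees[n] >= min_degree)
    # component center: highest degree, ties broken lexicographically
    centers = []
    for comp in components:
        if sum(degrees[n] for n in comp) // 2 > 1:  # more than one edge
            centers.append(sorted(comp, key=lambda n: (-degrees[n], n))[0])
    return HubReport(
        components=components,
        degrees=degrees,
        hubs=hubs,
        centers=tuple(centers),
        min_degree=min_degree,
    )


def write_edge_list(g: PairGraph, path) -> None:
    """Edge list TSV: node1, node2, z, p_z (sorted, deterministic)."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tz\tp_z\n")
        for a, b in g.edges:
            attrs = g.graph.edges[a, b]
            fh.write(f"{a}\t{b}\t{attrs.get('z', float('nan'))!r}\t{attrs.get('p_z', float('nan'))!r}\n")
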