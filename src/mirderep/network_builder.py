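"""Bipartite miRNA-gene regulatory networks from derepression hits.

A gene hit in several cell types collapses to a single node whose effect
attribute is the greatest change observed across those types (effects are
all positive after an up-filter, so the plain maximum is the greatest
change). Node ids are namespaced ("mirna:...", "gene:...") so a miRNA and
a gene can never collide in exported files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .deg_integration import DerepressionHit
from .mirna_orthology import MatureMiRNA

MIRNA_PREFIX = "mirna:"
GENE_PREFIX = "gene:"


@dataclass(frozen=True)
class GeneNode:
    symbol: str
    max_effect: float
    cell_types: tuple[str, ...]  # sorted


@dataclass
class RegulatoryNetwork:
    """Bipartite miRNA -> gene graph with per-node aggregated attributes."""

    mirna_nodes: dict[str, float | None] = field(default_factory=dict)  # id -> CSF logFC
    gene_nodes: dict[str, GeneNode] = field(default_factory=dict)
    edges: frozenset[tuple[str, str]] = frozenset()  # (miRNA id, gene symbol)
    effect_scale: str | None = None

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if m not in self.mirna_nodes or g not in self.gene_nodes:
                raise ValueError(f"edge ({m}, {g}) references a missing node")
        touched_m = {m for m, _ in self.edges}
        touched_g = {g for _, g in self.edges}
        if touched_m != set(self.mirna_nodes) or touched_g != set(self.gene_nodes):
            raise ValueError("network must not contain isolated nodes")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.mirna_nodes == other.mirna_nodes
            and self.gene_nodes == other.gene_nodes
            and self.edges == other.edges
            and self.effect_scale == other.effect_scale
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for mid, logfc in sorted(self.mirna_nodes.items()):
            attrs = {"node_class": "miRNA", "label": mid}
            if logfc is not None:
                attrs["csf_logfc_aging"] = float(logfc)
            g.add_node(MIRNA_PREFIX + mid, bipartite=0, **attrs)
        for sym, node in sorted(self.gene_nodes.items()):
            g.add_node(
                GENE_PREFIX + sym,
                bipartite=1,
                node_class="gene",
                label=sym,
                max_effect=float(node.max_effect),
                cell_types="|".join(node.cell_types),
            )
        for mid, sym in sorted(self.edges):
            g.add_edge(MIRNA_PREFIX + mid, GENE_PREFIX + sym, interaction="targets")
        if self.effect_scale is not None:
            g.graph["effect_scale"] = self.effect_scale
        return g


def build_network(
    hits: Sequence[DerepressionHit],
    mirnas: Iterable[MatureMiRNA] = (),
) -> RegulatoryNetwork:
    """Assemble the bipartite network for a set of derepression hits.

    One gene node per distinct gene with effect = max over its hits and the
    sorted list of cell types; one edge per distinct (miRNA, gene) pair.
    miRNA nodes carry the CSF aging log-fold-change when the miRNA is in
    ``mirnas``. Mixed effect scales across hits are an error.
    """
    scales = {h.effect_scale for h in hits}
    if len(scales) > 1:
        raise ValueError(f"hits mix effect scales: {sorted(scales)}")
    logfc_by_id = {m.id: m.csf_logfc_aging for m in mirnas}

    gene_nodes: dict[str, GeneNode] = {}
    edges: set[tuple[str, str]] = set()
    by_gene: dict[str, list[DerepressionHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene, []).append(h)
    for gene, ghits in by_gene.items():
        gene_nodes[gene] = GeneNode(
            symbol=gene,
            max_effect=max(h.effect for h in ghits),
            cell_types=tuple(sorted({h.cell_type for h in ghits})),
        )
        for h in ghits:
            for m in h.mirnas:
                edges.add((m, gene))
    mirna_nodes = {m: logfc_by_id.get(m) for m, _ in edges}
    return RegulatoryNetwork(
        mirna_nodes=mirna_nodes,
        gene_nodes=gene_nodes,
        edges=frozenset(edges),
        effect_scale=next(iter(scales)) if scales else None,
    )


@dataclass(frozen=True)
class NetworkSummary:
    n_mirnas: int
    n_genes: int
    n_edges: int
    out_degree: dict[str, int]  # per miRNA
    in_degree: dict[str, int]  # per gene


def network_summary(net: RegulatoryNetwork) -> NetworkSummary:
    out_deg = {m: 0 for m in net.mirna_nodes}
    in_deg = {g: 0 for g in net.gene_nodes}
    for m, g in net.edges:
        out_deg[m] += 1
        in_deg[g] += 1
    return NetworkSummary(
        n_mirnas=len(net.mirna_nodes),
        n_genes=len(net.gene_nodes),
        n_edges=len(net.edges),
        out_degree=out_deg,
        in_degree=in_deg,
    )
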