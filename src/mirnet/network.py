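"""Bipartite miRNA–gene regulatory network construction and export.

miRNA nodes are the enrichment hits (adjusted p at or below the network
threshold, 0.05 by default); each is connected to the downregulated pathway
genes inside its target set. Gene nodes carry log2 fold change and adjusted
p from the DE table. Consensus targets across several prediction sources
(set intersection plus a Venn-count table) live here too.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRecord
from .io import DifferentialExpressionTable, GeneSet, TargetMap

log = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "build_network",
    "consensus_targets",
    "export_network",
    "import_network",
]


@dataclass
class RegulatoryNetwork:
    """Bipartite graph: miRNA nodes (attribute ``p_adjusted``) connected to
    downregulated gene nodes (attributes ``log2_fc``, ``p_adj``)."""

    graph: nx.Graph

    @property
    def mirna_nodes(self) -> dict[str, dict]:
        return {
            n: d for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"
        }

    @property
    def gene_nodes(self) -> dict[str, dict]:
        return {
            n: d for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"
        }

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self.graph.edges():
            if self.graph.nodes[u].get("kind") == "mirna":
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def is_bipartite(self) -> bool:
        return all(
            {self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]}
            == {"mirna", "gene"}
            for u, v in self.graph.edges()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and self.edges == other.edges
        )


def build_network(
    records: list[EnrichmentRecord],
    de: DifferentialExpressionTable,
    alpha_network: float = 0.05,
    full_targets: TargetMap | None = None,
) -> RegulatoryNetwork:
    """Keep records with ``p_adjusted <= alpha_network`` (inclusive) and
    connect each retained miRNA to its overlap genes.

    With ``full_targets`` given, edges extend to every target of a retained
    miRNA that is in the DE universe, not only the downregulated overlap.
    An empty network is allowed and merely logged.
    """
    if not (0.0 < alpha_network <= 1.0):
        raise ValueError(f"alpha_network must be in (0, 1], got {alpha_network}")
    g = nx.Graph()
    for rec in records:
        if rec.p_adjusted > alpha_network:
            continue
        if full_targets is not None and rec.mirna_id in full_targets:
            genes = full_targets[rec.mirna_id] & de.universe
        else:
            genes = rec.overlap_genes
        if not genes:
            continue  # invariant: no isolated miRNA nodes
        g.add_node(rec.mirna_id, kind="mirna", p_adjusted=rec.p_adjusted)
        for gene in genes:
            if gene not in g:
                g.add_node(
                    gene, kind="gene", log2_fc=de.log2_fc(gene), p_adj=de.p_adj(gene)
                )
            g.add_edge(rec.mirna_id, gene)
    if g.number_of_nodes() == 0:
        log.info("no miRNA passed alpha_network=%s; network is empty", alpha_network)
    return RegulatoryNetwork(g)


def consensus_targets(
    maps: list[TargetMap], mirna_id: str
) -> tuple[GeneSet, pd.DataFrame]:
    """Intersect one miRNA's predicted target sets across >=2 sources.

    Returns the consensus gene set and a Venn table of per-source sizes and
    pairwise intersection counts.
    """
    if len(maps) < 2:
        raise ValueError("consensus requires at least two target maps")
    for tmap in maps:
        if mirna_id not in tmap:
            raise KeyError(f"miRNA {mirna_id!r} absent from target map {tmap.name!r}")
    sets = {tmap.name: tmap[mirna_id] for tmap in maps}
    consensus = frozenset.intersection(*sets.values())
    rows = [
        {"source_a": name, "source_b": name, "n_genes": len(s)}
        for name, s in sets.items()
    ]
    for (na, sa), (nb, sb) in itertools.combinations(sets.items(), 2):
        rows.append({"source_a": na, "source_b": nb, "n_genes": len(sa & sb)})
    rows.append(
        {"source_a": "ALL", "source_b": "ALL", "n_genes": len(consensus)}
    )
    venn = pd.DataFrame(rows, columns=["source_a", "source_b", "n_genes"])
    return GeneSet(f"{mirna_id}_consensus", consensus), venn


def export_network(net: RegulatoryNetwork, path, format: str = "graphml") -> None:
    """Write the network as GraphML (attribute-preserving) or as an edge TSV
    plus per-kind node-attribute TSVs (``<path>.mirna_nodes.tsv`` and
    ``<path>.gene_nodes.tsv``)."""
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_tsv":
        path = str(path)
        edges = pd.DataFrame(sorted(net.edges), columns=["mirna_id", "gene_id"])
        edges.to_csv(path, sep="\t", index=False)
        mir = pd.DataFrame(
            [
                {"mirna_id": n, "p_adjusted": d["p_adjusted"]}
                for n, d in sorted(net.mirna_nodes.items())
            ],
            columns=["mirna_id", "p_adjusted"],
        )
        mir.to_csv(path + ".mirna_nodes.tsv", sep="\t", index=False, float_format="%.17g")
        gene = pd.DataFrame(
            [
                {"gene_id": n, "log2_fc": d["log2_fc"], "p_adj": d["p_adj"]}
                for n, d in sorted(net.gene_nodes.items())
            ],
            columns=["gene_id", "log2_fc", "p_adj"],
        )
        gene.to_csv(path + ".gene_nodes.tsv", sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown export format {format!r}; use 'graphml' or 'edge_tsv'")


def import_network(path) -> RegulatoryNetwork:
    """Read back a GraphML export."""
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    return RegulatoryNetwork(nx.Graph(g))
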