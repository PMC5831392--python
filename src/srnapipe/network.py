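"""miRNA-gene regulatory network construction and hub detection.

The network mixes two edge types: directed-in-meaning regulatory edges
from miRNAs to their predicted target genes, and undirected gene-gene
interaction edges carrying a combined confidence score in [0, 1].
Interaction edges below the score cutoff (default 0.4) are discarded;
only genes retaining at least one interaction edge ("candidate target
genes with interactions") enter the network, together with the miRNAs
predicted to regulate them.

Hub genes are the ceil(fraction * n_genes) gene nodes of highest total
degree (default top 5%, ties broken lexicographically by node id); hub
miRNAs are every miRNA with a regulatory edge to at least one hub gene.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd


def build_network(
    target_sets: Mapping[str, Iterable[str]],
    ppi: pd.DataFrame,
    score_cutoff: float = 0.4,
) -> nx.Graph:
    """Build the combined regulatory network.

    Parameters
    ----------
    target_sets:
        miRNA id -> predicted candidate target genes.
    ppi:
        Interaction table with columns ``gene_a``, ``gene_b``,
        ``combined_score``; only edges between candidate target genes
        with score >= cutoff are kept, and parallel edges collapse.

    Nodes carry ``kind`` ("mirna" | "gene"); edges carry ``etype``
    ("regulatory" | "interaction") and interaction edges a ``score``.
    """
    for col in ("gene_a", "gene_b", "combined_score"):
        if col not in ppi.columns:
            raise ValueError(f"interaction table missing column {col!r}")
    candidates: set[str] = set()
    for genes in target_sets.values():
        candidates |= set(genes)

    G = nx.Graph()
    for _, row in ppi.iterrows():
        a, b, score = str(row["gene_a"]), str(row["gene_b"]), float(row["combined_score"])
        if a == b or score < score_cutoff:
            continue
        if a not in candidates or b not in candidates:
            continue
        if G.has_edge(a, b):
            G[a][b]["score"] = max(G[a][b]["score"], score)
            continue
        G.add_node(a, kind="gene")
        G.add_node(b, kind="gene")
        G.add_edge(a, b, etype="interaction", score=score)

    kept_genes = {n for n, d in G.nodes(data=True) if d["kind"] == "gene"}
    for mirna, genes in target_sets.items():
        regulated = set(genes) & kept_genes
        if not regulated:
            continue
        G.add_node(str(mirna), kind="mirna")
        for gene in regulated:
            if not G.has_edge(mirna, gene):
                G.add_edge(str(mirna), gene, etype="regulatory")
    return G


def gene_nodes(G: nx.Graph) -> list[str]:
    return sorted(n for n, d in G.nodes(data=True) if d["kind"] == "gene")


def mirna_nodes(G: nx.Graph) -> list[str]:
    return sorted(n for n, d in G.nodes(data=True) if d["kind"] == "mirna")


def find_hubs(
    G: nx.Graph, fraction: float = 0.05, degree_mode: str = "all"
) -> tuple[list[str], list[str]]:
    """Identify hub genes and hub miRNAs.

    ``degree_mode="all"`` (default) counts both edge types in a gene's
    degree; ``"interaction"`` counts only gene-gene interaction edges.
    Returns ``(hub_genes, hub_mirnas)``, each sorted.
    """
    if degree_mode not in ("all", "interaction"):
        raise ValueError(f"unknown degree_mode {degree_mode!r}")
    genes = gene_nodes(G)
    if not genes:
        raise ValueError("network has no gene nodes")
    if degree_mode == "all":
        degree = {g: G.degree(g) for g in genes}
    else:
        degree = {
            g: sum(1 for _n, d in G[g].items() if d["etype"] == "interaction")
            for g in genes
        }
    n_hubs = math.ceil(fraction * len(genes))
    ranked = sorted(genes, key=lambda g: (-degree[g], g))
    hubs = sorted(ranked[:n_hubs])
    hub_set = set(hubs)
    hub_mirnas = sorted(
        m
        for m in mirna_nodes(G)
        if any(
            nbr in hub_set and G[m][nbr]["etype"] == "regulatory" for nbr in G[m]
        )
    )
    return hubs, hub_mirnas


def export_network(G: nx.Graph, prefix: str | Path) -> dict[str, Path]:
    """Write edge-list, node-attribute and GraphML files.

    Returns the written paths.  ``import_network`` on the edge/node pair
    reproduces the graph exactly.
    """
    prefix = Path(prefix)
    edges_path = prefix.with_suffix(".edges.tsv")
    nodes_path = prefix.with_suffix(".nodes.tsv")
    graphml_path = prefix.with_suffix(".graphml")

    edge_rows = [
        {
            "source": u,
            "target": v,
            "etype": d["etype"],
            "score": d.get("score", ""),
        }
        for u, v, d in sorted(G.edges(data=True))
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "etype", "score"]).to_csv(
        edges_path, sep="\t", index=False
    )
    node_rows = [
        {"node": n, "kind": d["kind"], "degree": G.degree(n)}
        for n, d in sorted(G.nodes(data=True))
    ]
    pd.DataFrame(node_rows, columns=["node", "kind", "degree"]).to_csv(
        nodes_path, sep="\t", index=False
    )
    nx.write_graphml(G, graphml_path)
    return {"edges": edges_path, "nodes": nodes_path, "graphml": graphml_path}


def import_network(prefix: str | Path) -> nx.Graph:
    """Rebuild a network from the edge-list/node-attribute pair."""
    prefix = Path(prefix)
    nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
    G = nx.Graph()
    for _, row in nodes.iterrows():
        G.add_node(str(row["node"]), kind=str(row["kind"]))
    for _, row in edges.iterrows():
        attrs = {"etype": str(row["etype"])}
        if row["etype"] == "interaction":
            attrs["score"] = float(row["score"])
        G.add_edge(str(row["source"]), str(row["target"]), **attrs)
    return G
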