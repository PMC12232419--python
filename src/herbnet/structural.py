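"""Hub and bottleneck identification on target-phenotype subnetworks.

The subnetwork is the subgraph of the interactome induced on the union of
a target gene set and a phenotype gene set, with each node annotated by
its role (``target``, ``phenotype`` or ``both``). A *hub* is a node with
high degree centrality; a *bottleneck* is a node with high betweenness
centrality (exact shortest-path counting, normalized, endpoints excluded).
Centralities are computed on the induced subnetwork, not the full
interactome; computing them on the full graph would make every report
identical regardless of the target set under study.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .interactome import Interactome

logger = logging.getLogger(__name__)


def build_subnetwork(
    g: Interactome, targets: Iterable[str], phenotype_genes: Iterable[str]
) -> nx.Graph:
    """Induced subgraph on ``targets | phenotype_genes`` with role annotations."""
    targets = set(targets) & g.nodes
    phenotype_genes = set(phenotype_genes) & g.nodes
    if not targets and not phenotype_genes:
        raise ValueError("both gene sets are empty after restriction to interactome nodes")
    nodes = targets | phenotype_genes
    sub = g.graph.subgraph(nodes).copy()
    for node in sub.nodes:
        if node in targets and node in phenotype_genes:
            role = "both"
        elif node in targets:
            role = "target"
        else:
            role = "phenotype"
        sub.nodes[node]["role"] = role
    if sub.number_of_edges() == 0:
        logger.warning("induced subnetwork has no edges; centralities will all be zero")
    return sub


@dataclass
class StructuralReport:
    """Ranked centralities and the top-k hub/bottleneck lists."""

    n_nodes: int
    n_edges: int
    roles: dict[str, str]
    degree_rank: list[tuple[str, int]]
    betweenness_rank: list[tuple[str, float]]
    hubs: list[str]
    bottlenecks: list[str]
    k: int

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "roles": self.roles,
            "degree_rank": [[n, d] for n, d in self.degree_rank],
            "betweenness_rank": [[n, round(b, 10)] for n, b in self.betweenness_rank],
            "hubs": self.hubs,
            "bottlenecks": self.bottlenecks,
            "k": self.k,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def rank_hubs_bottlenecks(sub: nx.Graph, k: int = 3) -> StructuralReport:
    """Rank subnetwork nodes by degree and by exact betweenness centrality.

    Ties are broken lexicographically by gene id so ranks are strictly
    ordered and deterministic. ``k`` larger than the node count truncates
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = sub.number_of_nodes()
    if k > n:
        logger.warning("k=%d exceeds node count %d; truncating", k, n)
        k = n
    degree_rank = sorted(((node, int(d)) for node, d in sub.degree), key=lambda x: (-x[1], x[0]))
    bc = nx.betweenness_centrality(sub, normalized=True, endpoints=False)
    betweenness_rank = sorted(((node, float(b)) for node, b in bc.items()), key=lambda x: (-x[1], x[0]))
    return StructuralReport(
        n_nodes=n,
        n_edges=sub.number_of_edges(),
        roles={node: sub.nodes[node].get("role", "?") for node in sorted(sub.nodes)},
        degree_rank=degree_rank,
        betweenness_rank=betweenness_rank,
        hubs=[node for node, _ in degree_rank[:k]],
        bottlenecks=[node for node, _ in betweenness_rank[:k]],
        k=k,
    )


def write_subnetwork_edges(sub: nx.Graph, path: str | Path) -> None:
    """Export the subnetwork edge list as TSV for external viewers."""
    rows = sorted(tuple(sorted(e)) for e in sub.edges)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")
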