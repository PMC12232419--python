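"""Interactome container and the distance machinery behind proximity scores.

The interactome is an undirected, simple gene graph restricted to its
largest connected component. Two primitives live here:

* :func:`closest_distance` — the closest-distance gene-set metric
  ``d(P, S) = (1/|S|) * sum_{s in S} min_{p in P} d(p, s)`` over unweighted
  shortest paths, where ``P`` is typically a phenotype gene module and
  ``S`` a target set.
* :func:`degree_matched_sample` — degree-preserving random node sets for
  the permutation null, using logarithmic degree binning with a minimum
  bin occupancy (small bins are merged into their neighbours), the
  established practice for this null model; exact-degree matching is
  infeasible in the heavy tail.

For graphs up to ``DENSE_CACHE_MAX_NODES`` nodes an all-pairs BFS distance
matrix (scipy ``csgraph``) is cached on the container so that the thousands
of distance evaluations a permutation null needs are vectorised; larger
graphs fall back to per-call multi-source BFS.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._rng import rng_from

logger = logging.getLogger(__name__)

DENSE_CACHE_MAX_NODES = 5000


@dataclass
class Interactome:
    """Undirected simple gene graph, single connected component."""

    graph: nx.Graph
    component_filtered: bool = False
    _order: list[str] = field(default_factory=list, repr=False)
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _dist: np.ndarray | None = field(default=None, repr=False)
    _degree_arr: np.ndarray | None = field(default=None, repr=False)
    _bins_cache: dict[int, "DegreeBins"] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._order = sorted(self.graph.nodes)
        self._index = {n: i for i, n in enumerate(self._order)}

    @property
    def nodes(self) -> set[str]:
        return set(self._order)

    @property
    def n_nodes(self) -> int:
        return len(self._order)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def distance_matrix(self) -> np.ndarray | None:
        """Dense all-pairs shortest-path matrix (int16), or None if too large."""
        if self.n_nodes > DENSE_CACHE_MAX_NODES:
            return None
        if self._dist is None:
            rows, cols = [], []
            for u, v in self.graph.edges:
                iu, iv = self._index[u], self._index[v]
                rows.extend((iu, iv))
                cols.extend((iv, iu))
            adj = csr_matrix(
                (np.ones(len(rows), dtype=np.int8), (rows, cols)),
                shape=(self.n_nodes, self.n_nodes),
            )
            self._dist = shortest_path(adj, method="D", unweighted=True).astype(np.int16)
        return self._dist

    def indices(self, nodes: Iterable[str]) -> np.ndarray:
        return np.fromiter((self._index[n] for n in sorted(nodes)), dtype=np.int64)

    def degree_bins(self, min_bin_size: int = 10) -> "DegreeBins":
        if min_bin_size not in self._bins_cache:
            self._bins_cache[min_bin_size] = DegreeBins.from_graph(self, min_bin_size)
        return self._bins_cache[min_bin_size]


def prepare_graph(edges: Iterable[tuple[str, str]] | str | Path) -> Interactome:
    """Build an :class:`Interactome` from an edge list.

    Accepts either an iterable of node pairs or a path to a TSV edge list
    (two columns, optional ``gene_a``/``gene_b`` header, ``#`` comments).
    Self-loops and duplicate edges are removed and the graph is restricted
    to its largest connected component; removal counts are logged.
    """
    if isinstance(edges, (str, Path)):
        edges = list(_read_edge_list(Path(edges)))
    else:
        edges = list(edges)
    if not edges:
        raise ValueError("empty edge list")
    g = nx.Graph()
    n_self = 0
    for u, v in edges:
        if u == v:
            n_self += 1
            continue
        g.add_edge(str(u), str(v))
    if g.number_of_nodes() == 0:
        raise ValueError("edge list contains only self-loops")
    n_dup = len(edges) - n_self - g.number_of_edges()
    component_filtered = False
    if not nx.is_connected(g):
        components = sorted(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        largest = components[-1]
        dropped = g.number_of_nodes() - len(largest)
        g = g.subgraph(largest).copy()
        component_filtered = True
        logger.warning("graph not connected: kept largest component, dropped %d nodes", dropped)
    logger.info(
        "prepared interactome: %d nodes, %d edges (%d self-loops, %d duplicates removed)",
        g.number_of_nodes(), g.number_of_edges(), n_self, n_dup,
    )
    return Interactome(graph=g, component_filtered=component_filtered)


def _read_edge_list(path: Path):
    header_tokens = {"gene_a", "gene_b", "source", "target", "node_a", "node_b"}
    with open(path, encoding="utf-8") as fh:
        first = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            if first and parts[0].lower() in header_tokens:
                first = False
                continue
            first = False
            yield parts[0], parts[1]


def write_edge_list(g: Interactome, path: str | Path) -> None:
    """Write a sorted, byte-stable two-column edge list with header."""
    rows = sorted(tuple(sorted(e)) for e in g.graph.edges)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


def _filter_to_nodes(g: Interactome, genes: Iterable[str], name: str) -> list[str]:
    genes = set(genes)
    kept = sorted(genes & g.nodes)
    dropped = len(genes) - len(kept)
    if dropped:
        logger.debug("%s: dropped %d genes absent from the interactome", name, dropped)
    if not kept:
        raise ValueError(f"gene set {name!r} is empty after restriction to interactome nodes")
    return kept


def _multi_source_bfs(g: Interactome, sources: Sequence[str]) -> dict[str, int]:
    """Distances from the nearest source to every reachable node."""
    adj = g.graph.adj
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return dist


def closest_distance(g: Interactome, P: Iterable[str], S: Iterable[str]) -> float:
    """Closest-distance metric from target set ``S`` to gene module ``P``.

    Averages, over each ``s`` in ``S``, the unweighted shortest-path length
    to the nearest member of ``P``. Genes outside the graph are dropped
    first; an empty set after filtering raises, naming the offending set.
    Asymmetric in (P, S) by construction.
    """
    P_kept = _filter_to_nodes(g, P, "P")
    S_kept = _filter_to_nodes(g, S, "S")
    dmat = g.distance_matrix()
    if dmat is not None:
        pi = g.indices(P_kept)
        si = g.indices(S_kept)
        return float(dmat[np.ix_(pi, si)].min(axis=0).mean())
    dist = _multi_source_bfs(g, P_kept)
    return float(np.mean([dist[s] for s in S_kept]))


def _closest_distance_idx(dmat: np.ndarray, pi: np.ndarray, si: np.ndarray) -> float:
    # hot path used by the permutation null; callers guarantee validity
    return float(dmat[np.ix_(pi, si)].min(axis=0).mean())


@dataclass
class DegreeBins:
    """Adaptive degree bins with a minimum occupancy, for null sampling.

    Nodes are grouped by exact degree; consecutive degree groups are then
    accumulated (lowest first) until each bin holds at least
    ``min_bin_size`` nodes, an undersized tail bin merging downward. Where
    a degree is abundant the bin is effectively exact-degree; in the sparse
    heavy tail bins span geometrically growing degree ranges, giving the
    logarithmic-style binning this null model conventionally uses.
    ``node_bin`` maps each node to the index of its bin in ``bins`` (each a
    sorted node list).
    """

    bins: list[list[str]]
    node_bin: dict[str, int]
    bin_indices: list[np.ndarray] | None = None  # same bins as integer node ids

    @classmethod
    def from_graph(cls, g: Interactome, min_bin_size: int = 10) -> "DegreeBins":
        if g.n_nodes < max(2, min_bin_size):
            raise ValueError(
                f"graph too small for degree binning: {g.n_nodes} nodes < min_bin_size {min_bin_size}"
            )
        by_degree: dict[int, list[str]] = {}
        for node in g.nodes:
            by_degree.setdefault(g.degree(node), []).append(node)
        merged: list[list[str]] = []
        pending: list[str] = []
        for degree in sorted(by_degree):
            pending.extend(by_degree[degree])
            if len(pending) >= min_bin_size:
                merged.append(sorted(pending))
                pending = []
        if pending:  # tail bin too small: merge downward
            if merged:
                merged[-1] = sorted(merged[-1] + pending)
            else:
                merged.append(sorted(pending))
        node_bin = {n: i for i, b in enumerate(merged) for n in b}
        bin_indices = [g.indices(b) for b in merged]
        return cls(bins=merged, node_bin=node_bin, bin_indices=bin_indices)


def degree_matched_sample(
    g: Interactome,
    template: Iterable[str],
    rng: int | np.random.Generator,
    *,
    min_bin_size: int = 10,
) -> frozenset[str]:
    """Random node set degree-matched to ``template``.

    Each template node is replaced by a uniform draw from its degree bin,
    without replacement within the sample. If a bin is exhausted mid-sample
    the candidate pool widens to adjacent bins (nearest first). The sample
    has exactly the template's size. Deterministic given the rng state.
    """
    rng = rng_from(rng)
    template = sorted(set(template))
    missing = [t for t in template if t not in g._index]
    if missing:
        raise KeyError(f"template nodes absent from interactome: {missing[:5]}")
    binning = g.degree_bins(min_bin_size)
    chosen: list[str] = []
    chosen_set: set[str] = set()
    for t in template:
        b = binning.node_bin[t]
        pool = [n for n in binning.bins[b] if n not in chosen_set]
        radius = 1
        while not pool:
            lo, hi = b - radius, b + radius
            widened: list[str] = []
            if lo >= 0:
                widened.extend(binning.bins[lo])
            if hi < len(binning.bins):
                widened.extend(binning.bins[hi])
            pool = [n for n in sorted(widened) if n not in chosen_set]
            radius += 1
            if radius > len(binning.bins):
                raise RuntimeError("degree-matched sampling exhausted every bin")
        pick = pool[int(rng.integers(len(pool)))]
        chosen.append(pick)
        chosen_set.add(pick)
    return frozenset(chosen)
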