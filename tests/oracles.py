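"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles — containment
scans, breadth-first search, exhaustive enumeration — sharing no code path
with the package implementation under test.
"""

from collections import deque
from itertools import combinations
import math


def brute_force_rules(transactions, min_support, universe, max_size=4):
    """All rules antecedent -> phenotype by exhaustive subset enumeration.

    Returns tuples (antecedent frozenset, phenotype, support, confidence,
    lift, antecedent_count, joint_count, consequent_count) sorted by the
    canonical rule order (confidence desc, lift desc, antecedent, consequent).
    """
    n = len(transactions)
    min_count = max(1, math.ceil(min_support * n - 1e-9))
    items = sorted({i for t, _ in transactions for i in t})
    rules = []
    for ph in sorted(universe):
        consequent_count = sum(1 for _, labels in transactions if ph in labels)
        if consequent_count == 0:
            continue
        for size in range(1, max_size + 1):
            for antecedent in combinations(items, size):
                aset = set(antecedent)
                antecedent_count = sum(1 for t, _ in transactions if aset <= t)
                joint = sum(
                    1 for t, labels in transactions if aset <= t and ph in labels
                )
                if joint >= min_count:
                    conf = joint / antecedent_count
                    rules.append(
                        (
                            frozenset(antecedent), ph, joint / n, conf,
                            conf / (consequent_count / n),
                            antecedent_count, joint, consequent_count,
                        )
                    )
    rules.sort(key=lambda r: (-r[3], -r[4], tuple(sorted(r[0])), r[1]))
    return rules


def bfs_distances(adjacency, source):
    """Single-source unweighted shortest paths by plain BFS."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def adjacency_from_edges(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def closest_distance_oracle(edges, P, S):
    """d(P, S) recomputed with per-node BFS: mean over S of min over P."""
    adj = adjacency_from_edges(edges)
    total = 0.0
    for s in S:
        dist = bfs_distances(adj, s)
        total += min(dist[p] for p in P)
    return total / len(S)


def count_shortest_paths(adjacency, s):
    """(distances, path counts) from s, by BFS with path accumulation."""
    dist = {s: 0}
    sigma = {s: 1}
    queue = deque([s])
    order = []
    while queue:
        u = queue.popleft()
        order.append(u)
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness_oracle(edges, nodes):
    """Exact normalized betweenness (endpoints excluded) by enumerating, for
    every pair, all shortest paths via backtracking over BFS distance layers."""
    adj = adjacency_from_edges(edges)
    for n in nodes:
        adj.setdefault(n, set())
    nodes = sorted(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist, _ = count_shortest_paths(adj, s)
        if t not in dist:
            continue
        # enumerate all shortest s-t paths by recursive backtracking
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for v in adj[u]:
                if v in dist and dist[v] == dist[u] + 1 and dist[t] >= dist[v]:
                    path.append(v)
                    extend(path)
                    path.pop()

        extend([s])
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1 / len(paths)
    n = len(nodes)
    scale = 2 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return {v: bc[v] * scale for v in nodes}


def enumerate_degree_matched_pairs(bins, node_bin, template):
    """All equally likely degree-matched samples for a 1- or 2-node template.

    Mirrors without-replacement sampling over disjoint log-degree bins:
    same bin -> all 2-subsets of the bin; different bins -> the product.
    """
    template = sorted(template)
    if len(template) == 1:
        return [frozenset({n}) for n in bins[node_bin[template[0]]]]
    if len(template) != 2:
        raise ValueError("oracle supports templates of size 1 or 2")
    b1, b2 = node_bin[template[0]], node_bin[template[1]]
    if b1 == b2:
        return [frozenset(p) for p in combinations(bins[b1], 2)]
    return [
        frozenset({a, b}) for a in bins[b1] for b in bins[b2] if a != b
    ]
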