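"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from sympy.utilities.iterables import multiset_partitions


def union_find_components(nodes, edges):
    """Connected components via a hand-rolled union-find."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def modularity_oracle(graph: nx.Graph, cluster_sets, weighted=True) -> float:
    """Modularity via networkx's own implementation."""
    weight = "weight" if weighted else None
    return nx.community.modularity(graph, cluster_sets, weight=weight)


def exhaustive_max_modularity(graph: nx.Graph, weighted=True) -> float:
    """Exact maximum modularity by enumerating all node-set partitions."""
    nodes = list(graph.nodes)
    best = -math.inf
    for part in multiset_partitions(nodes):
        q = modularity_oracle(graph, [set(p) for p in part], weighted=weighted)
        best = max(best, q)
    return best


def assortativity_oracle(graph: nx.Graph, target: set) -> float:
    """Newman's two-category r via explicit e-matrix enumeration."""
    e = np.zeros((2, 2))
    for u, v in graph.edges:
        cu, cv = int(u in target), int(v in target)
        e[cu, cv] += 1.0
        e[cv, cu] += 1.0
    e /= e.sum()
    a = e.sum(axis=1)
    denom = 1.0 - np.sum(a ** 2)
    if denom == 0.0:
        return math.nan
    return float((np.trace(e) - np.sum(a ** 2)) / denom)


def bfs_distance_oracle(graph: nx.Graph, sources: set) -> dict:
    """Per-node shortest edge count to the nearest source, via per-source BFS."""
    out = {}
    for node in graph.nodes:
        if node in sources:
            continue
        best = math.inf
        for s in sources:
            try:
                d = nx.shortest_path_length(graph, node, s)
            except nx.NetworkXNoPath:
                continue
            best = min(best, d)
        out[node] = best
    return out


def hamming_identity(a: str, b: str) -> float:
    """Closed-form %identity for equal-length, indel-free sequences."""
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
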