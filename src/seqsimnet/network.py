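"""Thresholded similarity networks and their partitions.

A :class:`SimilarityNetwork` holds an undirected graph whose nodes are
dereplicated sequences and whose edges carry the percent identity of the
surviving pairwise hit; an edge exists only when that identity reaches the
network's threshold, and nodes left without any edge (singletons) are
excluded. Two partitions are derived: connected components (CC), the
coarse clustering, and level-1 Louvain communities (LC), the fine one.
Louvain level 1 is the partition after the first local-move phase of
modularity optimisation converges, before any graph aggregation. All
cluster identifiers are deterministic: the lexicographically smallest
member id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .records import SequenceRecord
from .similarity import AlignmentHit

LABEL_KEYS = ("molecule", "epoch", "site", "habitat", "truth_species")


@dataclass
class SimilarityNetwork:
    """An identity-thresholded, weighted, label-carrying graph."""

    threshold: float
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes: Iterable[str]) -> nx.Graph:
        return self.graph.subgraph(nodes)


@dataclass
class Partition:
    """Assignment of every network node to exactly one cluster."""

    kind: str  # "CC" or "LC"
    threshold: float
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if self.kind not in ("CC", "LC"):
            raise ValueError(f"unknown partition kind {self.kind!r}")

    def clusters(self) -> dict[str, frozenset]:
        out: dict[str, set] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return {cid: frozenset(nodes) for cid, nodes in out.items()}

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def refines(self, other: "Partition") -> bool:
        """True if every cluster of ``self`` lies within one cluster of ``other``."""
        seen: dict[str, str] = {}
        for node, cid in self.assignment.items():
            parent = other.assignment.get(node)
            if parent is None:
                return False
            if cid in seen and seen[cid] != parent:
                return False
            seen[cid] = parent
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.assignment), "cluster": list(self.assignment.values()),
             "kind": self.kind, "threshold": self.threshold}
        ).sort_values(["cluster", "id"], ignore_index=True)


def _clusters_to_partition(sets: Iterable[Iterable[str]], kind: str,
                           threshold: float) -> Partition:
    assignment: dict[str, str] = {}
    for members in sets:
        members = sorted(members)
        cid = members[0]
        for node in members:
            assignment[node] = cid
    return Partition(kind=kind, threshold=threshold, assignment=assignment)


def build_network(hits: Sequence[AlignmentHit],
                  records: Optional[Sequence[SequenceRecord]] = None,
                  threshold: float = 97.0) -> SimilarityNetwork:
    """Build the similarity network at an identity threshold.

    ``hits`` should already be filtered (one per pair, EGN thresholds).
    An edge is present iff ``pct_identity >= threshold``; isolated nodes
    are dropped; labels are copied from ``records`` when given.
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError(f"threshold must lie in (0, 100], got {threshold}")
    g = nx.Graph()
    for h in hits:
        if h.pct_identity >= threshold and h.query_id != h.subject_id:
            g.add_edge(h.query_id, h.subject_id, weight=float(h.pct_identity))
    if records is not None:
        by_id = {r.id: r for r in records}
        for node in g.nodes:
            rec = by_id.get(node)
            if rec is None:
                continue
            for key in LABEL_KEYS:
                value = getattr(rec, key)
                if value is not None:
                    g.nodes[node][key] = value
    return SimilarityNetwork(threshold=threshold, graph=g)


def connected_components(net: SimilarityNetwork) -> Partition:
    """Connected components: the coarse clustering of the network."""
    return _clusters_to_partition(nx.connected_components(net.graph),
                                  "CC", net.threshold)


def _louvain_one_level(graph: nx.Graph, weighted: bool,
                       rng: np.random.Generator,
                       init: Optional[dict] = None) -> list[set]:
    """One Louvain local-move phase, run to convergence, no aggregation.

    Starting from ``init`` (node -> community index; singletons when not
    given), every node is repeatedly offered its best neighbouring
    community; a move is accepted only for a strictly positive modularity
    gain, so the objective increases monotonically and the sweep loop
    terminates. Ties keep the node where it is.
    """
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    nbrs: list[list[tuple[int, float]]] = [[] for _ in nodes]
    strength = np.zeros(len(nodes))
    w_total = 0.0
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        iu, iv = index[u], index[v]
        nbrs[iu].append((iv, w))
        nbrs[iv].append((iu, w))
        strength[iu] += w
        strength[iv] += w
        w_total += w
    n = len(nodes)
    if init is None:
        comm = np.arange(n)
    else:
        comm = np.array([init[node] for node in nodes], dtype=int)
    # one spare slot per node so a node can always escape to a fresh
    # singleton community when staying put has negative gain
    sigma_tot = np.zeros(2 * n)
    for i in range(n):
        sigma_tot[comm[i]] += strength[i]
    spare = [c for c in range(2 * n - 1, -1, -1) if not np.any(comm == c)]
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            c0 = comm[i]
            k_i = strength[i]
            links: dict[int, float] = {}
            for j, w in nbrs[i]:
                links[comm[j]] = links.get(comm[j], 0.0) + w
            sigma_tot[c0] -= k_i
            # gain of joining community c, relative to being a singleton
            def gain(c: int) -> float:
                return (links.get(c, 0.0) / w_total
                        - sigma_tot[c] * k_i / (2.0 * w_total * w_total))
            best_c, best_gain = c0, gain(c0)
            if best_gain < -1e-12:  # escaping to a fresh singleton wins
                best_c, best_gain = spare[-1], 0.0
            for c in links:
                g = gain(c)
                if g > best_gain + 1e-12:
                    best_c, best_gain = c, g
            sigma_tot[best_c] += k_i
            if best_c != c0:
                if spare and best_c == spare[-1]:
                    spare.pop()
                comm[i] = best_c
                if not np.any(comm == c0):  # c0 emptied: recycle its id
                    spare.append(c0)
                improved = True
    groups: dict[int, set] = {}
    for i, n in enumerate(nodes):
        groups.setdefault(int(comm[i]), set()).add(n)
    return list(groups.values())


def louvain_level1(net: SimilarityNetwork, seed: int = 0,
                   weighted: bool = True, n_restarts: int = 12) -> Partition:
    """Level-1 Louvain communities of the network.

    One local-move phase of weighted modularity optimisation (edge weight =
    percent identity), run to convergence without aggregation — the most
    fine-grained Louvain resolution. The local-move phase is a greedy
    ascent whose fixed point depends on the initial partition and the node
    visiting order, so this is a seeded multi-start: one restart from whole
    connected components (the coarse baseline), a third from singletons
    (the classical start) and the rest from random groupings, keeping the
    highest-modularity result. The outcome is deterministic given ``seed``
    and never has lower modularity than the all-singletons partition.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot partition an empty network")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2 ** 31)
    nodes = sorted(net.graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    cc_init = {}
    for comp in nx.connected_components(net.graph):
        for node in comp:
            cc_init[node] = index[min(comp, key=str)]
    n_singleton = max(1, n_restarts // 3)
    best: Partition | None = None
    best_q = -np.inf
    for ri, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        if ri == 0:
            init = cc_init
        elif ri <= n_singleton:
            init = None
        else:
            k = int(rng.integers(2, max(3, min(len(nodes), 6))))
            groups = rng.integers(0, k, size=len(nodes))
            init = {node: int(groups[i]) for i, node in enumerate(nodes)}
        level1 = _louvain_one_level(net.graph, weighted, rng, init=init)
        part = _clusters_to_partition(level1, "LC", net.threshold)
        q = modularity(net, part, weighted=weighted)
        if q > best_q:
            best, best_q = part, q
    return best


def modularity(net: SimilarityNetwork, partition: Partition,
               weighted: bool = True) -> float:
    """Newman-Girvan modularity Q of a partition of the network.

    ``Q = sum_c [ W_c / W - (S_c / 2W)^2 ]`` with W the total edge weight,
    W_c the intra-cluster weight and S_c the summed strength of cluster c.
    Q is 0 for the single-cluster partition of a connected graph.
    """
    g = net.graph
    missing = set(g.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    w_tot = 0.0
    w_in: dict[str, float] = {}
    strength: dict[str, float] = {}
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        w_tot += w
        cu, cv = partition.assignment[u], partition.assignment[v]
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + w
        strength[cu] = strength.get(cu, 0.0) + w
        strength[cv] = strength.get(cv, 0.0) + w
    if w_tot == 0:
        raise ValueError("modularity undefined on an edgeless network")
    q = 0.0
    for cid in set(partition.assignment.values()):
        q += w_in.get(cid, 0.0) / w_tot - (strength.get(cid, 0.0) / (2 * w_tot)) ** 2
    return q


def giant_component(net: SimilarityNetwork) -> str:
    """Cluster id of the largest connected component (lexicographic ties)."""
    cc = connected_components(net)
    clusters = cc.clusters()
    if not clusters:
        raise ValueError("network has no components")
    return min(clusters, key=lambda cid: (-len(clusters[cid]), cid))


def supernode_graph(net: SimilarityNetwork, lc_partition: Partition) -> nx.Graph:
    """Quotient graph with one supernode per Louvain community.

    Each supernode carries the community size and the fraction of each
    epoch/site/habitat label among its members; two supernodes are joined
    when at least one original edge crosses the two communities.
    """
    if lc_partition.kind != "LC":
        raise ValueError("supernode_graph expects an LC partition")
    g = net.graph
    q = nx.Graph()
    for cid, members in lc_partition.clusters().items():
        attrs: dict[str, float] = {"size": len(members)}
        for key in ("epoch", "site", "habitat"):
            counts: dict[str, int] = {}
            for node in members:
                value = g.nodes[node].get(key)
                if value is not None:
                    counts[value] = counts.get(value, 0) + 1
            for value, n in sorted(counts.items()):
                attrs[f"frac_{key}_{value}"] = n / len(members)
        q.add_node(cid, **attrs)
    for u, v in g.edges:
        cu, cv = lc_partition.assignment[u], lc_partition.assignment[v]
        if cu != cv:
            q.add_edge(cu, cv)
    return q


# ---------------------------------------------------------------------------
# exports

def write_graphml(net: SimilarityNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edgelist(net: SimilarityNetwork, path) -> None:
    """3-column weighted edge list: node1, node2, pct_identity (TSV)."""
    rows = sorted((min(u, v), max(u, v), d["weight"])
                  for u, v, d in net.graph.edges(data=True))
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tpct_identity\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:g}\n")


def write_partition(partition: Partition, path) -> None:
    partition.to_frame().to_csv(path, sep="\t", index=False)
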