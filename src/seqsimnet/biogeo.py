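"""Endemism versus cosmopolitan dispersal: assortativity and cluster profiles.

Two complementary measures. First, Newman's two-category assortativity
coefficient r, computed per cluster (CC or LC induced subgraph) for each
site or habitat label against all other nodes, with a topology-preserving
label-shuffle null: r = 0 when edges between the two categories are placed
randomly, positive when same-label nodes preferentially connect. Observed
and null r distributions are compared with a one-sided two-sample
Kolmogorov-Smirnov test (observed stochastically greater than null).
Second, per-cluster profiles of abundance (sequence count), occurrence
(number of distinct sampling sites) and evenness (Simpson index
``SI = 1 - sum p_i^2`` over per-site proportions, ranging from 0 for a
single-site cluster to 1 - 1/N for a perfectly even spread over N sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import Partition, SimilarityNetwork


# ---------------------------------------------------------------------------
# two-category assortativity

def _edge_arrays(graph: nx.Graph) -> tuple[np.ndarray, np.ndarray, list]:
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    if graph.number_of_edges() == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp), nodes
    uv = np.array([(index[u], index[v]) for u, v in graph.edges], dtype=np.intp)
    return uv[:, 0], uv[:, 1], nodes


def _r_from_mask(u: np.ndarray, v: np.ndarray, target: np.ndarray) -> float:
    """Newman's r for categories {target, other} from edge index arrays.

    With e_ij half the fraction of ordered edge endpoints joining category
    i to j (symmetric, summing to 1) and a_i its marginals:
    ``r = (sum_i e_ii - sum_i a_i^2) / (1 - sum_i a_i^2)``.
    """
    m = u.size
    tu, tv = target[u], target[v]
    n_tt = float(np.count_nonzero(tu & tv))
    n_oo = float(np.count_nonzero(~tu & ~tv))
    n_to = m - n_tt - n_oo
    e_tt, e_oo = n_tt / m, n_oo / m
    half_cross = n_to / (2.0 * m)
    a_t = e_tt + half_cross
    a_o = e_oo + half_cross
    trace = e_tt + e_oo
    sq = a_t * a_t + a_o * a_o
    if sq == 1.0:
        raise ValueError("assortativity undefined: single category present")
    return (trace - sq) / (1.0 - sq)


def _target_mask(graph: nx.Graph, nodes: Sequence, label_key: str,
                 label_value: str) -> np.ndarray:
    return np.array([graph.nodes[n].get(label_key) == label_value
                     for n in nodes], dtype=bool)


def assortativity_two_cat(subgraph: nx.Graph, label_key: str,
                          label_value: str) -> float:
    """Two-category assortativity of ``label_value`` vs all other nodes.

    Unweighted edges. Raises ``ValueError`` on an edgeless subgraph or when
    only one category is present (denominator 0).
    """
    u, v, nodes = _edge_arrays(subgraph)
    if u.size == 0:
        raise ValueError("assortativity undefined: subgraph has no edges")
    return _r_from_mask(u, v, _target_mask(subgraph, nodes, label_key, label_value))


def shuffle_null(subgraph: nx.Graph, label_key: str, label_value: str,
                 n_perm: int, seed: int = 0) -> np.ndarray:
    """Null r values from label shuffles that keep the topology fixed.

    Permutes the node-label multiset (category counts preserved, edges
    untouched) ``n_perm`` times and returns each permutation's r.
    """
    u, v, nodes = _edge_arrays(subgraph)
    if n_perm == 0:
        return np.empty(0)
    if u.size == 0:
        raise ValueError("assortativity undefined: subgraph has no edges")
    target = _target_mask(subgraph, nodes, label_key, label_value)
    if target.all() or not target.any():
        raise ValueError("assortativity undefined: single category present")
    rng = np.random.default_rng(seed)
    return np.array([_r_from_mask(u, v, rng.permutation(target))
                     for _ in range(n_perm)])


@dataclass
class AssortativityResult:
    """Observed and null assortativity for one label value."""

    label_key: str
    label_value: str
    observed: dict[str, float]          # cluster id -> r
    null: np.ndarray                    # pooled shuffles over those clusters
    excluded: dict[str, str]            # cluster id -> reason
    ks_statistic: float = math.nan
    p_value: float = math.nan
    significant: bool = False


def assortativity_significance(observed: Sequence[float],
                               null: Sequence[float],
                               alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sided KS test of observed r stochastically greater than null."""
    if len(observed) == 0 or len(null) == 0:
        return math.nan, math.nan, False
    res = stats.ks_2samp(observed, null, alternative="less")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def assortativity_scan(net: SimilarityNetwork, partition: Partition,
                       label_key: str,
                       label_values: Optional[Sequence[str]] = None,
                       n_perm: int = 100, seed: int = 0,
                       alpha: float = 0.05) -> list[AssortativityResult]:
    """Per-cluster assortativity with shuffle null, for every label value.

    Clusters lacking edges or one of the two categories are excluded from
    observed and null distributions symmetrically, with the reason
    recorded. The per-value KS test compares the observed per-cluster r
    values with the pooled null.
    """
    g = net.graph
    if label_values is None:
        label_values = sorted({d[label_key] for _, d in g.nodes(data=True)
                               if d.get(label_key) is not None})
    clusters = partition.clusters()
    seeds = np.random.SeedSequence(seed).generate_state(
        len(label_values) * len(clusters)) % (2 ** 31)
    results = []
    for vi, value in enumerate(label_values):
        observed: dict[str, float] = {}
        null_parts = []
        excluded: dict[str, str] = {}
        for ci, cid in enumerate(sorted(clusters)):
            sub = g.subgraph(clusters[cid])
            u, v, nodes = _edge_arrays(sub)
            if u.size == 0:
                excluded[cid] = "no edges"
                continue
            target = _target_mask(sub, nodes, label_key, value)
            if target.all() or not target.any():
                excluded[cid] = "single category"
                continue
            observed[cid] = _r_from_mask(u, v, target)
            null_parts.append(shuffle_null(sub, label_key, value, n_perm,
                                           seed=int(seeds[vi * len(clusters) + ci])))
        null = np.concatenate(null_parts) if null_parts else np.empty(0)
        stat, p, sig = assortativity_significance(list(observed.values()),
                                                  null, alpha=alpha)
        results.append(AssortativityResult(
            label_key=label_key, label_value=value, observed=observed,
            null=null, excluded=excluded, ks_statistic=stat, p_value=p,
            significant=sig))
    return results


def pooled_significance(results: Sequence[AssortativityResult],
                        alpha: float = 0.05) -> tuple[float, float, bool]:
    """Overall label-class test: pool observed and null r over all values.

    At desk scale a single mixed giant component can dominate, leaving one
    observed value per label; pooling across the label class (e.g. all
    eight sites) restores a testable sample while asking the same
    question — are same-label sequences preferentially connected?
    """
    observed = [r for res in results for r in res.observed.values()]
    null = (np.concatenate([res.null for res in results if res.null.size])
            if any(res.null.size for res in results) else np.empty(0))
    return assortativity_significance(observed, null, alpha=alpha)


def assortativity_frame(results: Sequence[AssortativityResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        rows.append({
            "label_key": res.label_key, "label_value": res.label_value,
            "n_clusters_tested": len(res.observed),
            "n_clusters_excluded": len(res.excluded),
            "mean_observed_r": (float(np.mean(list(res.observed.values())))
                                if res.observed else math.nan),
            "mean_null_r": float(res.null.mean()) if res.null.size else math.nan,
            "ks_statistic": res.ks_statistic, "p_value": res.p_value,
            "significant": res.significant})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evenness and cluster profiles

def simpson_evenness(site_counts: Sequence[float]) -> float:
    """Simpson index ``SI = 1 - sum p_i^2`` over per-site proportions.

    0 when all sequences fall at one site; approaches the upper limit
    ``1 - 1/N`` for a perfectly even spread over N sites.
    """
    counts = np.asarray(site_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("site counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("site counts must sum to a positive value")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass
class ClusterProfile:
    """Abundance / occurrence / evenness profile of one cluster."""

    cluster: str
    abundance: int
    occurrence: int
    evenness: float
    exclusive_site: Optional[str]
    exclusive_habitat: Optional[str]
    cosmopolitan: bool
    restricted: bool


def cluster_profiles(partition: Partition, net: SimilarityNetwork,
                     n_sites: int = 8,
                     restricted_max_sites: int = 4) -> list[ClusterProfile]:
    """Profile every cluster: abundance, occurrence, Simpson evenness, flags.

    Occurrence counts distinct sites among environmental members (cultured
    members, which carry no site, are ignored). A cluster is cosmopolitan
    when it spans all ``n_sites`` sites and restricted when it spans at
    most ``restricted_max_sites``. Clusters with no sited member get
    occurrence 0 and NaN evenness.
    """
    g = net.graph
    profiles = []
    for cid, members in sorted(partition.clusters().items()):
        site_counts: dict[str, int] = {}
        habitats: set = set()
        for node in members:
            site = g.nodes[node].get("site")
            if site is not None:
                site_counts[site] = site_counts.get(site, 0) + 1
            habitat = g.nodes[node].get("habitat")
            if habitat is not None:
                habitats.add(habitat)
        occurrence = len(site_counts)
        evenness = (simpson_evenness(list(site_counts.values()))
                    if occurrence else math.nan)
        profiles.append(ClusterProfile(
            cluster=cid, abundance=len(members), occurrence=occurrence,
            evenness=evenness,
            exclusive_site=(next(iter(site_counts)) if occurrence == 1 else None),
            exclusive_habitat=(habitats.pop() if len(habitats) == 1 else None),
            cosmopolitan=occurrence == n_sites,
            restricted=0 < occurrence <= restricted_max_sites))
    return profiles


def profiles_frame(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])


def exclusivity_fractions(partition: Partition, net: SimilarityNetwork,
                          label_key: str) -> dict[str, float]:
    """Fraction of clusters exclusive to each value of a label class.

    A cluster is exclusive to value v when every environmental member
    (members carrying the label) shares v and at least one such member
    exists. The denominator is the total cluster count.
    """
    g = net.graph
    values = sorted({d[label_key] for _, d in g.nodes(data=True)
                     if d.get(label_key) is not None})
    counts = {v: 0 for v in values}
    clusters = partition.clusters()
    for members in clusters.values():
        seen = {g.nodes[n][label_key] for n in members
                if g.nodes[n].get(label_key) is not None}
        if len(seen) == 1:
            counts[next(iter(seen))] += 1
    total = len(clusters)
    return {v: (c / total if total else math.nan) for v, c in counts.items()}
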