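"""Novelty of environmental diversity relative to cultured references.

Cultured isolates anchor the networks: a sequence close to a reference sits
near it (short path, high closeness), while genuinely new diversity forms
reference-free clusters at the periphery. This module quantifies that in
four ways: per-cluster epoch composition, the novel-community rule
(communities at a permissive threshold consisting exclusively of new-survey
sequences whose members are on average below 95% identity to every cultured
reference), shortest-path distance to the nearest cultured node, and
per-component closeness centrality contrasted between groups with a
one-sided Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .records import SequenceRecord
from .similarity import AlignmentHit, filter_hits, pairwise_hits
from .network import Partition, SimilarityNetwork


@dataclass
class KSResult:
    statistic: float
    p_value: float
    alternative: str
    significant_05: bool
    significant_01: bool


def epoch_composition(partition: Partition, net: SimilarityNetwork) -> pd.DataFrame:
    """Per-cluster fractions of cultured / prior_env / new_survey members."""
    rows = []
    for cid, members in sorted(partition.clusters().items()):
        counts = {"cultured": 0, "prior_env": 0, "new_survey": 0}
        for node in members:
            counts[net.graph.nodes[node].get("epoch", "new_survey")] += 1
        n = len(members)
        rows.append({"cluster": cid, "size": n,
                     **{k: v / n for k, v in counts.items()}})
    return pd.DataFrame(rows)


def exclusive_clusters(partition: Partition, net: SimilarityNetwork,
                       epoch: str) -> list[str]:
    """Clusters whose members all carry the given epoch label."""
    out = []
    for cid, members in sorted(partition.clusters().items()):
        if all(net.graph.nodes[n].get("epoch") == epoch for n in members):
            out.append(cid)
    return out


def reference_free_fraction(partition: Partition, net: SimilarityNetwork) -> float:
    """Fraction of clusters containing no cultured or prior-survey member."""
    n = partition.n_clusters
    return len(exclusive_clusters(partition, net, "new_survey")) / n if n else math.nan


def best_reference_identities(members: Sequence[SequenceRecord],
                              cultured_refs: Sequence[SequenceRecord],
                              hits: Optional[Sequence[AlignmentHit]] = None,
                              **filter_kwargs) -> dict[str, float]:
    """Best filtered-hit identity of each member to any cultured reference.

    Members with no hit surviving the standard filters contribute 0. When
    ``hits`` (an already-filtered hit list covering members and references)
    is given it is reused; otherwise member-vs-reference alignments are
    computed and filtered here.
    """
    if not cultured_refs:
        raise ValueError("cultured reference set is empty")
    ref_ids = {r.id for r in cultured_refs}
    member_ids = {m.id for m in members}
    if hits is None:
        hits = filter_hits(pairwise_hits(list(members) + list(cultured_refs)),
                           list(members) + list(cultured_refs), **filter_kwargs)
    best = {mid: 0.0 for mid in member_ids}
    for h in hits:
        for mid, rid in ((h.query_id, h.subject_id), (h.subject_id, h.query_id)):
            if mid in member_ids and rid in ref_ids:
                best[mid] = max(best[mid], h.pct_identity)
    return best


def novel_lcs(lc_partition: Partition,
              records: Sequence[SequenceRecord],
              cultured_refs: Sequence[SequenceRecord],
              avg_identity_cutoff: float = 95.0,
              hits: Optional[Sequence[AlignmentHit]] = None,
              pair_mean: bool = False) -> list[str]:
    """Novel communities: exclusively new-survey and far from all references.

    A community is novel when (a) every member has epoch ``new_survey`` and
    (b) the mean over members of each member's best identity to any
    cultured reference (0 when no qualifying hit) is below
    ``avg_identity_cutoff``. With ``pair_mean=True`` the mean is instead
    taken over all member x reference identities.
    """
    if not cultured_refs:
        raise ValueError("cultured reference set is empty")
    by_id = {r.id: r for r in records}
    novel = []
    for cid, members in sorted(lc_partition.clusters().items()):
        recs = [by_id[m] for m in members]
        if any(r.epoch != "new_survey" for r in recs):
            continue
        if pair_mean:
            total, count = 0.0, 0
            for ref in cultured_refs:
                ids = best_reference_identities(recs, [ref], hits=hits)
                total += sum(ids.values())
                count += len(ids)
            mean_identity = total / count
        else:
            best = best_reference_identities(recs, cultured_refs, hits=hits)
            mean_identity = sum(best.values()) / len(best)
        if mean_identity < avg_identity_cutoff:
            novel.append(cid)
    return novel


# ---------------------------------------------------------------------------
# path distances and closeness

def distances_to_culture(net: SimilarityNetwork) -> dict[str, float]:
    """Shortest-path edge count from each environmental node to the
    nearest cultured node (``inf`` when unreachable)."""
    g = net.graph
    cultured = [n for n, d in g.nodes(data=True) if d.get("epoch") == "cultured"]
    dist = {n: math.inf for n in g.nodes}
    queue = deque()
    for n in cultured:
        dist[n] = 0
        queue.append(n)
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if dist[v] == math.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return {n: d for n, d in dist.items()
            if g.nodes[n].get("epoch") != "cultured"}


def distance_to_culture(net: SimilarityNetwork, node: str) -> float:
    """Distance of one environmental node to the nearest cultured node."""
    dists = distances_to_culture(net)
    if node not in dists:
        raise KeyError(f"{node!r} is not an environmental node of the network")
    return dists[node]


def distance_class_fractions(net: SimilarityNetwork) -> dict[str, float]:
    """Fractions of environmental nodes at distance 1, >1, and unreachable."""
    dists = list(distances_to_culture(net).values())
    n = len(dists)
    if n == 0:
        return {"distance_1": math.nan, "distance_gt1": math.nan,
                "unreachable": math.nan}
    return {
        "distance_1": sum(d == 1 for d in dists) / n,
        "distance_gt1": sum(1 < d < math.inf for d in dists) / n,
        "unreachable": sum(math.isinf(d) for d in dists) / n,
    }


def closeness_values(net: SimilarityNetwork) -> dict[str, float]:
    """Per-component closeness of every node.

    Within a node's connected component of size n_c, closeness is
    ``(n_c - 1) / sum of shortest-path distances`` to the other members;
    the two nodes of a single-edge component both score 1.
    """
    g = net.graph
    out: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n_c = len(comp)
        for node in comp:
            total = sum(nx.single_source_shortest_path_length(sub, node).values())
            out[node] = (n_c - 1) / total if total else 0.0
    return out


def closeness(net: SimilarityNetwork, node: str) -> float:
    g = net.graph
    if node not in g:
        raise KeyError(f"{node!r} is not in the network")
    comp = nx.node_connected_component(g, node)
    sub = g.subgraph(comp)
    total = sum(nx.single_source_shortest_path_length(sub, node).values())
    return (len(comp) - 1) / total if total else 0.0


def closeness_contrast(group_a: Sequence[float], group_b: Sequence[float],
                       alpha: tuple[float, float] = (0.05, 0.01)) -> KSResult:
    """One-sided two-sample KS test: values of A stochastically greater
    than values of B (e.g. cultured closeness vs environmental closeness)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    # scipy's 'less': empirical CDF of the first sample below the second's,
    # i.e. the first sample takes larger values.
    res = stats.ks_2samp(group_a, group_b, alternative="less")
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                    alternative="A stochastically greater than B",
                    significant_05=bool(res.pvalue < alpha[0]),
                    significant_01=bool(res.pvalue < alpha[1]))


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class NoveltyReport:
    threshold: float
    composition: pd.DataFrame
    exclusive: dict[str, list[str]]
    novel_communities: list[str]
    node_measures: pd.DataFrame  # id, distance_to_culture, closeness
    contrasts: dict[str, KSResult]

    def write(self, out_dir, prefix: str = "novelty") -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        self.composition.to_csv(out / f"{prefix}_composition.tsv", sep="\t",
                                index=False)
        self.node_measures.to_csv(out / f"{prefix}_node_measures.tsv", sep="\t",
                                  index=False)
        rows = [{"test": name, "ks_statistic": r.statistic, "p_value": r.p_value,
                 "significant_0.05": r.significant_05,
                 "significant_0.01": r.significant_01}
                for name, r in self.contrasts.items()]
        pd.DataFrame(rows).to_csv(out / f"{prefix}_tests.tsv", sep="\t",
                                  index=False)
        pd.DataFrame({"novel_community": self.novel_communities}).to_csv(
            out / f"{prefix}_novel_communities.tsv", sep="\t", index=False)


def novelty_report(net: SimilarityNetwork,
                   lc_partition: Partition,
                   records: Sequence[SequenceRecord],
                   hits: Optional[Sequence[AlignmentHit]] = None,
                   avg_identity_cutoff: float = 95.0) -> NoveltyReport:
    """Assemble the full novelty report for one network."""
    refs = [r for r in records if r.epoch == "cultured"]
    comp = epoch_composition(lc_partition, net)
    exclusive = {e: exclusive_clusters(lc_partition, net, e)
                 for e in ("cultured", "prior_env", "new_survey")}
    novel = novel_lcs(lc_partition, records, refs, hits=hits,
                      avg_identity_cutoff=avg_identity_cutoff) if refs else []
    dists = distances_to_culture(net)
    close = closeness_values(net)
    node_measures = pd.DataFrame(
        {"id": sorted(net.graph.nodes),
         "distance_to_culture": [dists.get(n, 0.0) for n in sorted(net.graph.nodes)],
         "closeness": [close[n] for n in sorted(net.graph.nodes)]})
    groups: dict[str, list[float]] = {"cultured": [], "prior_env": [],
                                      "new_survey": []}
    for node, value in close.items():
        groups[net.graph.nodes[node].get("epoch", "new_survey")].append(value)
    contrasts = {}
    env_all = groups["prior_env"] + groups["new_survey"]
    if groups["cultured"] and groups["prior_env"]:
        contrasts["cultured_vs_prior_env"] = closeness_contrast(
            groups["cultured"], groups["prior_env"])
    if groups["cultured"] and env_all:
        contrasts["cultured_vs_all_environmental"] = closeness_contrast(
            groups["cultured"], env_all)
    return NoveltyReport(threshold=net.threshold, composition=comp,
                         exclusive=exclusive, novel_communities=novel,
                         node_measures=node_measures, contrasts=contrasts)
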