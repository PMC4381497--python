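import itertools

import networkx as nx
import numpy as np
import pytest

from oracles import (exhaustive_max_modularity, modularity_oracle,
                     union_find_components)
from seqsimnet import (SequenceRecord, build_network, connected_components,
                       giant_component, louvain_level1, modularity,
                       supernode_graph)
from seqsimnet.network import (Partition, SimilarityNetwork, write_edgelist,
                               write_partition)
from seqsimnet.similarity import AlignmentHit


def _hit(q, s, pct):
    return AlignmentHit(query_id=q, subject_id=s, pct_identity=pct,
                        align_length=380, evalue=1e-100)


#: the five-node mock: A-B 99, B-C 97, D-E 97, C-D 96
MOCK_HITS = [_hit("A", "B", 99), _hit("B", "C", 97),
             _hit("D", "E", 97), _hit("C", "D", 96)]


def _net_from_graph(g, threshold=97.0):
    return SimilarityNetwork(threshold=threshold, graph=g)


def test_mock_network_two_components_at_97():
    net = build_network(MOCK_HITS, threshold=97)
    assert set(map(frozenset, nx.connected_components(net.graph))) == \
        {frozenset("ABC"), frozenset("DE")}
    cc = connected_components(net)
    assert cc.n_clusters == 2


def test_mock_network_single_giant_component_at_96():
    net = build_network(MOCK_HITS, threshold=96)
    assert net.n_edges == 4
    cc = connected_components(net)
    assert cc.n_clusters == 1
    assert set(cc.assignment) == set("ABCDE")


def test_threshold_100_with_no_perfect_hits_gives_empty_network():
    net = build_network(MOCK_HITS, threshold=100)
    assert net.n_nodes == 0 and net.n_edges == 0


def test_singletons_are_excluded():
    net = build_network(MOCK_HITS, threshold=98)  # only A-B survives
    assert set(net.graph.nodes) == {"A", "B"}


@pytest.mark.parametrize("threshold", [0, -1, 101])
def test_threshold_validation(threshold):
    with pytest.raises(ValueError):
        build_network(MOCK_HITS, threshold=threshold)


def test_network_carries_labels_from_records():
    recs = [SequenceRecord(id="A", sequence="ACGT", epoch="cultured"),
            SequenceRecord(id="B", sequence="ACGT", site="site1",
                           habitat="DCM")]
    net = build_network([_hit("A", "B", 99)], recs, threshold=97)
    assert net.graph.nodes["A"]["epoch"] == "cultured"
    assert net.graph.nodes["B"]["site"] == "site1"
    assert "site" not in net.graph.nodes["A"]


def test_component_ids_are_lexicographic_minima():
    net = build_network(MOCK_HITS, threshold=97)
    cc = connected_components(net)
    assert set(cc.clusters()) == {"A", "D"}


def test_components_match_union_find_oracle():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n = int(rng.integers(2, 51))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.02, 0.3)),
                                seed=int(rng.integers(2 ** 31)))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            continue
        net = _net_from_graph(g)
        ours = set(connected_components(net).clusters().values())
        oracle = union_find_components(g.nodes, g.edges)
        assert ours == oracle


def test_modularity_single_cluster_is_zero(small_networks):
    g = nx.path_graph(5)
    net = _net_from_graph(g)
    part = Partition(kind="CC", threshold=97,
                     assignment={n: "c" for n in g.nodes})
    assert modularity(net, part) == pytest.approx(0.0, abs=1e-12)


def test_modularity_singletons_on_four_cycle():
    g = nx.cycle_graph(4)
    net = _net_from_graph(g)
    part = Partition(kind="LC", threshold=97,
                     assignment={n: str(n) for n in g.nodes})
    assert modularity(net, part) == pytest.approx(-0.25, abs=1e-12)


def test_modularity_matches_networkx_on_random_weighted_graphs():
    rng = np.random.default_rng(21)
    for _ in range(20):
        g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(2 ** 31)))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_edges() == 0:
            continue
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(85, 100))
        labels = {n: str(rng.integers(3)) for n in g.nodes}
        sets = {}
        for n, c in labels.items():
            sets.setdefault(c, set()).add(n)
        part = Partition(kind="LC", threshold=85, assignment=labels)
        net = _net_from_graph(g, 85)
        assert modularity(net, part) == pytest.approx(
            modularity_oracle(g, list(sets.values())), abs=1e-12)


def test_modularity_requires_full_cover():
    g = nx.path_graph(3)
    net = _net_from_graph(g)
    part = Partition(kind="CC", threshold=97, assignment={0: "a", 1: "a"})
    with pytest.raises(ValueError, match="cover"):
        modularity(net, part)


def _two_cliques_bridge():
    g = nx.Graph()
    for offset in (0, 4):
        g.add_edges_from((i + offset, j + offset)
                         for i, j in itertools.combinations(range(4), 2))
    g.add_edge(0, 4)
    return g


def test_louvain_recovers_two_cliques_exactly():
    g = _two_cliques_bridge()
    net = _net_from_graph(g)
    lc = louvain_level1(net, seed=1)
    assert set(lc.clusters().values()) == {frozenset(range(4)),
                                           frozenset(range(4, 8))}
    assert modularity(net, lc, weighted=False) == pytest.approx(
        exhaustive_max_modularity(g, weighted=False), abs=1e-12)


def test_louvain_single_clique_is_one_community():
    g = nx.complete_graph(5)
    lc = louvain_level1(_net_from_graph(g), seed=1)
    assert lc.n_clusters == 1


def test_louvain_beats_singletons_and_refines_components(small_networks):
    _, _, nets = small_networks
    for t, net in nets.items():
        if net.n_nodes == 0:
            continue
        lc = louvain_level1(net, seed=2)
        cc = connected_components(net)
        assert lc.refines(cc)
        singletons = Partition(kind="LC", threshold=t,
                               assignment={n: n for n in net.graph.nodes})
        assert modularity(net, lc) >= modularity(net, singletons)


def test_louvain_near_optimal_on_small_graphs():
    """The local-move phase reaches >= 0.9x the exhaustive modularity
    optimum. Tiny dense graphs are rich in greedy-ascent traps, so basin
    coverage needs a deep multi-start (restarts are ~free at n <= 8)."""
    rng = np.random.default_rng(31)
    tested = 0
    while tested < 25:
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.3, 0.8)),
                                seed=int(rng.integers(2 ** 31)))
        if not nx.is_connected(g) or g.number_of_edges() == 0:
            continue
        tested += 1
        net = _net_from_graph(g)
        lc = louvain_level1(net, seed=5, n_restarts=64)
        q = modularity(net, lc, weighted=False)
        best = exhaustive_max_modularity(g, weighted=False)
        assert q >= 0.9 * best - 1e-12


def test_threshold_monotonicity(small_networks):
    """Raising the threshold only splits components: the CC partition at a
    higher threshold refines the lower-threshold partition on shared nodes."""
    _, _, nets = small_networks
    thresholds = sorted(nets)
    for lo, hi in zip(thresholds, thresholds[1:]):
        cc_lo, cc_hi = connected_components(nets[lo]), connected_components(nets[hi])
        restricted = Partition(
            kind="CC", threshold=hi,
            assignment={n: c for n, c in cc_hi.assignment.items()
                        if n in cc_lo.assignment})
        assert restricted.refines(cc_lo)


def test_giant_component_size_and_ties():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                      ("x", "y")])
    assert giant_component(_net_from_graph(g)) == "a"
    tie = nx.Graph()
    tie.add_edges_from([("m", "n"), ("n", "o"), ("a", "b"), ("b", "c")])
    assert giant_component(_net_from_graph(tie)) == "a"  # 3 vs 3, lexicographic


def test_supernode_graph_quotient():
    g = _two_cliques_bridge()
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    for i in range(4):
        g.nodes[f"n{i}"]["epoch"] = "new_survey"
        g.nodes[f"n{i + 4}"]["epoch"] = "cultured"
    net = _net_from_graph(g)
    lc = louvain_level1(net, seed=1)
    q = supernode_graph(net, lc)
    assert q.number_of_nodes() == 2 and q.number_of_edges() == 1
    fracs = {q.nodes[c].get("frac_epoch_new_survey", 0.0) for c in q.nodes}
    assert fracs == {0.0, 1.0}
    assert all(q.nodes[c]["size"] == 4 for c in q.nodes)


def test_supernode_fraction_direct_count():
    g = nx.complete_graph(10)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    for i, n in enumerate(sorted(g.nodes)):
        g.nodes[n]["epoch"] = "new_survey" if i < 4 else "prior_env"
    net = _net_from_graph(g)
    lc = Partition(kind="LC", threshold=97,
                   assignment={n: "c" for n in g.nodes})
    q = supernode_graph(net, lc)
    assert q.nodes["c"]["frac_epoch_new_survey"] == pytest.approx(0.4)
    assert q.number_of_edges() == 0


def test_exports_round_trip(tmp_path, small_networks):
    _, _, nets = small_networks
    net = nets[97]
    write_edgelist(net, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert lines[0] == "node1\tnode2\tpct_identity"
    assert len(lines) - 1 == net.n_edges
    cc = connected_components(net)
    write_partition(cc, tmp_path / "cc.tsv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "cc.tsv", sep="\t")
    assert set(df.columns) == {"id", "cluster", "kind", "threshold"}
    assert len(df) == net.n_nodes
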