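import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import assortativity_oracle
from seqsimnet import (assortativity_scan, assortativity_significance,
                       assortativity_two_cat, cluster_profiles,
                       connected_components, exclusivity_fractions,
                       pooled_significance, shuffle_null, simpson_evenness)
from seqsimnet.biogeo import profiles_frame
from seqsimnet.network import Partition, SimilarityNetwork


def _labelled(edges, labels, key="site"):
    g = nx.Graph()
    g.add_edges_from(edges)
    for n, v in labels.items():
        g.nodes[n][key] = v
    return g


# ---------------------------------------------------------------------------
# assortativity coefficient

def test_alternating_four_cycle_is_perfectly_disassortative():
    g = _labelled([(0, 1), (1, 2), (2, 3), (3, 0)],
                  {0: "T", 1: "O", 2: "T", 3: "O"})
    assert assortativity_two_cat(g, "site", "T") == pytest.approx(-1.0,
                                                                  abs=1e-12)


def test_path_ttoo_is_one_third():
    g = _labelled([(0, 1), (1, 2), (2, 3)],
                  {0: "T", 1: "T", 2: "O", 3: "O"})
    assert assortativity_two_cat(g, "site", "T") == pytest.approx(1 / 3,
                                                                  abs=1e-12)


def test_single_category_and_edgeless_are_undefined():
    g = _labelled([(0, 1)], {0: "T", 1: "T"})
    with pytest.raises(ValueError, match="single category"):
        assortativity_two_cat(g, "site", "T")
    lonely = _labelled([], {})
    lonely.add_nodes_from([0, 1])
    with pytest.raises(ValueError, match="no edges"):
        assortativity_two_cat(lonely, "site", "T")


def test_matches_brute_force_and_networkx_oracles():
    """r agrees with an explicit e-matrix enumeration (and networkx's own
    categorical coefficient) on 200 random labelled graphs, to 1e-12."""
    rng = np.random.default_rng(41)
    tested = 0
    while tested < 200:
        n = int(rng.integers(3, 31))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.5)),
                                seed=int(rng.integers(2 ** 31)))
        if g.number_of_edges() == 0:
            continue
        target = {i for i in g.nodes if rng.random() < 0.5}
        if not target or len(target) == len(g.nodes):
            continue
        for i in g.nodes:
            g.nodes[i]["site"] = "T" if i in target else "O"
        expected = assortativity_oracle(g, target)
        if math.isnan(expected):  # denominator 0 (e.g. all edges cross)
            continue
        tested += 1
        r = assortativity_two_cat(g, "site", "T")
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(
            nx.attribute_assortativity_coefficient(g, "site"), abs=1e-9)
        assert -1.0 <= r <= 1.0


# ---------------------------------------------------------------------------
# shuffle null

def test_shuffle_null_mean_is_zero():
    """Random mixing calibrates r to ~0; the exact permutation expectation
    carries a small negative finite-size bias, well within +/-0.05 at n=30."""
    g = nx.gnp_random_graph(30, 0.2, seed=7)
    g.remove_nodes_from(list(nx.isolates(g)))
    nodes = sorted(g.nodes)
    for i, n in enumerate(nodes):
        g.nodes[n]["site"] = "T" if i < len(nodes) // 2 else "O"
    null = shuffle_null(g, "site", "T", n_perm=1500, seed=5)
    assert abs(null.mean()) < 0.05


def test_shuffle_null_contracts():
    g = _labelled([(0, 1), (1, 2), (2, 3)],
                  {0: "T", 1: "T", 2: "O", 3: "O"})
    assert shuffle_null(g, "site", "T", n_perm=0).size == 0
    a = shuffle_null(g, "site", "T", n_perm=50, seed=9)
    b = shuffle_null(g, "site", "T", n_perm=50, seed=9)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, shuffle_null(g, "site", "T", 50, seed=10))


def test_shuffle_null_constant_on_complete_graph():
    g = nx.complete_graph(6)
    for i in g.nodes:
        g.nodes[i]["site"] = "T" if i < 3 else "O"
    null = shuffle_null(g, "site", "T", n_perm=200, seed=1)
    assert np.allclose(null, null[0])


def test_significance_directions():
    rng = np.random.default_rng(44)
    null = rng.normal(0.0, 0.1, size=500)
    _, p_same, sig_same = assortativity_significance(null[:50], null)
    assert not sig_same
    _, p_hi, sig_hi = assortativity_significance(null[:50] + 0.8, null)
    assert sig_hi and p_hi < 1e-6
    _, _, sig_lo = assortativity_significance(null[:50] - 0.8, null)
    assert not sig_lo


def test_assortativity_scan_excludes_degenerate_clusters():
    g = _labelled([(0, 1), (1, 2), (2, 3), (10, 11)],
                  {0: "T", 1: "T", 2: "O", 3: "O", 10: "T", 11: "T"})
    net = SimilarityNetwork(threshold=97, graph=g)
    cc = connected_components(net)
    (res,) = assortativity_scan(net, cc, "site", label_values=["T"],
                                n_perm=20, seed=3)
    assert len(res.observed) == 1
    assert res.excluded == {10: "single category"}
    assert res.null.size == 20


# ---------------------------------------------------------------------------
# evenness

def test_simpson_hand_values():
    assert simpson_evenness([10, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.0)
    assert simpson_evenness([5, 5]) == pytest.approx(0.5)
    assert simpson_evenness([3] * 8) == pytest.approx(1 - 1 / 8)


def test_simpson_input_validation():
    with pytest.raises(ValueError):
        simpson_evenness([0, 0])
    with pytest.raises(ValueError):
        simpson_evenness([-1, 2])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                max_size=8).filter(lambda c: sum(c) > 0))
def test_simpson_range_property(counts):
    """SI lies in [0, 1 - 1/N] and is 0 exactly when one site is occupied."""
    si = simpson_evenness(counts)
    n = len(counts)
    assert -1e-12 <= si <= 1 - 1 / n + 1e-12
    occupied = sum(c > 0 for c in counts)
    assert (si == pytest.approx(0.0, abs=1e-12)) == (occupied == 1)


# ---------------------------------------------------------------------------
# cluster profiles and exclusivity

def _profile_net(site_lists, habitat="DCM"):
    g = nx.Graph()
    nodes = []
    for ci, sites in enumerate(site_lists):
        prev = None
        for ni, site in enumerate(sites):
            name = f"c{ci}n{ni}"
            g.add_node(name, site=site, habitat=habitat)
            if prev:
                g.add_edge(prev, name)
            prev = name
            nodes.append(name)
    return SimilarityNetwork(threshold=99, graph=g)


def test_profile_single_site_cluster():
    net = _profile_net([["site3"] * 10])
    (prof,) = cluster_profiles(connected_components(net), net)
    assert (prof.abundance, prof.occurrence, prof.evenness) == (10, 1, 0.0)
    assert prof.exclusive_site == "site3"
    assert prof.restricted and not prof.cosmopolitan


def test_profile_cosmopolitan_flag():
    net = _profile_net([[f"site{i}" for i in range(1, 9)]])
    (prof,) = cluster_profiles(connected_components(net), net, n_sites=8)
    assert prof.cosmopolitan and prof.occurrence == 8
    assert not prof.restricted
    assert prof.evenness == pytest.approx(1 - 1 / 8)


def test_profile_cultured_members_ignored():
    g = nx.Graph()
    g.add_node("ref", epoch="cultured")
    g.add_node("e1", site="site1", epoch="new_survey")
    g.add_edge("ref", "e1")
    net = SimilarityNetwork(threshold=99, graph=g)
    (prof,) = cluster_profiles(connected_components(net), net)
    assert prof.abundance == 2 and prof.occurrence == 1


def test_exclusivity_fractions_denominator_is_all_clusters():
    g = nx.Graph()
    g.add_node("a1", habitat="sediment"); g.add_node("a2", habitat="sediment")
    g.add_node("b1", habitat="sediment"); g.add_node("b2", habitat="DCM")
    g.add_edges_from([("a1", "a2"), ("b1", "b2")])
    net = SimilarityNetwork(threshold=99, graph=g)
    fracs = exclusivity_fractions(connected_components(net), net, "habitat")
    assert fracs == {"DCM": 0.0, "sediment": 0.5}


def test_no_exclusive_clusters_gives_zero_fractions():
    g = nx.Graph()
    g.add_node("a1", habitat="sediment"); g.add_node("a2", habitat="DCM")
    g.add_edge("a1", "a2")
    net = SimilarityNetwork(threshold=99, graph=g)
    fracs = exclusivity_fractions(connected_components(net), net, "habitat")
    assert set(fracs.values()) == {0.0}


def test_cosmopolitan_species_span_all_sites():
    """Under uniform dispersal, deeply sampled species (40 sequences over 8
    sites; coupon-collector coverage probability ~0.96 each) give a
    majority of components flagged cosmopolitan."""
    from seqsimnet import (ScenarioConfig, build_network, dereplicate,
                           filter_hits, generate_dataset, length_filter,
                           pairwise_hits)
    cfg = ScenarioConfig(n_species=8, seqs_per_species=40, frac_novel=0.25,
                         frac_cultured=0.75, dispersal_mode="cosmopolitan",
                         seed=47)
    records, _ = generate_dataset(cfg)
    recs, _ = dereplicate(length_filter(records))
    hits = filter_hits(pairwise_hits(recs), recs)
    net = build_network(hits, recs, threshold=97)
    profiles = cluster_profiles(connected_components(net), net, n_sites=8)
    cosmo = sum(p.cosmopolitan for p in profiles) / len(profiles)
    assert cosmo > 0.5


def test_profiles_frame_columns(small_networks):
    _, _, nets = small_networks
    net = nets[99]
    profs = cluster_profiles(connected_components(net), net)
    df = profiles_frame(profs)
    assert {"cluster", "abundance", "occurrence", "evenness"} <= set(df.columns)
    assert (df.occurrence <= 8).all()
    # SI = 0 whenever a cluster occupies a single site
    single = df[df.occurrence == 1]
    assert np.allclose(single.evenness, 0.0)
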