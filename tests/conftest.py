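import pytest

from seqsimnet import (ScenarioConfig, build_network, connected_components,
                       dereplicate, filter_hits, generate_dataset,
                       length_filter, pairwise_hits)


@pytest.fixture(scope="session")
def small_scenario():
    """A small planted community: 8 species (4 with cultured refs, 4 novel),
    6 sequences each, endemic dispersal."""
    cfg = ScenarioConfig(n_species=8, seqs_per_species=6, seed=11)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def small_products(small_scenario):
    """Dereplicated records and filtered all-vs-all hits for the small
    scenario."""
    _, records, _ = small_scenario
    recs, mult = dereplicate(length_filter(records))
    hits = filter_hits(pairwise_hits(recs), recs)
    return recs, mult, hits


@pytest.fixture(scope="session")
def small_networks(small_products):
    recs, _, hits = small_products
    nets = {t: build_network(hits, recs, threshold=t)
            for t in (85, 90, 95, 96, 97, 98, 99)}
    return recs, hits, nets
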