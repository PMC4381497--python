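# seqsimnet

Sequence-similarity networks for amplicon diversity surveys: from labelled
V4-length rDNA sequences to thresholded graphs, community partitions,
novelty detection against cultured references, and statistical tests of
endemism versus cosmopolitan dispersal.

## The problem

Environmental amplicon surveys (e.g. of marine ciliates sampled at several
coastal sites and habitats) produce far more sequences than can be placed
on curated phylogenies, and most of that diversity has no close cultured
relative. Sequence-similarity networks offer an assembly-free alternative:
every (dereplicated) sequence is a node, and two nodes are joined when a
filtered pairwise alignment reaches a percent-identity threshold τ. The
resulting graph family — one network per τ ∈ {85, 90, 95, 96, 97, 98, 99} —
supports three kinds of inference:

* **Clustering.** Connected components (CCs) are OTU-like clusters at
  threshold τ; level-1 Louvain communities (LCs) refine them into the
  tightest groups of similar sequences.
* **Novelty.** Sequences close to a cultured isolate sit near it: short
  path distance (edge count to the nearest cultured node) and high
  closeness `(n_c − 1) / Σ d(u, v)` within a component. Genuinely new
  diversity forms communities that contain only new-survey sequences and
  whose members average below 95% identity to every cultured reference.
* **Biogeography.** Newman's two-category assortativity
  `r = (Σᵢ eᵢᵢ − Σᵢ aᵢ²) / (1 − Σᵢ aᵢ²)` measures whether same-site (or
  same-habitat) sequences preferentially connect; significance comes from a
  topology-preserving label-shuffle null and a one-sided two-sample
  Kolmogorov–Smirnov test. Per-cluster profiles report abundance,
  occurrence (distinct sites, max 8) and Simpson evenness
  `SI = 1 − Σ pᵢ²` ∈ [0, 1 − 1/N].

Because real survey deposits are large and external, the package ships a
synthetic community generator that plants species with known centroids,
within/between-species divergences, dispersal scenarios (endemic,
cosmopolitan, habitat-structured) and a controlled fraction of novel
species — so every stage can be validated against ground truth.

## Worked example

```python
from seqsimnet import *

cfg = ScenarioConfig(n_species=8, seqs_per_species=6,
                     dispersal_mode="endemic", seed=11)
records, truth = generate_dataset(cfg)
recs, mult = dereplicate(length_filter(records))
hits = filter_hits(pairwise_hits(recs), recs)
print(f"{len(records)} records -> {len(recs)} dereplicated, {len(hits)} filtered hits")
for t in (85, 97):
    net = build_network(hits, recs, threshold=t)
    cc = connected_components(net)
    print(f"threshold {t}%: {net.n_nodes} nodes, {net.n_edges} edges, "
          f"{cc.n_clusters} components")

net85 = build_network(hits, recs, 85)
lc = louvain_level1(net85, seed=0)
refs = [r for r in recs if r.epoch == "cultured"]
novel = novel_lcs(lc, recs, refs, hits=hits)
print(f"novel communities at 85%: {len(novel)} (planted novel species: "
      f"{int(truth.species.novel.sum())})")

scan = assortativity_scan(net85, connected_components(net85), "site",
                          n_perm=100, seed=0)
stat, p, sig = pooled_significance(scan)
print(f"site assortativity (pooled one-sided KS): p = {p:.3g} -> "
      f"{'endemism' if sig else 'no structure'} detected")
```

prints

```
52 records -> 48 dereplicated, 291 filtered hits
threshold 85%: 48 nodes, 215 edges, 5 components
threshold 97%: 48 nodes, 122 edges, 8 components
novel communities at 85%: 4 (planted novel species: 4)
site assortativity (pooled one-sided KS): p = 0.00437 -> endemism detected
```

Reading the output: at the permissive 85% threshold the four related
(non-novel) species merge into one giant component while each of the four
planted novel species stays isolated (5 components); at the species-like
97% threshold the components equal the eight planted species. The
novel-community rule recovers exactly the four planted novel species, and
because each species was confined to one site, same-site sequences connect
preferentially — the shuffle-null KS test flags endemism.

The same pipeline runs from the shell:

```bash
seqsimnet simulate --n-species 8 --seqs-per-species 6 --mode endemic \
    --seed 11 --out demo
seqsimnet similarity demo.fasta --out demo_hits.tsv
seqsimnet network demo.fasta demo_hits.tsv --threshold 97 --out-prefix demo97
seqsimnet novelty demo.fasta demo_hits.tsv --out-dir demo_novelty
seqsimnet biogeo demo.fasta demo_hits.tsv --out-dir demo_biogeo
seqsimnet run --simulate endemic --seed 11 --out-dir demo_run   # all stages
```

Inputs can also be real data: any FASTA (headers may carry
`|molecule=..|epoch=..|site=..|habitat=..` labels) plus, optionally,
precomputed all-vs-all hits in 12-column BLAST tabular format
(`--blast-tab`), to which the standard filters (E < 1e-5, identity ≥ 60%,
alignment length ≥ 40% of the shorter sequence, per-site dereplication,
length ≥ 300 bp) are applied.

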