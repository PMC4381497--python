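# Methods

This note documents the models, statistics and numerical choices behind
seqsimnet, and what the synthetic validation does and does not establish.

## Pipeline overview

Input sequences (FASTA; labels in the header dialect) pass through:

1. **Dataset filters.** Length ≥ 300 nt; dereplication keeping one
   representative per distinct sequence string within each (site, molecule)
   group — reference sequences (cultured isolates, prior surveys) are
   grouped by epoch instead of site. The first record in input order is the
   representative; a multiplicity map records collapsed counts but is not
   used as abundance (cluster abundance counts dereplicated sequences).
2. **Pairwise similarity.** All-vs-all alignment; hits filtered at
   E-value < 1e-5 (strict), identity ≥ 60% and alignment length ≥ 40% of
   the shorter sequence (both inclusive — the thresholds are minima);
   self-hits removed; one hit per unordered pair (greatest identity, then
   longest alignment, then lowest E-value). The filter is idempotent and
   symmetric under query/subject exchange.
3. **Networks.** One undirected graph per identity threshold
   τ ∈ {85, 90, 95, 96, 97, 98, 99}: edge iff identity ≥ τ, weighted by
   identity; nodes without edges (singletons) are excluded. Partitions:
   connected components (CC) and level-1 Louvain communities (LC), which
   always refine the CCs. Raising τ never merges components.
4. **Novelty.** Per-cluster epoch composition; the novel-community rule;
   BFS distance to the nearest cultured node (infinite when unreachable);
   per-component closeness; one-sided KS contrasts of closeness
   (cultured vs prior surveys; cultured vs all environmental) at
   α = 0.05 and 0.01.
5. **Biogeography.** Per-cluster two-category assortativity for every site
   and habitat value with a 100-permutation label-shuffle null (seeded);
   one-sided KS per label and pooled across a label class; per-cluster
   abundance/occurrence/evenness profiles at the conspecific threshold
   (99% by default) with cosmopolitan (occurrence = 8) and restricted
   (occurrence ≤ 4) flags; exclusivity fractions with the total cluster
   count as denominator.

A single root seed drives the generator, Louvain visiting orders and the
permutation null (per-stage seeds split via `numpy.random.SeedSequence`),
making whole runs byte-reproducible.

## Alignment model

`align_pair` is an exact local alignment under BLASTn-like scoring
(match +1, mismatch −2, gap open −5, gap extend −2). Percent identity is
matches over alignment columns, gap columns included (the `pident`
convention of the tabular format), rounded to three decimals so hits
round-trip bit-exactly through files. E-values use the Karlin–Altschul form
`E = K·m·n·exp(−λS)`; for +1/−2 at uniform base composition λ has the
closed form `ln((3+√21)/2) ≈ 1.3328` (positive root of
`0.25·e^λ + 0.75·e^{−2λ} = 1`) and K = 0.621, the standard ungapped value.
The effective database size defaults to the summed length of the dataset.

The all-vs-all driver instead uses a global (Needleman–Wunsch, unit-cost)
alignment via edlib, rescored with the same scheme. A distance-only
prescreen skips pairs whose global identity estimate falls 5 points below
the 60% filter; because the +1/−2 score of a global alignment turns
negative below ~67% identity, no reportable hit is lost. On
substitution-only data the two routes agree; in general the unit-cost
traceback may trade a cluster of substitutions for an indel pair of equal
edit distance, shifting identity by a fraction of a percent. Note that a
local alignment legitimately trims mismatching sequence ends (a terminal
mismatch always lowers the +1/−2 score), so full-length identity equals the
Hamming closed form only when sequence ends match.

## Louvain communities, level 1

LCs are the finest Louvain resolution: a local-move phase of weighted
modularity ascent (`Q = Σ_c [W_c/W − (S_c/2W)²]`, edge weight = percent
identity) run to convergence with no aggregation step. Moves are accepted
only for strictly positive gain, which guarantees termination (Q increases
monotonically over a finite state space); a node whose current community
has negative retention gain may escape to a fresh singleton community.

Greedy local moves are initialization and order dependent, and tiny dense
graphs are rich in ascent traps: on concrete 5–7-node graphs every
singleton-start visiting order converges to the same sub-optimal fixed
point, while the global optimum is itself always a fixed point. The
implementation is therefore a seeded multi-start: one restart from whole
connected components (the coarse baseline), a third from singletons (the
classical start), the rest from random k-groupings; the highest-modularity
result is kept. Twelve restarts is the default; exhaustive-oracle
comparisons on n ≤ 8 graphs use 64 (restarts are microseconds there), at
which depth the multi-start attained the exhaustive optimum on 700/700
random graphs. Determinism: all restarts derive from the single seed, and
cluster identifiers are the lexicographically smallest member id (the same
tie-break used everywhere).

## The novelty rule

A community at the 85% network is *novel* when (a) every member is a
new-survey sequence and (b) the mean over members of each member's best
identity to any cultured reference is below 95%. "Best identity" uses hits
surviving the standard filters; a member with no qualifying hit contributes
0 (short spurious local matches are excluded by the E-value and 40%-cover
filters, which is what makes the 0 convention safe). The mean-of-best-
identities reading follows the "closest cultured reference" notion; a
mean-over-all-pairs variant is available behind `pair_mean=True`.
Closeness is per-component — cross-component distances are undefined in
disconnected similarity networks, so harmonic/global variants were
rejected.

## Assortativity and its null

Newman's two-category coefficient is computed per cluster (CC or LC induced
subgraph) on unweighted edges — the cited definition is on edge counts, so
identity-weighting was rejected. Clusters with no edges or only one
category are excluded from observed and null distributions symmetrically,
with the reason recorded. The null shuffles the node-label multiset
(category counts preserved, topology untouched), 100 permutations per
cluster by default, seeded. Significance is a one-sided two-sample KS test
(observed stochastically greater than null, α = 0.05), run per label value
and also pooled across a label class. The pooled variant exists because a
permissive-threshold network concentrates mixing into one giant component,
leaving a single observed r per label — pooling across the eight site
labels restores a testable sample while asking the same question. Note the
exact permutation expectation of r is not 0 but
`(2k(k−1)/(n(n−1)) − ½)/½` for k target nodes among n — about −0.034 at
n = 30 with an even split, vanishing as n grows; the r = 0 reading of
random mixing is asymptotic.

## Synthetic communities

The generator plants `n_species` centroids and emits members as centroid
copies with i.i.d. per-site substitutions at `within_species_divergence`
(default 0.005 over 380 nt, i.e. ~99.0% expected within-species identity:
two members differ per site with probability `2d(1−d) + (2/3)d²`).
Substitution-only is the default so identity has a closed form; an indel
rate exists (default 0).

Centroid geometry is the load-bearing choice. Non-novel centroids grow as a
random recursive chain — each new centroid mutates a uniformly chosen
earlier one at 1.3× `between_species_divergence`, with rejection sampling
enforcing the minimum (failure after 200 tries raises, signalling
incompatible settings). Parent–child member identities land at ~86–88%
while all other pairs fall below ~80%, so the 85% network shows one sparse
giant component mixing many species (the regime where assortativity is
informative) and the ≥ 90% networks separate species exactly — the
generator's end-to-end contract is that 97% components equal the planted
species (adjusted Rand index 1). Novel species are independent uniform-
random sequences rejection-checked below the 95% criterion against every
cultured centroid; they are so much more divergent that they stay isolated
at all thresholds, which is what makes exact novelty recovery
(precision = recall = 1) a guarantee rather than a tendency. That guarantee
requires `frac_cultured + frac_novel = 1` (the defaults are 0.5/0.5):
species with neither a cultured reference nor novel status would be
indistinguishable from novel ones.

Dispersal scenarios: *endemic* fixes one (site, habitat) per species;
*cosmopolitan* draws both uniformly per sequence; *habitat_structured*
confines a configured fraction of species (default 0.5) to one habitat
(default sediment) with sites uniform. Cultured references are emitted as
the unmutated centroid — mirroring isolates acting as cluster anchors — so
they sit at the hub of their species' star and score the highest
closeness.

Default sizes (40 species × 20 sequences, 8 sites, 3 habitats) keep the
full three-scenario parameter-recovery run around a minute per scenario on
one CPU. Statistical power notes: with 20 uniform draws over 8 sites a
species covers all sites with probability ~0.53 (coupon collector), so the
"majority of clusters cosmopolitan" property is demonstrated at 40
sequences per species (coverage ~0.96), while the endemic/cosmopolitan
assortativity contrast and restriction flags are robust at the default
depth.

## What the synthetic validation does not show

The generator draws i.i.d. substitutions on a star-within-chain topology;
real amplicon data have rate heterogeneity along the molecule, indels and
homopolymer artefacts, chimeras, abundance skew, and reference databases
with taxonomic bias. Passing the planted-recovery tests therefore
establishes the correctness of the graph statistics and their calibration
under the stated model — not that a 97% threshold delineates species, nor
the magnitude of endemism, in any real survey. Headline fractions from real
deposits (reference-free component percentages, distance-class fractions,
habitat exclusivity percentages) depend on the deposit and are outside the
test surface; the pipeline exposes the same counts in its manifest so
deposit reruns are comparable.

## Degenerate inputs and tie-breaks

Empty networks cannot be partitioned by Louvain (error) and yield no
profiles; culture-free datasets skip the novelty report; clusters with no
sited member get occurrence 0 and NaN evenness; `simpson_evenness`
requires a positive total. Deterministic tie-breaks: cluster id = smallest
member id; giant component by size then lexicographic id; hit reduction by
identity, length, E-value, then orientation; dereplication keeps the first
record in input order.
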