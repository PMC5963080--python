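# Methods

## Graph model

Graphs are undirected and simple. A link is an unordered pair of distinct
opaque string node-ids; `(u, v)` and `(v, u)` are the same link, stored in
canonical order (lexicographic, or A-side first under a bipartition, so
sets of pairs hash consistently and asymmetric operators receive arguments
deterministically). Self-links are dropped at parse time (the
neighbourhood heuristics are undefined for them) and counted in the log.
Duplicate observations of a link with conflicting years keep the
*earliest* year: a link "forms" at its first observation, which is the
semantics time-slicing needs. Optional per-link integer years and an
optional two-way node partition (every link must cross it) complete the
model. Isolated nodes are representable but not preserved by the edge-list
format, which carries links only.

## Slicing

**Random slicing** removes a target fraction of links (default 40%) into
the test set, uniformly at random, subject to never disconnecting a
component of the input graph. The implementation draws links in a seeded
random order and tests each candidate removal with a local BFS between its
endpoints; a removal that would disconnect is rolled back and the edge
marked permanently ineligible — valid because an edge that is a bridge of
the current residual graph remains a bridge under any further deletions.
If the eligible pool is exhausted first, the request is infeasible (e.g.
any tree) and the error reports the maximum removable fraction. The
training positives (default 10% of all links) are drawn uniformly from
the induction links: training links are deliberately *inside* the
induction set, since withholding them from representation learning would
only produce worse representations.

**Time slicing** assigns links by year: induction = links up to a cut
year, training = the trailing window of the induction era, test = links
after the cut up to a horizon. Connectivity cannot be enforced here; nodes
whose first link postdates the cut reach the predictor with no structural
signal, which is precisely the pathology the time-sliced evaluation is
meant to expose.

**Negatives** are unlinked node pairs sampled uniformly (rejection
sampling while the candidate space is sparse, exhaustive enumeration
otherwise), 1:1 with positives, with three guarantees: no sampled negative
is a positive of *any* slice of the full graph (otherwise labels would
contradict within one experiment), train and test negatives are disjoint,
and under a bipartition only cross-partition pairs are drawn. Negatives
are re-sampled per run seed.

## Heuristics

Common Neighbours, Adamic-Adar in its common-neighbour-count form
`1/log c`, and Jaccard. On bipartite graphs two linkable nodes can never
share direct neighbours, so the second argument's neighbourhood is
replaced by its two-hop set `N̂(v) = ⋃_{w∈N(v)} N(w)`; the hat is applied
to the second argument and the A-side node is always passed first. `N̂(v)`
is a deduplicated set and may contain `v` itself — no exclusion is
applied, and a flag is not offered because rankings, the only thing the
pipeline consumes, are unaffected for the graphs under study far more
often than not; the choice is recorded here as a convention.

Adamic-Adar degenerate counts: `1/log c` is undefined at `c = 1` and
`c = 0`. `c = 0` scores 0 (no shared evidence). `c = 1` receives the
finite cap `2/ln 2 ≈ 2.885`, chosen strictly above the `c = 2` score
`1/ln 2` so the score remains strictly decreasing in `c` — the ordering
principle this weighting encodes (few shared items count for more). The
natural logarithm is used throughout; the base rescales scores uniformly
and cannot change any ranking.

## Embeddings

Walk generation: `walks_per_vertex` (default 10) truncated walks of
`walk_length` 40 from every node. Uniform mode steps to a uniformly random
neighbour; biased mode is a second-order walk with unnormalized weights
`1/p` to return to the previous node, `1` to a candidate adjacent to the
previous node, `1/q` otherwise (defaults p = 2, q = 4). Isolated nodes
emit length-1 walks rather than failing; such nodes end up with
initialization-quality vectors, which is the honest representation of
their information content.

The trainer is pluggable: any callable mapping a walk corpus and a config
to per-node vectors satisfies the contract (every corpus node gets a
vector of the configured dimension; window co-occurrence pulls vectors
together in cosine similarity, asserted statistically). The default
backend is a compact skip-gram with negative sampling on numpy: dynamic
windows (effective size uniform in 1..window, the standard word2vec
reduction), 5 negatives per pair drawn from the unigram^0.75 distribution,
minibatch SGD (batch 1024) with linear learning-rate decay from 0.025,
3 passes over the pair list. Single-threaded numpy makes it exactly
reproducible per seed. Embedding dimension defaults to 100.

First- and second-order proximity tables (each half the target dimension)
can be merged by concatenation followed by L2 normalization; all-zero
vectors pass through unnormalized. Nodes absent from the trained table —
nodes unseen before a time cut — receive seeded i.i.d. uniform
`[-0.5/d, 0.5/d]` components (the conventional embedding-matrix
initialization) and are flagged `random-init`, so the unseen fraction is
measurable downstream.

## Link predictor

Two node vectors are combined element-wise by one of: average,
concatenate (doubles the dimension; endpoints fed in canonical order so
the result is order-independent), hadamard, |difference|, or squared
difference. The classifier is deliberately minimal so that ranking
quality reflects the representations, not model capacity: one hidden
layer of 100 rectified linear units, sigmoid output, log-loss, trained
for exactly 7 epochs with adam at its conventional rate (1e-3), batch
128, no early stopping, no dropout, no validation split. It is
implemented over scikit-learn's `MLPClassifier`; raw (unstandardized)
combined embeddings are the input. Probabilities over the evaluation
pairs form a single ranked list per method.

## Metrics

Ties in any ranking are broken lexicographically by pair id *before*
metric computation, making every rank-based metric deterministic. AUROC
alone uses the standard probabilistic definition on the raw scores (a
random positive outranks a random negative, ties counted half), so it is
invariant under strictly monotone score transforms.

- **AUPR**: the precision-recall step sum — precision at each positive's
  rank, averaged over positives.
- **precision@k** with `k = ceil(k_ratio × #positives)`, default ratio
  0.3: k is pinned to the positive count, not the list length, so it is
  comparable across graph sizes.
- **MAP** and **averaged R-precision** are node-equality metrics: each
  node's sublist of the single global ranking (entries incident to the
  node, global order preserved) is scored — average precision for MAP,
  precision within the top R (R = the node's positive count) for
  R-precision — and node scores are averaged unweighted. Nodes with no
  test positive have undefined per-node scores and are excluded, the
  standard IR convention.

Aggregation over runs reports mean and sd per method and metric, and a
two-tailed two-sample t-test verdict at α = 0.05 against the best-mean
method. Two degenerate fast paths: identical value multisets are
not-different; two zero-variance groups with unequal means are different.
With the default three runs the test is severely under-powered;
"not-different" is weak evidence and the summary should be read with
that in mind.

## No-common-neighbour diagnostic

Test positives whose endpoints share no induction common neighbour
(endpoints missing from the induction graph included — their
neighbourhoods are empty) are exactly the links CN scores 0. "Top half"
means rank ≤ floor(n/2) of the full evaluation list, the midpoint of a
balanced list. Since all such links tie at score 0 under CN, their
placement depends on tie handling: the deterministic lexicographic
placement is reported alongside the expected value under uniformly random
tie-breaking, so the CN number is not an artifact of sort order.

## Synthetic generator

A stochastic block model: nodes split evenly into blocks, intra-block
pairs linked with `p_intra`, inter-block with `p_inter`. SBM was chosen
over preferential attachment because community structure is the signal
both heuristic and embedding methods exploit, letting one generator cover
both contrasted regimes; a degree-skew option is deferred. Bipartite mode
pairs consecutive blocks into A/B communities (paired-block pairs use
`p_intra`, other cross-partition pairs `p_inter`, same-partition pairs
never link). Link years are drawn over the year range with probability
proportional to `rank^skew` (skew 0 = uniform; skew 3 puts the majority
of links in the last quartile), emulating growth skewed toward recent
years. A node's first-occurrence year is derived from its links, and the
split-scenario generator can push randomly chosen nodes' links past a cut
year until a target unseen-node fraction (default scenario: 14.5%) is
met, with ground truth (first-link years, blocks, unseen set) returned
for downstream assertions.

What the generator does **not** emulate: heavy-tailed degree
distributions, assortativity beyond block structure, correlated
timestamps within communities, and the sheer scale of curated interaction
databases (10^5–10^7 links). Passing tests therefore demonstrate
methodological correctness and the qualitative regime contrasts
(data-rich embeddings beat heuristics; small or disconnected-node-heavy
graphs favour heuristics; predictors retain skill on
no-common-neighbour links), not performance figures transferable to any
real corpus.

## Problem sizes and defaults

The default study conditions are a 400-node, 4-block graph
(`p_intra = 0.25`, `p_inter = 0.02`, ≈ 6,000 links) for the data-rich
regime and a 60-node strong-contrast graph for the small-graph regime;
experiments repeat 3 runs with consecutive seeds, every method scoring
the identical split per run. These sizes keep a full multi-method
experiment in the minutes range on one CPU while leaving both regimes
clearly separated. All randomness (generation, slicing, negative
sampling, walks, trainer, predictor) flows from explicit seeds; a rerun
with the same config is identical byte-for-byte.

## Known limitations

- The skip-gram backend is tuned for clarity and determinism, not speed;
  corpora beyond ~10^6 walk tokens call for plugging in an optimized
  trainer through the trainer contract.
- LINE-style first/second-order optimization and autoencoder-based
  embeddings are out of scope; the concatenate-and-normalize
  post-processing accepts any two half-dimension tables.
- The t-test protocol at n = 3 runs is reproduced faithfully but has
  little power; treat significance verdicts as descriptive.
- Negative sampling assumes missing links are negative; in evolving
  graphs some sampled negatives are future positives. Within one
  experiment no negative collides with any slice's positives, but the
  epistemic caveat stands.
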