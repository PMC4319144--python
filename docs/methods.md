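# Methods

This note documents the models, estimators and numerical conventions
behind `mhealthscape`, and what the synthetic corpus does and does not
show about real app-store data.

## Dictionary tagging

Tagging is exact multi-pattern matching: the description is case-folded
(`str.casefold`, so non-ASCII text is handled) and tokenized on `\w+`
word runs; a corpus surface string matches iff its own token sequence
occurs consecutively in the description's token sequence. Consequences
of this convention:

* any run of non-word characters acts as a word boundary ("drug" never
  matches inside "drugstore", but matches "drug;" or "drug-safe");
* multi-word phrases match across arbitrary separators ("heart-rate"
  matches the phrase "heart rate");
* overlapping matches all fire ("heart rate" and "heart" both count);
  deduplication happens at the tag level, so two synonyms of one tag
  contribute a single distinct tag.

No stemming or fuzzy matching is applied — determinism and
auditability are worth more here than recall, and the inclusion filter
(at least `k_min = 4` distinct tags, configurable) is calibrated for
this matcher. Matching is implemented with a first-token index over
the corpus (single words by dictionary lookup, phrases by n-gram
comparison); the test suite checks it against an independent
per-pattern regex scan.

Only descriptions are scanned; titles are not. Whether titles should
contribute tags is a genuinely open design point, but descriptions are
where the functionality vocabulary lives, and mixing in titles would
entangle the inclusion filter with title length.

## Shared-tag graph

Vertices are included apps; the edge weight between two apps is the
size of their tag-set intersection (≥ `min_shared`, default 1). Weights
are the default because they preserve strictly more information than
binary co-occurrence; an `unweighted` switch collapses weights to 1
for sensitivity runs. No self-loops exist at this stage. GraphML is
the exchange format (lossless for vertices, edges and integer
weights); a 3-column TSV edge list is available for quick inspection.

## Modularity and Louvain

Modularity follows the weighted Newman–Girvan definition; the
implementation uses the per-community form
Q = Σ_c [W_in(c)/m − (K_c/2m)²]. The trivial all-in-one partition
scores exactly 0; an edgeless graph has undefined modularity and is
reported as 0 with a warning.

The Louvain optimizer is implemented in this package rather than
delegated, so that every nondeterministic choice is pinned:

* vertices are visited in a seed-shuffled order (NumPy `default_rng`);
* a vertex moves to the neighbouring community with the largest
  strictly positive modularity gain; among equal gains (within 1e−12)
  the lowest community id wins;
* one pass = local moving until no vertex improves, then aggregation
  of communities into super-vertices (internal weight appears as a
  self-loop with A_cc = 2·W_in so degrees are conserved);
* passes repeat until a pass improves Q by less than 1e−9;
* the returned Q is recomputed from scratch on the input graph, and a
  `validate` mode cross-checks the incremental bookkeeping against
  from-scratch recomputation after every accepted move.

No resolution parameter is used — plain modularity. Cluster ids are
canonicalized (contiguous from 0, ordered by each cluster's smallest
member app id) so runs are comparable. For graphs of ≤ 10 vertices an
exhaustive oracle enumerates all set partitions (restricted-growth
strings, Bell-number bound) and returns the global optimum with a
deterministic lexicographic tie-break; the test suite holds Louvain to
this optimum on disjoint-clique graphs. Recovery of planted structure
is scored with the adjusted Rand index.

## Inter-rater agreement (Janson–Olsson ι)

Ratings live on K nominal variables (here the five characteristics).
The distance between two ratings is the fraction of variables on which
they differ. The implemented estimator is

* D_obs: mean distance over all objects and unordered pairs of
  distinct judges rating the same object;
* D_exp: mean distance over all ordered pairs of distinct objects
  crossed with all ordered pairs of distinct judges;
* ι = 1 − D_obs/D_exp.

The published literature admits several estimator variants (pair
weighting, same-object handling); this one is fixed, documented and
verified against a brute-force double-loop oracle to 1e−12. With this
variant, perfect agreement gives ι = 1 and two judges who each rate
constantly but disagree everywhere give ι = 0. If every rating in the
matrix is identical, D_exp = 0 and ι is undefined; it is reported as 1
with a degenerate-data warning. Characteristic levels are treated as
nominal — no ordinal weighting — because the assessment scheme defines
categories, not scores.

## Archetype consolidation

After adjudication there is exactly one resolved assessment per
informative cluster; clusters with identical five-characteristic
vectors form one archetype. Archetypes are numbered in ascending
severity order of the signature — specificity first
(standard < nonstandard < medical), then leaks, change, loss, value
(none < low < high) — which reproduces the ordering of the bundled
reference taxonomy. Descriptors are optional human-supplied labels;
they are never computed. Uninformative clusters are excluded before
assessment and never enter percentage denominators.

## Rating statistics

Per-store summaries report mean/median/SD of the 5-star mean over
rated apps and the fractions unrated, rated < 10 times, rated > 1000
times, and (among rated apps) ≥ 4 or ≤ 2 stars. The two-store
comparison uses the Mann–Whitney rank-sum statistic, reported for the
first-named group (orientation is a convention and is fixed here),
with a tie-corrected normal approximation without continuity
correction, and effect size r = |z|/√n. The rating-count/download
association is the Spearman correlation between rating count and the
ordinal rank of the download bracket. Rendered percentages use
half-up decimal rounding at the printed precision (1 decimal for
cluster shares, 2 for app shares); full precision is retained
internally.

## Synthetic corpus: what it emulates

Generator defaults are calibrated to the marginal statistics of the
2013 store snapshot that motivated the pipeline:

| parameter | default | rationale |
|---|---|---|
| `n_apps` | 2000 | default study size; large enough for stable recovery |
| `store_weights` | iOS 0.8995 / Android 0.1005 | 8.95 : 1 store imbalance |
| `noise_fraction` | 0.3448 | share of listings failing the 4-tag filter |
| `archetype_count` | 8 | planted cluster structure |
| `tags_per_archetype_pool` | 12 | pool size vs. 4–8 tags per app |
| `tags_per_app_min/max` | 4 / 8 | uniform; non-noise apps always pass the filter |
| `pool_overlap_fraction` | 0.1 | connects the graph; clustering stays non-trivial |
| `unrated_probability_by_store` | iOS 0.7576 / Android 0.4237 | zero inflation |
| `rating_count_tail_params` | iOS (3.77, 1.99) / Android (1.72, 2.69) | log-normal (μ, σ) solved from the published fractions rated < 10 and > 1000 times |
| `rating_mean_params_by_store` | iOS (3.1, 1.01) / Android (3.7, 1.08) | target mean/SD of the 5-star mean |
| `download_ratio_log_mean/sd` | ln 50 / 0.5 | downloads-per-rating multiplier; σ chosen so the count/band Spearman sits near 0.9 |

Two modelling choices deserve a note. Rating counts are zero-inflated
log-normal: the published record gives only the unrated fractions and
the tail shares, and solving the log-normal parameters from the < 10
and > 1000 quantiles reproduces both. Rating means are drawn from a
Beta distribution rescaled to [1, 5] and moment-matched to the target
mean/SD; a truncated normal cannot reach the Android pair (at mean 3.7
the maximum achievable SD on [1, 5] is ≈ 1.03 < 1.08), while the
scaled Beta matches both stores' first two moments exactly.

Noise apps carry 0–3 planted tags from the whole tag universe (always
below the default inclusion threshold) and sometimes an empty
description; non-noise apps embed one randomly chosen synonym of each
planted tag, on intact word boundaries, amid filler text from a fixed
non-health vocabulary. Because surface strings contain digits and the
filler list does not, the tagger recovers planted tags exactly — a
deliberate construction that turns tagging into a testable identity.

What the generator does **not** emulate: real description language and
length, correlated tag usage within archetypes beyond pool membership,
store-specific category idiosyncrasies, temporal dynamics, or rating
behaviour conditional on app quality. Passing the planted-recovery
suite therefore shows that the pipeline is correct and well-calibrated
under its stated model — not that real store data would cluster this
cleanly. On real data the shared-tag graph is far denser and noisier;
published analyses of comparable snapshots report modularity near 0.5
and hundreds of clusters, whereas the planted corpus yields Q ≈ 0.74
and exactly the planted cluster count.

## Degenerate inputs and numerical conventions

* Empty description → empty tag set (no error).
* `k_min = 0` → every app included.
* Edgeless graph → singleton partition, Q = 0 with a warning.
* Louvain move acceptance margin 1e−12; pass convergence 1e−9;
  incremental-vs-scratch tolerance 1e−9; ι oracle tolerance 1e−12.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configuration and seed
  regenerate byte-identical corpora and identical partitions.

## Problem sizes used by the automated runs

The test and acceptance runs use the default 2000-app corpus for
clustering/recovery, a 5000-app corpus for rating calibration, ≤
10-vertex graphs for the exhaustive oracle, and 50 random 24-vertex
graphs for the Louvain trace invariants. These sizes give stable
statistics (binomial 99% acceptance intervals, ARI well above the 0.8
threshold) while keeping a full run in the order of seconds.
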