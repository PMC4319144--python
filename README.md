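# mhealthscape

Tag-based clustering and privacy-risk archetype analysis of
mobile-health (mHealth) app-store listings.

## The problem

App stores offer tens of thousands of health-related apps — medication
reminders, fitness trackers, symptom checkers, health records — that
differ enormously in what personal information they touch and in what
an information-security or privacy failure would cost their users.
Store listings (title, category, free-text description, rating
metadata) are the only scalable evidence about an app's functionality,
so landscape analyses of this kind proceed in stages:

1. **Tagging.** A curated tag corpus maps surface strings in
   descriptions ("medication", "pharmaceutical", "drug", "heart rate")
   to normalized tag labels. Descriptions are scanned with exact,
   case-insensitive, word-boundary matching; apps matched by fewer
   than four distinct tags (typically non-English or non-health
   listings) are excluded.
2. **Graph clustering.** Apps become vertices of an undirected graph;
   an edge joins two apps that share tags, weighted by the shared-tag
   count. Clusters are found by Louvain modularity optimization, where
   modularity is

   *Q* = (1/2m) Σ<sub>ij</sub> [A<sub>ij</sub> − k<sub>i</sub>k<sub>j</sub>/2m] δ(c<sub>i</sub>, c<sub>j</sub>)

   with A<sub>ij</sub> the edge weights, k<sub>i</sub> the weighted
   degrees and m the total edge weight.
3. **Assessment.** Human raters score each informative cluster on five
   nominal characteristics: health **specificity** of the information
   available to the apps (standard / nonstandard / medical) and
   potential damage through **leaks**, **change** (manipulation),
   **loss** of information, plus the **value** of the information to
   third parties (each none / low / high). Inter-rater agreement is
   quantified with Janson–Olsson ι, a multivariate extension of
   Cohen's κ: ι = 1 − D<sub>obs</sub>/D<sub>exp</sub>.
4. **Archetypes.** Clusters with identical five-characteristic vectors
   are consolidated into archetypes — a compact taxonomy of the
   privacy-risk landscape — and aggregated into characteristic-level
   summary tables.

Because no store snapshot of this kind is freely redistributable, the
package ships a seeded synthetic-corpus generator with planted
archetype/tag structure and realistic rating metadata (store imbalance,
zero-inflated heavy-tailed rating counts, per-store rating
distributions, download brackets coupled to rating counts), so the
entire pipeline is testable end to end and every reported number is
recomputable from scratch. A bundled reference archetype table from a
2013 iOS/Android store survey drives worked-example aggregation tests.

## Worked example

```python
from mhealthscape import *

config = GeneratorConfig(seed=7)          # 2000 apps, 8 planted archetypes
records, truths, corpus = generate_corpus(config)

assignments = tag_records(records, corpus)           # dictionary tagging
included, excluded = filter_min_tags(assignments)    # >= 4 distinct tags
print(f"{len(records)} apps discovered, {len(excluded)} excluded by tagging")

graph = build_graph(included)                        # shared-tag graph
print(f"graph: {graph.number_of_nodes()} vertices, {graph.number_of_edges()} edges")

partition, trace = louvain(graph, seed=13)           # modularity optimization
print(f"{partition.n_clusters} clusters, Q = {partition.q:.3f} in {trace.n_passes} passes")

truth = {t.app_id: t.planted_archetype for t in truths if t.app_id in partition.assignment}
print(f"planted-archetype recovery (ARI): {recovery_score(partition, truth):.3f}")
```

prints

```
2000 apps discovered, 673 excluded by tagging
graph: 1327 vertices, 152969 edges
8 clusters, Q = 0.742 in 2 passes
planted-archetype recovery (ARI): 1.000
```

673/2000 ≈ 34% of apps fail the four-distinct-tag filter (the planted
noise fraction), the Louvain optimizer converges in two passes, and the
recovered clusters match the eight planted archetypes exactly (adjusted
Rand index 1.0). The same chain is available from the shell:

```sh
mhealthscape run --seed 7 --out-dir out/
```

which writes the records (JSON Lines), tag corpus (TSV), assignments
(CSV), graph (GraphML), partition (CSV + JSON sidecar) and rating
reports into `out/`.

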