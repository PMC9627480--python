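# Methods

## Scope and data model

The pipeline reconstructs a tissue miRNome as a gene interaction network
and analyses it in five stages: network assembly, topology, hub
identification, term over-representation, and knockout-phenotype
cross-tabulation. Its inputs are four local tables — miRNA→target
predictions with a 0–100 score, gene–gene interactions with a combined
confidence, flat term→gene annotations, and gene→phenotype records. No
remote database is queried; identifier mapping between naming systems is
out of scope (identifiers are taken as given, matched case-insensitively
with the first-seen capitalization preserved).

## Filters and assembly

* **Target score:** strictly `> 90`. The boundary is deliberately
  exclusive and pinned by tests; a pair scoring exactly 90 is dropped.
* **Interaction confidence:** `>= 0.700` after dialect normalization.
  Interaction databases export both 0–1 reals and 0–1000 integers; any
  value above 1 in the column switches the whole column to the 0–1000
  reading (divide by 1000). Normalization is idempotent and a column that
  normalizes outside [0, 1] is rejected as a dialect mix. A
  `confidence_strict` option switches the cutoff to `>`.
* **Duplicates:** duplicate unordered interaction pairs are collapsed to
  their maximum confidence *before* filtering, so a low-confidence
  duplicate cannot shadow a qualifying one. Duplicate target rows are kept
  at read time (they carry distinct miRNA provenance) and deduplicate
  naturally at assembly.
* **Assembly:** nodes are the distinct filtered target genes; edges are
  filtered interactions with both endpoints in the node set; self-loops
  are dropped. miRNAs become per-gene provenance rather than nodes — the
  published node/component counts of networks built this way are only
  consistent with a gene-only graph in which non-interacting targets stay
  isolated. An exploratory bipartite mode (miRNA nodes with miRNA→gene
  edges) exists but is not part of the analysis path.

The main component is the largest connected component; ties break toward
the component containing the lexicographically smallest gene, and all
orderings (components, hub lists, tables) are deterministic so reruns are
byte-identical.

## Topology conventions

* **Shortest paths** are counted over ordered pairs (n, m), n ≠ m, with
  finite distance — a connected N-node graph reports exactly N(N−1) pairs
  and 100%. The characteristic path length is the mean distance over those
  pairs; the diameter is the maximum finite distance, which keeps it
  defined on disconnected networks. Edgeless networks report zero paths
  and an undefined (NaN) path length.
* **Clustering** uses the standard Watts–Strogatz
  C_i = 2n_i/(k_i(k_i−1)); the network value averages over nodes with
  k ≥ 2 (the convention of the widely used network-analysis desktop
  tools), with an `all_nodes` mode that counts k < 2 nodes as zero.
* **Degree distribution:** histogram over k ≥ 1 with degree-0 nodes
  tallied separately and excluded from fitting (log k is undefined at 0
  and isolated nodes carry no attachment information).
* **Power-law fit:** OLS of log₁₀ count on log₁₀ k over positive-count
  bins, no binning and no k_min cutoff; γ is the slope. R² is the
  determination coefficient of that log-log regression. R is reported as
  the Pearson correlation between observed counts and the fitted a·k^γ on
  the original scale; the two statistics are therefore on different scales
  by design and R² need not equal R². Maximum-likelihood tail fitting and
  formal model comparison are out of scope — the regression convention is
  the one the reported quantities are defined by.
* **Hierarchy:** mean clustering per degree C(k) (k ≥ 2, C(k) > 0) is
  regressed on k in log-log space; the network is called hierarchical when
  the fit's R² reaches a configurable cutoff (default 0.5). Fewer than two
  usable points yields an explicit indeterminate verdict. Degenerate
  regressions with zero response variance report R² = 1 when residuals
  vanish (a constant explained exactly) and 0 otherwise.

## Hubs

ND > μ + σ with population σ (divide by N): the degree sequence is the
complete population of the analysed network, not a sample from one.
`sample_sd=True` flips to the (N−1) convention and `inclusive=True` to
≥ — on a k-regular graph the strict rule correctly yields no hubs while
the inclusive rule yields all nodes. Hubs are computed on the main
component by default. On heavy-tailed networks of ~1,700 nodes the rule
marks a few percent of nodes (about 5% on the synthetic
preferential-attachment component, versus roughly 10% reported for real
miRNome components, whose degree variance is higher); the fraction is a
property of the degree distribution and is reported, not targeted.

## Enrichment

Upper hypergeometric tail P[X ≥ k] per term (population = background
universe, successes = term genes in the universe, draws = hub genes in the
universe), computed through the survival function in log space; exact
against exhaustive enumeration for populations up to 12 in tests.
Benjamini–Hochberg adjustment across all tested terms at α = 0.05.
Defaults: the universe is the annotated subset of the network's nodes
(options: all annotated genes, or a user list); terms need ≥ 2 universe
genes (`min_term_size`, set to 1 to test singletons); only
over-representation is tested. Hub genes outside the universe do not count
toward the sample size — pinned by test. Because hypergeometric p-values
are discrete, the realized type-I rate at p ≤ 0.05 sits below nominal;
calibration tests assert the upper bound.

## Phenotype cross-tabulation

Free-text phenotype terms are classified into reproductive-system and
embryo categories by case-insensitive keyword matching (families shipped
in `data/keywords.yaml`; first listed category wins on a double match;
explicit record categories always override). The classified records are
joined with the hub list into one table per category, sorted by degree
descending, plus the set of genes in both. The package ships
`data/ko_phenotypes.tsv`, a 21-gene reference cross-tabulation (11
reproductive-system, 13 embryo, 3 shared genes, top gene at 93 links) used
as a fixture; its free-text disease columns are carried opaquely as notes.

## Synthetic data

The generators produce inputs whose ground truth is known, at the scale
the analysis assumes:

* **Target table:** 60 miRNAs × Uniform{180..270} targets drawn without
  replacement per miRNA from a 20,000-gene pool (a mouse-genome-sized
  universe), scores Uniform(50, 100). A fraction 0.2 passes the >90
  filter, leaving ≈ 2,700 retained pairs over ≈ 2,500–2,600 distinct genes
  — the scale of the real filtered network. An integer-score mode
  exercises the strict boundary at exactly 90.
* **Connectivity:** 65.5% of the filter-passing genes are wired into one
  planted component; the remainder stay isolated. The default model is
  hand-grown preferential attachment — initial clique of m+1 nodes
  (default m = 2), each new node attaching m degree-proportional edges —
  giving a connected graph with exactly m(n−m−1) + C(m+1, 2) edges,
  deterministic per seed. An Erdős–Rényi G(n, p) null model is available
  for contrast.
* **Interaction table:** true edges get confidence Uniform(0.700, 0.999),
  decoy non-edges (1× the edge count by default) Uniform(0.150, 0.699),
  so the 0.700 filter recovers the planted graph losslessly; pipeline
  recovery is asserted end-to-end.
* **Annotations:** 40 background terms of 5–60 genes sampled uniformly;
  planted terms over-sample the planted component's hubs at 20:1 odds.
* **Phenotypes:** one record per hub gene with terms drawn from the two
  category keyword families plus neutral templates
  (0.2/0.25/0.55 reproductive/embryo/other).

What the generators do **not** emulate: real miRNA target multiplicity
(shared targeting across miRNA families), the mid-sized components real
interaction layers produce besides singletons (synthetic isolates are all
size 1), annotation term overlap structure, and correlated
phenotype/connectivity effects. Passing tests therefore demonstrate the
pipeline's correctness and the recoverability of planted structure, not
biological conclusions about any real tissue.

## Problem sizes and determinism

Tests and the acceptance script run graphs up to 2,665 nodes (the
published full-network size), 20-replicate fit recoveries at n = 2,000,
200-graph oracle sweeps on ≤ 30-node graphs and 500-replicate null
simulations for FDR control — sizes chosen so the whole suite completes in
well under a minute while the statistical assertions keep comfortable
margins. Every stochastic step takes an explicit seed; one generator call
owns one RNG stream and no global state is used.

## Known limitations

* No ontology propagation: annotations must arrive pre-propagated.
* No statistical test of scale-freeness against alternatives (lognormal,
  exponential); the regression slope is descriptive.
* The keyword classifier is transparent but crude; a curated category
  column always overrides it and is the recommended path for real data.
* Identifier normalization is casefolding only; cross-namespace mapping
  (symbol ↔ Ensembl) must happen upstream.
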