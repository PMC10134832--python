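# Methods

This note defines every statistical and algorithmic convention used in
`magcat`, in the order a typical analysis runs.

## Gene catalogue

Genes are predicted per assembly contig and named `<contig>_<n>`; the
contig is recovered by splitting on the last underscore. A nonredundant
catalogue is the output of greedy sequence clustering in the `.clstr`
dialect: blocks start with `>Cluster N`, each member line carries the
gene length and id (truncated at `...`), and exactly one line per block
ends in `*`, marking the representative (centroid). Clusters partition
the gene set; `magcat` enforces this on construction.

Functional annotation is performed at the centroid level and propagated
to all cluster members, following the standard nonredundant-catalogue
convention. Annotation rate as a function of cluster size
(`annotation_rate_by_cluster_size`) profiles whether rare genes are
systematically darker.

## GO DAG, information content, informative terms

Only `is_a` edges are used. Upward propagation closes a term set over
ancestors; it is idempotent and monotone. Given a reference corpus of
*n* proteins where term *i* annotates *nᵢ* proteins after propagation,
the Shannon information content is

    IC(i) = −log₂(nᵢ / n)   [bits].

Propagation guarantees a child never exceeds its parent, so IC is
monotone non-decreasing from root to leaf.

A term is **informative at threshold k** (default k = 2000) when its
propagated count is strictly greater than k and every proper
descendant's count is strictly less than k. A term with count exactly k
satisfies neither side. The selected set is an antichain (no member is
an ancestor of another), giving a rank-free cross-section of the
ontology at comparable specificity. `filter_informative` projects any
annotation set onto this antichain: each gene's terms are propagated
upward and intersected with the informative set, keeping the maximum
contributing score.

## Annotation channels and score thresholds

Structure-based predictions arrive as (gene, GO term, confidence) rows;
confidence ≥ 0.2 is the standard-quality threshold and ≥ 0.5 the
high-quality threshold (both inclusive; rows below the active threshold
are dropped at read time). Orthology-mapper annotations arrive one row
per gene with the GO terms comma-packed in one column (`-` = none) and
a free-text description column; GO calls from this channel carry no
score and are recorded at 1.0. Duplicate (gene, term, method) rows keep
the maximum score.

## Concordance stratified by information content

To compare two annotation channels at matched specificity, each gene's
propagated term set from each channel is assigned to integer IC levels
(`floor(IC)`; terms without IC go to an `unbinned` bucket). Within each
level, each gene in the level's universe falls into exactly one
category:

- **concordant** — both channels place terms at this level and the term
  sets intersect;
- **discordant** — both do, and the sets are disjoint;
- **unique_a / unique_b** — only one channel reaches this level.

Categories therefore partition every level's gene universe. A looser
`level_only` mode counts reaching the same level as agreement
regardless of which terms. Two- and three-way Venn region counts over
annotated gene sets are provided by `annotation_venn`.

## Abundance

Per-sample per-gene read counts are normalized to counts-per-million in
two modes:

- `paper_raw`: CPM = c × 10⁶ / total_reads, where total_reads is the
  sample's sequencing depth (row sums to 10⁶ × mapped fraction);
- `length_rescaled` (default): rate = c / L per gene, rescaled so each
  sample's row sums to exactly 10⁶.

Function-level abundance sums gene CPM over all genes carrying a term;
a multi-term gene contributes fully to each of its terms. The annotated
fraction of a sample is the percentage of its total CPM carried by
annotated genes.

## MAG quality, taxonomy, pangenomes

A MAG is **nearly complete** when completeness ≥ 90 and
contamination < 5 (CheckM conventions; the completeness bound is
inclusive, the contamination bound exclusive). GTDB taxonomy strings
(`d__;p__;c__;o__;f__;g__;s__`) are parsed with lower ranks blanked
below the first empty rank. Genes map to MAGs through
(sample, contig) membership; cluster-level taxonomy sharing counts the
distinct species (or genus) labels among a cluster's members' MAGs,
using only MAGs with contamination < 5.

A species qualifies for a reference-free pangenome when it has ≥ 10
nearly complete MAGs. Its presence matrix marks each catalogue cluster
present/absent per MAG; a cluster is **core** when present in ≥ 90% of
the MAGs (inclusive), else **accessory**. Accessory clusters found in
any other species' pangenome are **shared**, the rest **unique**
(a stricter `accessory_only` mode requires presence in another species'
*accessory* set). Pangenome size is summarized against MAG count with a
Pearson correlation (scipy).

## Synthetic communities with planted truth

The generator (`magcat.synth`) plants every quantity the analyses
estimate:

- a fixed 20-term molecular-function toy ontology with propagated
  counts over a corpus of 100,000, chosen so the informative set at
  k = 2000 is known (4 terms) and all 8 annotation leaves share IC
  level 7;
- per species, a core pool and an accessory pool of gene clusters;
  accessory carrier counts are drawn strictly below the 90% core
  threshold, so with zero dropout and contamination the core/accessory
  partition is exactly recoverable. Core genes are present in each MAG
  with probability 1 − d (dropout d), so core recovery follows the
  binomial tail P(Binom(m, 1−d) ≥ ⌈0.9 m⌉);
- two annotation channels over cluster centroids with a planted
  agreement probability (default 0.7), recoverable as leaf-level
  concordance;
- per-sample Poisson read counts, length-proportional with lognormal
  per-species factors; optionally adjusted by exact integer arithmetic
  so annotated genes carry a planted share of each sample's counts.

A truth manifest records all planted values; a fixed seed yields
byte-identical fixture files (SHA-256 manifest included). Test oracles
compare every analysis against either this truth or a brute-force
reimplementation.
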