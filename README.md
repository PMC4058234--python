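# multirank

Consensus differential expression for RNA-seq read-count matrices.

No single count-based test is uniformly best: methods that model counts as
negative binomial (NB) differ mainly in how they stabilize the per-gene
dispersion estimate, and on real data — especially when a gene's counts
vary wildly within a group — they can disagree sharply about the same
gene. `multirank` runs three NB engines with deliberately contrasting
dispersion philosophies, ranks every gene by each engine's raw
significance score, and reports the **per-gene rank sum** as a consensus
statistic: a gene that every engine places near the top of its list gets a
small rank sum, regardless of how the engines' absolute p-values are
calibrated. The package is aimed at analysts with a gene × sample count
matrix and a two-group design who want DE calls that are robust to the
choice of test.

## The model

Counts are modeled as NB with mean μ and dispersion α, Var = μ + αμ².
For a two-group comparison the package provides:

- **`deseq_like`** — median-of-ratios size factors; per-gene dispersion is
  the *maximum* of the method-of-moments estimate and a fitted
  dispersion–mean trend α(μ) = a₀ + a₁/μ (conservative);
- **`edger_like`** — TMM (trimmed mean of M-values) effective library
  sizes; the per-gene dispersion is *moderated toward* the trend by a
  weighted combination with a fixed prior weight;
- **`bayseq_like`** — empirical Bayes model comparison between a
  shared-mean NB model and a group-specific-means model, with an
  empirically sampled prior over parameter tuples and model weights
  estimated by iterated expectation. It reports 1 − P(DE | data) instead
  of a p-value and, being a model-comparison method, no fold change.

The first two engines share a two-sided exact test conditional on the
pooled count: p is the probability, under the NB model, of all splits of
the total no more probable than the observed split. Raw scores are
ranked (average ranks on ties) and summed:

    rank_sum(g) = Σ_m rank_m(g)

Benjamini–Hochberg FDR adjustment accompanies every engine, but ranking
uses raw scores because adjusted values tie in long runs.

Before testing, a QC stage checks the data from three angles: per-sample
total-count normalization (counts per ten million by default) with
distribution summaries, average-linkage hierarchical clustering of
samples on Spearman distance — repeated after keeping only the top 10%
and 5% of genes by coefficient of variation, which exposes samples whose
apparent grouping is driven by uninformative genes — and batch-effect
tests (Kruskal–Wallis and Fligner–Killeen) on machine/run/flowcell/lane
factors parsed from Illumina read names.

## Worked example

```bash
python examples/consensus_analysis.py
```

simulates a 3 vs 3 study (1000 genes, 10% DE at |log2FC| = 2), runs all
three engines and prints:

```
top 10 genes by consensus rank sum (smaller = stronger agreement):
  gene_00269  rank_sum=    6.0  truth=DE
  gene_00908  rank_sum=   10.0  truth=DE
  gene_00922  rank_sum=   12.0  truth=DE
  ...
10/10 of the top consensus genes are truly differentially expressed in the simulation truth.
report written to scratch/report.html (+ scratch/report.tsv)
```

The rank sum runs from 3 (first by every engine) to 3 × n_genes; the TSV
table lists, per gene, each engine's log2 fold change (empty for
`bayseq_like`), raw score, FDR score and rank, with the rank sum in the
last column. The HTML report adds dendrograms per CV filter, boxplots,
the sample correlation matrix, the three-way Venn of significant genes, a
scalable volcano plot (dot size = consensus rank), a top-gene heatmap and
pairwise engine-concordance scatter plots.

The other examples each exercise one capability:
`cv_filtered_clustering.py` (misclassified-sample detection),
`batch_effect_detection.py` (lane-effect testing from read names),
`adjusted_count_normalization.py` (the per-sample adjusted-count
arithmetic on a worked immunoglobulin gene).

Command-line use mirrors the library:

```bash
multirank simulate --out counts.csv --truth truth.tsv --seed 5
multirank run --counts counts.csv --groups 0,0,0,1,1,1 --out report.html --seed 5
```

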