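# Methods

This note documents the statistical procedures implemented in
`multirank`, the choices made where the design was genuinely open, and
what the simulation-based tests do and do not demonstrate.

## Input model and scope

The atomic datum is a nonnegative integer read count per (gene, sample).
All inference assumes a two-group design encoded as a 0/1 vector aligned
with the matrix columns; each group needs at least two samples (three are
recommended and a warning is raised below that). Multi-factor designs,
isoform-level quantities and FPKM-style length-normalized measures are
out of scope. Genes with zero counts in every sample are excluded before
testing and ranking — they carry no evidence either way — and the
exclusion count is recorded in the report provenance.

## Normalization

Two distinct normalizations serve two distinct purposes:

- **Display/QC normalization**: value(g, s) = count(g, s) / total(s) ×
  C with C = 10⁷ (counts per ten million) by default, overridable.
  Every column then sums to C. An integer-rounded (half-up) view exists
  for tabular display. All display transforms use log2(x + 1); the
  pseudocount avoids undefined logs at zero counts.
- **Testing normalization**: per-sample size factors with geometric mean
  1. The `deseq_like` engine uses median-of-ratios factors (median over
  genes positive in all samples of count / per-gene geometric mean). The
  `edger_like` engine uses TMM: the reference sample is the one whose
  upper quartile of count/library-size is closest to the mean upper
  quartile; each sample's log2 ratios to the reference are doubly trimmed
  (30% on log-ratios, 5% on abundance), averaged with inverse
  asymptotic-variance weights, exponentiated and combined with library
  size into an effective library size.

## Dispersion estimation

Raw per-gene dispersion is method-of-moments on size-factor-normalized
counts: α(g) = max(0, (pooled within-group variance − mean) / mean²).
A parametric trend α(μ) = a₀ + a₁/μ is fitted by nonnegative least
squares to genes with positive raw dispersion (fewer than 10 such genes
triggers a flat median-dispersion fallback with a warning). The final
value is mode-specific:

- `deseq_like`: final = max(raw, trend at the gene's mean) — never less
  conservative than either source;
- `edger_like`: final = (G₀ · trend + d · raw) / (G₀ + d), with prior
  weight G₀ = 10 equivalent residual degrees of freedom (exposed as a
  parameter) against the design's residual df d = n − 2.

The parametric trend was chosen over local regression deliberately: with
the small designs this package targets (3–6 samples per group) a local
fit has little data per window, and the 1/μ form captures the dominant
shot-noise component. On simulations with constant true α = 0.2
(2000 genes, 3 vs 3) the median final dispersion lands near 0.2 under
both rules; Poisson data yield medians below 0.05.

## The exact NB test

Both p-value engines test each gene conditionally on its pooled count.
Counts are first equalized: divided by the size factor and rounded
half-up ("pseudo-counts"). Group sums A and B are modeled as NB with
means n_a·μ and n_b·μ and dispersions α/n_a and α/n_b (the sum of n iid
NB(μ, α) variables); the two-sided p-value adds the probabilities of all
splits of the total no more probable than the observed one (log-scale tie
tolerance 10⁻⁸), normalized by the total probability of the conditioning
event. α = 0 reduces exactly to the binomial split of a Poisson total; a
zero total returns p = 1. The implementation enumerates all splits with
vectorized log-pmf arithmetic; tests verify exact agreement with an
independent brute-force enumeration for all totals ≤ 30 over a dispersion
grid.

Log2 fold changes are log2((mean₁ + 0.5) / (mean₀ + 0.5)) on normalized
counts; the 0.5 pseudocount keeps near-zero groups from producing
unbounded fold changes.

## The empirical Bayes engine

`bayseq_like` compares two models per gene: M₀ (one NB mean shared by
all samples) and M₁ (group-specific means). Parameters are never fitted
per gene at test time; instead an empirical prior is built from a seeded
random subset of up to `n_prior_samples` (default 1000) expressed genes,
each contributing a tuple (overall mean, group means, dispersion) from
method-of-moments fits. Each model's marginal likelihood for a gene is
the average NB likelihood over the prior tuples; the model prior weight
is estimated by iterating the expected membership (EM on a two-component
mixture, tolerance 10⁻⁴, ≤ 100 iterations). The per-gene score is
1 − P(M₁ | data); the estimated-FDR column is the running mean of these
scores down the posterior-sorted gene list.

Two calibration choices matter and were fixed after a design-time variant
comparison on the generator's standard conditions:

- **Tuple dispersions come from the total variance about the shared
  mean**, not the within-group variance. The shared-mean model must
  account for between-sample-mean noise as ordinary NB noise; estimating
  α within groups systematically understated M₀'s tolerance and let the
  richer model absorb null fluctuations (the converged DE prior weight on
  fully null data was ≈ 0.19 with within-group α, ≈ 0.02 with total α).
- **M₁ treats its group means as unordered**: its marginal likelihood
  averages both orientations of each tuple, so no direction of change is
  privileged and label swaps leave scores invariant by construction.

The posterior ordering is the engine's deliverable; the absolute
posterior level is less well calibrated than a p-value (on strongly DE
data the estimated DE prior weight overshoots the true DE fraction), which
is one more reason the consensus layer ranks rather than thresholds.

## Rank aggregation

Each engine's genes are ranked ascending by raw score with average ranks
on ties (min-rank is available as an option); the per-gene rank sum over
engines is the consensus statistic, and the output table is sorted by it
with gene-id tie-breaks so runs are bit-reproducible. Mid-ranks were
chosen because the motivation for ranking raw rather than FDR-adjusted
scores is precisely to avoid large tied blocks; the rank-sum is invariant
under any strictly monotone transform of each engine's scores, which the
property tests assert. Per-method weights (default 1) allow a weighted
variant but the plain sum is the documented default.

## QC stage

**Clustering.** Sample dissimilarity is 1 − Spearman ρ (average ranks on
tied counts), robust to the heavy right tail of count data; a sample with
identical counts across all genes has undefined ρ and is reported as an
error. Agglomerative clustering uses average linkage — the conventional
choice for correlation dissimilarities — and is cut at k = 2; samples in
the minority under the best cut-to-group relabeling are flagged
misclassified. The pass is repeated at CV filters {1.0, 0.10, 0.05}
(coefficient of variation = sd(n−1)/mean on raw counts, mean-zero genes
defined as CV 0, ceil(f·n) genes kept, cutoff ties broken by gene id).
CV is computed on raw counts by default, with a normalized-CV option.

**Distributions.** Per-sample five-number summaries of log2(x+1) for raw
and normalized values use linear-interpolation (type-7) quantiles, fixed
for reproducibility, plus the full pairwise Spearman matrix.

**Batch tests.** Machine, run, flowcell and lane are parsed from Illumina
read names (Casava ≥ 1.8 seven-field convention, with the five-field
pre-1.8 fallback; the first parseable name per sample defines its batch
and later disagreements are logged). The tested response is the
per-sample median of log2(normalized + 1) across genes — one number per
sample, compared across factor levels with Kruskal–Wallis (location) and
Fligner–Killeen (scale). A per-gene testing mode was considered and
deferred: with one summary per sample the tests are exactly calibrated
permutation-style nonparametrics, whereas per-gene pooling needs its own
multiplicity handling. Factors need ≥ 2 levels with ≥ 2 samples each;
identical summaries across levels report p = 1 by convention.

## Synthetic data

The generator draws count(g, s) ~ NB(μ_g · lib_s · 2^(lfc_g·group_s) ·
2^(batch shift), α_g) with a log-normal baseline (meanlog 5, sdlog 1 —
median ≈ 150 counts, spanning roughly 10–10⁴), uniform library factors in
[0.7, 1.4], constant or trended dispersion (default α = 0.1, a typical
bulk RNA-seq scale), DE fraction 10% at |log2FC| = 2 with random signs in
the standard labeled study, and a single seed feeding independent
`SeedSequence`-spawned streams per ingredient. Standard study sizes used
throughout the tests: 3 vs 3 samples; 5000 genes for calibration runs,
1000–2000 genes for labeled-recovery runs.

A batch shift is applied to a random 30% of genes (configurable), not to
all genes: a shift common to every gene is exactly removed by total-count
normalization, and real lane/flowcell artifacts are gene-subset
phenomena. With the default fraction, a +2 log2 lane shift moves the
per-sample median of log2(normalized+1) by about −log2(1.9) on the
unshifted majority, which the Kruskal–Wallis test detects with power
≈ 0.97 at 6 + 6 samples.

Two purpose-built scenarios mirror failure modes seen in practice:

- **Noise-dominated clustering**: 97% of genes are biologically flat but
  carry a shared multiplicative "processing signature" (log2-normal, sd
  0.3) in the disease samples *and* one control; 3% are informative
  markers (|log2FC| = 1.8) on which that control is a genuine control.
  Full-matrix Spearman clustering drags the control into the disease
  block; the top-5% CV filter isolates the markers and corrects it.
- **Single-outlier inflation**: a standard 10%-DE study where each DE
  gene has one group-1 count blown up past 10–30× the group's largest
  count. Cross-engine rank concordance is measurably lower than on the
  matched clean study — the regime where a consensus statistic earns its
  keep.

What the simulations do not emulate: gene–gene correlation, GC/length
biases, isoform switching, and sample contamination other than the
constructed scenarios. Passing tests therefore demonstrate internal
correctness and calibration under the stated NB world, not performance
guarantees on arbitrary real data.

## Numerical conventions

- NB parameterized by (mean, α), Var = μ + αμ²; α = 0 handled as Poisson
  throughout (no floor except 10⁻⁶ inside the empirical Bayes tuples).
- Rounding of pseudo-counts and displayed adjusted counts is half-up.
- Raw scores are clipped into (0, 1] (floor 10⁻³⁰⁰ for p-values, 10⁻¹²
  for posterior-based scores) so BH input contracts hold.
- BH adjustment delegates to the standard step-up implementation and is
  cross-checked against a brute-force reimplementation in the tests.
- All report figures are rendered as deterministic inline SVG (fixed
  hash salt, no embedded date); rendering the same bundle twice is
  byte-identical apart from the explicit timestamp field.

## Known limitations

- The engines are faithful-in-spirit reimplementations of three
  dispersion philosophies, not numerical clones of any published
  software; absolute p-values will differ from other tools even when
  rankings broadly agree.
- The exact test enumerates all splits of the pooled count; for very
  deeply sequenced genes (pooled pseudo-counts in the tens of millions)
  this is memory- and time-heavy.
- The bayseq-like FDR column is an estimated Bayesian FDR and should not
  be mixed with the BH columns of the other engines when thresholding.
- Batch testing detects; it does not correct. Detected factors should be
  handled upstream or with dedicated adjustment tools.
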