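# Methods

## Statistical model

Counts are modelled on the log₂-cpm scale. For gene *g* and sample *s*,

    y_gs = log2( (c_gs + 0.5) / (N_s · f_s + 1) · 10^6 )

with library size `N_s`, TMM factor `f_s` and a 0.5 pseudo-count so zero
counts stay finite. Each gene follows a weighted linear model `y_g = Xβ_g + ε`,
`ε_s ~ N(0, σ²_g / w_gs)`, under a group-means design X (one indicator
column per cell subset, or per lineage for the total-ILC-vs-total-Th
comparison). The weights come from the voom mean–variance trend: the
square-rooted residual standard deviations of an unweighted fit are
lowess-smoothed (span 0.5) against average log₂ count, and each
observation's predicted standard deviation enters as `w = sd⁻⁴`.

Residual variances are shrunk by empirical Bayes. The prior
`σ²_g ~ s₀²·d₀/χ²_{d₀}` is fitted by moment matching on `log s²_g`
(di-/trigamma offsets, trigamma inversion by Newton iteration), giving the
posterior `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` and a moderated
t statistic with `d₀ + d_g` degrees of freedom. Two-sided p-values are
BH-adjusted across all genes of one contrast.

Enrichment of a gene set S in a contrast is scored on the list ranked by
decreasing moderated t (ties broken by gene id): members add
`|t|^P / Σ_S |t|^P` (P = 1 by default), non-members subtract `1/(N − N_S)`;
the maximum of the walk is ES_up, the minimum ES_down, both in [−1, 1].
The null redraws the member labels uniformly from the ranked universe
(gene-label randomization, 1,000 draws). NES divides the observed ES by
the *magnitude* of the mean same-direction null ES, and the p-value is the
proportion of null scores at least as extreme in that direction.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| filter threshold | 1 cpm in ≥ 1 sample, inclusive | retains any gene detectably expressed in a single subset/donor |
| TMM trims | 30% on M, 5% on A | the canonical double-trim of the standard implementation |
| voom pseudo-count / denominator | 0.5 / `N·f + 1` | keeps log-cpm finite and nearly scale-invariant |
| lowess span | 0.5 | standard trend smoothing; robust at ~20k genes down to ~300 |
| significance level α | 0.05 (BH-adjusted) | conventional FDR target |
| GSEA weight P | 1 | running sum proportional to \|t\| |
| permutations | 1,000 | p-value floor 1/1001 ≈ 10⁻³ with the add-one estimator |
| PCA genes | top 500 by log-cpm variance, centred, unscaled | focuses on the dominant biological axes |
| d₀ cap | 10⁷ | numerical stand-in for an infinite prior df |

## Synthetic data

The generator emulates the study shape: 6 subsets × 3 donors, ~2,000 genes
at the default desk scale (the analysis it mirrors retains ~20,000; all
properties checked here are scale-free or improve with more genes).
Baselines are log₂-uniform on (1, 9); dispersions gamma with mean 0.1
(`Var = μ + φμ²`); library factors log-normal (sd 0.3 on the natural log);
donor effects are per-(gene, donor) multipliers of sd 0.1 log₂ — small
enough that the default fits need no blocking factor. Ten percent of genes
carry a planted ±2 log₂ effect; half of those are lineage-wide (all three
ILC or all three Th subsets), matching the observation that innate and
adaptive lineages differ globally on top of subset-specific programs.
Planted enriched gene sets draw ≥ 90% of members from genes truly
up-regulated for a target subset or lineage; when the eligible pool is
small the set shrinks rather than diluting below that purity, so the
recorded enrichment truth stays meaningful.

What the simulator does *not* emulate: correlated co-expression modules,
gene-length and GC effects, sample-quality variation, and the long-tailed
signature sizes of real subsets (for example an ILCP-like population with
hundreds of signature genes). Passing tests therefore demonstrate
correctness and calibration of the machinery under a faithful
negative-binomial null, not biological completeness.

## Numerical choices

- **TMM reference sample**: column whose 75th-percentile count proportion is
  closest to the mean; genes with a zero in either compared sample carry no
  ratio information and are dropped pair-wise; factors are rescaled to
  geometric mean 1. Matches the Bioconductor implementation to ~1e-15 (see
  `tests/test_r_crosscheck.py`).
- **Degenerate variance ensembles**: when gene-wise variances have zero
  excess spread the prior df is capped at 10⁷ and every posterior variance
  collapses onto s₀², which equals the common variance up to the O(1/d_g)
  log-scale offset inherent to the moment-matching estimator.
- **Permutation p-values** use the add-one estimator `(1 + extreme)/(1 + n)`
  so no set gets p = 0; the raw proportion is available
  (`GseaConfig(add_one=False)`) for literal replication of the historical
  procedure.
- **Shared nulls**: all sets of one size within one ranked list share a
  null sample (identical by exchangeability of uniform label draws);
  disable with `GseaConfig(shared_null=False)`.
- **NES sign**: dividing by the *absolute* mean of the same-direction null
  preserves the sign of the observed ES, so down-enrichments report
  negative NES.
- **Ties and determinism**: ranked lists break t ties by gene id; PCA signs
  are fixed by making the largest-magnitude loading positive;
  complete-linkage leaf order follows scipy's index-ordered tie-break; one
  global seed fans out to per-stage child seeds by fixed offsets, and the
  run manifest records SHA-256 hashes of every table.
- **Row z-scores** use the sample (n−1) standard deviation; constant rows
  map to 0.

## Design choices

- voom weights are computed once, on the full 6-subset design, and reused
  by the lineage fit; the total-ILC-vs-total-Th comparison is its own
  2-group fit on the same normalized matrix rather than a contrast of the
  6-group model.
- Donors are not modelled as a blocking factor; the generator's donor
  effects are deliberately small, and empirical FDR stays controlled under
  that amount of intra-donor correlation (measured in the acceptance
  suite).
- A subset's signature requires BH-significance *and* a positive estimate
  in all five pairwise comparisons — a conjunction that makes the six
  signatures provably disjoint (asserted at run time).
- lncRNA tables are read out of the genome-wide DE results without
  re-adjusting p-values: the lncRNA set is a fixed annotation-driven
  partition, not a new test family.
- Gene matching between counts, annotation and gene sets is by exact,
  case-sensitive id; unmatched gene-set members are dropped with a logged
  count.

## Problem sizes

The test and acceptance runs use 2,000-gene simulations (300–5,000 where a
specific property needs it), 500 gene sets with 1,000 permutations for the
end-to-end run, 1,000 random sets for null calibration, and 10–20 seeds
for FDR, power and signature-recovery rates. These sizes give stable
rates while keeping a full run of everything in a few minutes on one CPU.

## Known limitations

No donor blocking or duplicate-correlation option; no variance-trend or
robust variants of the empirical-Bayes step; phenotype-label permutation
and leading-edge extraction are out of scope; heatmap/spider rendering is
numeric-only (matrices, not figures).
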