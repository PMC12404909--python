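# Methods

This note records what each stage of `stresshypo` computes, the default
parameter values and why they were chosen, and what the synthetic generator
does and does not emulate. Notation: counts `c_gj` for gene `g` in sample
`j`, library size `L_j = Σ_g c_gj`, two groups (Control / Stressed) of 10
samples each by default.

## Synthetic experiment generator

Counts are drawn gene-wise from a negative binomial with a log-link mean and
quadratic mean–variance relation `Var = μ + φ μ²`.

1. **Baseline means.** Per-gene mean expression is drawn log-uniformly over
   `mean_expression_range` (default 5–500 counts), then multiplied by a
   per-sample library factor drawn uniformly from `lib_size_range`
   (default 0.7–1.3).
2. **Planted differential expression.** `n_de` genes (default 300 of 5000)
   receive a group-dependent shift of `± lfc_de / 2` (default `lfc_de = 1.0`)
   on the log2 mean, split half up / half down with ties toward up. DE genes
   are planted outside modules so that the two kinds of structure can be
   scored independently.
3. **Planted co-expression modules.** Each of `n_modules` modules (default 8,
   sizes uniform in `module_size_range = (30, 120)`) has a per-sample latent
   factor `z_j ~ N(0, 1)` added to the log2 mean with gene loading
   `λ_g = c/√(1−c²) · σ_g`, where `c = module_cor_strength` (default 0.7)
   and `σ_g = √(φ + 1/μ_g)/ln 2` approximates the gene's log2-scale noise
   SD. This makes the expected pairwise correlation within a module ≈ `c²`
   and the gene–eigengene correlation ≈ `c`.
4. **Group-shifted modules.** The first `n_group_shifted_modules` (default 2)
   modules have their latent factor offset by `group_shift` (default 2.0) in
   the Stressed group, with alternating sign across shifted modules so the
   planted group effects are not all in one direction. Because eigengenes are
   computed from standardized expression, the group effect on the eigengene
   scale is approximately the latent shift itself; at `group_shift = 2.0`
   the two-sample comparison at n = 10 + 10 has analytic power ≈ 0.99 at
   α = 0.05, comfortably above the 0.8 design target (`group_shift = 1.5`
   measured ≈ 0.7 and was rejected during calibration — calibrated on the
   power target, not on any test outcome).
5. **Randomness.** A `SeedSequence` spawned from the single `seed` feeds
   three independent sub-streams (structure, latent factors, counts), so the
   planted truth is reproducible under partial regeneration.

Phenotypes are drawn from normal distributions with the published group
means/SDs; non-negative measures are truncated at zero. Daily subjugation
behaviors are drawn for Stressed animals only and left missing for Controls.

Not emulated: raw reads, UMIs, PCR duplicates, mapping artifacts, batch
effects, or anatomically distinct regions (cross-region analyses take
independent replicate matrices).

## Preprocessing

- **Filters.** `filter_min_count` keeps genes with ≥ 10 counts in at least
  one sample (`mode="all"` requires every sample). `filter_prevalence` drops
  genes with fewer than 15 counts in more than 75 % of samples (used before
  network construction).
- **Size factors.** Median-of-ratios: reference is the geometric mean across
  samples over genes positive in all samples; the factor is the median ratio
  to the reference. Requires at least one all-positive gene (filter first).
- **voom-style transform.** `logcpm = log2((c + 0.5) / (L + 1) × 10⁶)`. A
  lowess curve (span 0.5) of the square-root residual SD against mean
  log-count gives per-observation precision weights as the interpolated
  curve value to the power −4, with flat extrapolation beyond the fitted
  range.
- **QC.** Sample PCA on gene-standardized expression flags samples more than
  3× the median distance from the centroid. Marker validation reports
  presence and mean CPM of user-supplied marker genes.

## Differential expression

Per gene, weighted least squares of `logcpm` on intercept + group with voom
weights gives the log2 fold change, its unscaled standard deviation, and the
residual variance `s²` on `n − 2` df.

- **Empirical-Bayes moderation.** The prior `(d0, s0²)` is estimated by
  moment-matching the log residual variances; the excess of `Var(log s²)`
  over the pure-sampling expectation `ψ′(d/2)` is inverted through the
  trigamma function (Newton iteration). If there is no excess variance the
  prior df is infinite (complete pooling). Posterior variance is
  `(d0 s0² + d s²)/(d0 + d)`; the moderated t uses `d0 + d` df. The limits
  are exact: `d0 = 0` gives the ordinary t, `d0 = ∞` a common-variance z.
- **Permutation empirical FDR.** Group labels are shuffled without
  restriction, with replacement, identity not excluded (default 5000
  permutations). For each observed p, `eFDR = (mean over permutations of
  null p-values ≤ p) / (observed p-values ≤ p)`, capped at 1, made monotone
  by a running minimum from the largest observed p downward.
- **Calls.** `up` / `down` require `|log2FC| ≥ 0.2` *and* `eFDR < 0.05`.
- **Cross-region tables.** Over ≥ 2 result tables, a gene called in the same
  direction in ≥ 2 regions is an overlap (direction + region list); a gene
  called up somewhere and down elsewhere is an incongruence; a gene can
  appear in both tables.

## Co-expression network

- **Adjacency.** Signed hybrid: `a_ij = cor(i, j)^β` for positive
  correlations, 0 otherwise; diagonal 0.
- **Power.** Default fixed `β = 6`. `power="scan"` selects by scale-free
  fit: bin the connectivities, regress `log10 p(k)` on `log10 k̄`, fit index
  `R² × (−sign(slope))`. Rule `"paper"` takes the qualifying power
  (fit > 0.8) with minimal mean connectivity, i.e. the largest qualifying β;
  rule `"smallest"` takes the smallest qualifying β. On strongly modular
  synthetic data the `"paper"` rule can pick a large β that crushes
  within-module adjacency, which is why the fixed default is preferred for
  planted-structure work.
- **TOM.** `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 −
  a_ij)`, diagonal 1.
- **Modules.** Average-linkage hierarchical clustering of `1 − TOM`; static
  cut at height 0.995 with minimum module size 30 (labels ranked by size,
  0 = background). The `dynamic_tree` option scans 40 quantile-spaced
  heights and keeps the cut maximizing the number of min-size clusters — a
  deliberate simplification of the full Dynamic Tree Cut algorithm.
- **Eigengenes.** First principal component of the module's
  gene-standardized expression, scaled to unit variance and sign-oriented so
  the mean member correlation is positive; variance explained is the leading
  singular value's share. `kME` is the Pearson correlation of each gene with
  each eigengene; hubs are the top-|kME| members.
- **Group association.** OLS of each eigengene on intercept + group; for a
  binary indicator the coefficient is the group-mean difference and the test
  the pooled-variance two-sample t on `n − 2` df.

## Enrichment

Hypergeometric upper-tail test of the overlap between a query list and each
GMT set, both intersected with the supplied universe; Benjamini–Hochberg
adjustment across tested sets. The query must be a subset of the universe.

## Phenotype statistics

- **Welch t-test** from raw vectors or summary statistics, signed
  Stressed − Control, Welch–Satterthwaite df, Cohen's d with the
  average-variance denominator `√((s1² + s2²)/2)`.
- **Holm** step-down with an explicit family size `m` (which may exceed the
  number of computed tests when they belong to a wider family).
- **Behavior screen.** Spearman correlation of each top-DEG's expression
  with each behavior; pairs with a constant vector are reported as missing
  and do not consume a Holm slot.

## Numerical choices and limitations

- All closed-form WLS/OLS paths exploit the binary design; no iterative
  solvers are used in the DE stage.
- The permutation space at n = 10 + 10 has 2²⁰ label assignments; sampling
  with replacement means small permutation counts carry Monte-Carlo noise in
  the eFDR — the default 5000 keeps this below the decision thresholds, and
  the end-to-end example uses 500 as a documented speed compromise.
- Problem-size defaults (5000 genes; 11 000 genes for the end-to-end
  benchmark) are this package's own desk-scale choices: large enough for the
  asymptotics of the moderation and eFDR machinery, small enough for a
  single CPU and < 8 GiB of memory.
- The generator's NB model has a single dispersion for all genes; it does
  not attempt to match any real library's mean–dispersion trend.
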