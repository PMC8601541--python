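# Methods

This note documents the models, the numerical choices and the limits of
what the package's tests demonstrate.  Notation: the data are an
`n × m` table of counts (samples × OTUs); `x` denotes a closed
(relative-abundance) composition, `X` the clr-transformed matrix.

## Preprocessing chain

Counts are closed per sample, filtered, zero-replaced and
clr-transformed, in that order.

* **Filter.** An OTU is kept iff (a) its relative abundance exceeds
  `min_rel = 5e-5` (strict `>`) in at least one sample, and (b) it is
  present (abundance > 0) in at least `prevalence = 0.5` (inclusive
  `>=`) of the samples of at least one design cell.  Evaluating
  prevalence within cells deliberately keeps taxa specific to one
  experimental group.  Both thresholds are arguments; the boundary
  conventions are unit-tested.
* **CZM zero replacement.** Zeros in sample *i* become
  `δ_i = 0.65 · DL_i`, with the detection limit `DL_i = 1/depth_i` when
  depths are known and the smallest positive part of the row otherwise;
  non-zero parts are multiplied by `1 − z_i δ_i`.  This preserves
  closure exactly and all ratios among originally non-zero parts.  A
  warning is logged if `δ_i` reaches an observed value.  `0.65` and the
  detection-limit rule are arguments.
* **clr** requires strictly positive input (callers must zero-replace
  first); rows of the output sum to zero.  **Scaling** is per method:
  column centering for ASCA and the distance-based tests (Euclidean
  distances are centering-invariant), autoscaling (unit column sd,
  `n−1` denominator) for the 50-50 MANOVA and the rotation tests.
  Constant columns are left centered and logged.

## Design matrices and ANOVA partition

Factors are coded with sum-to-zero contrasts (k levels → k−1 columns);
interactions are element-wise products of parent codings.  Terms are
orthonormalized sequentially after the intercept; columns aliased with
earlier terms (e.g. subjects nested in diet in crossover layouts) are
dropped and logged, so the model matrix always has full rank.

The multivariate partition projects `X` onto each term's subspace.
Sequential (Type I) sums of squares follow model order; partial sums
adjust each term for all others.  Effect size is
`100 · ‖X_t‖²_F / ‖X − x̄‖²_F`.  Conventions per method: ASCA uses
sequential SSQ on centered data, the 50-50 MANOVA partial SSQ on
autoscaled data, PERMANOVA sequential SSQ on the Gower-centred distance
matrix.  For balanced designs all three coincide up to the scaling of
the input; the residual decomposition identity
(`Σ_t SS_t + SS_res = SS_total`) is exact for the sequential partition.

## Permutation testing

All community tests permute sample rows freely (the simplest scheme
valid for the factorial designs handled here; restricted schemes for
blocked designs are out of scope) and use the add-one convention
`p = (1 + #{T_π ≥ T_obs}) / (1 + n_perm)`, so p is never 0; with
`n_perm="exact"` all `n!` orderings are enumerated (n ≤ 8) and p is the
exact tail fraction.  Tie comparison uses a relative tolerance of 1e-9
so exactly tied statistics always count.  The default `n_perm = 999`
makes 0.001 the smallest attainable p.  Statistics: ASCA — the term's
SSQ; PERMANOVA — pseudo-F; ANOSIM — R on ranked distances.

**50-50 MANOVA statistic.** For a term with hypothesis matrix `H` (the
partial projection of `X`) and error matrix `E` (the residual), the
principal components of `M = H + E` are computed; the first `q`
components reaching 50% of M's variance form the test space, the next
`⌈q/2⌉` components are a buffer excluded from the error, and the
remaining tail is pooled into the error sum of squares.  The statistic
is `SSH/SSE` over that split; its null distribution comes from the same
permutation scheme (degree-of-freedom constants cancel).  This is this
package's own variant of principal-component-buffered MANOVA: it is
validated by its contracts — for a single response it reduces exactly
to the permutation distribution of the classical F statistic, and its
type-I error is calibrated on null simulations — not by parity with any
external implementation.

## OTU-level procedures

* **SIMPER.** Contribution of OTU j over between-group pairs (k,l):
  `mean |x_jk − x_jl| / Σ_i (x_ik + x_il)`; contributions sum exactly to
  the mean between-group Bray-Curtis dissimilarity.  The p-value is the
  permutation probability of a larger contribution.  Runs on filtered
  relative abundances (not zero-replaced).
* **Rotation tests.** Per-OTU classical F for one term adjusted for the
  others; raw p from the F distribution.  Familywise-adjusted p-values
  replace the hypothesis directions with random orthonormal frames
  inside the complement of the nuisance space (a rotation test, exact
  under spherical residuals) and apply a step-down max-F adjustment,
  clipped to be ≥ the raw p.
* **PLS-DA / VIP / UVE.** PLS regression (scikit-learn's NIPALS) of a
  ±1 dummy on the effect+residual matrix; `VIP_j² = m · Σ_a SSY_a
  (w_ja/‖w_a‖)² / Σ_a SSY_a`, so mean VIP² = 1.  Component count is
  chosen by 10-fold cross-validated classification error, capped at 5.
  UVE appends one independently permuted copy of every real column,
  takes the maximal noise VIP as threshold, repeats 100 times, and
  flags OTUs above threshold in > 95% of repetitions.  Ranking uses
  |PLS coefficient| (or |first-component ASCA loading| for two-level
  factors).
* **ANCOM.** For every ordered pair (i, j≠i) an F-test of
  `log(x_i/x_j)` on the factor (adjusted for additive covariate terms);
  within OTU i the m−1 p-values are BH-corrected at 0.05 and
  `W_i` counts rejections.  Significance: `W ≥ 0.6·(m−1)` — the cutoff
  of the reference implementation of the method.  A literal
  60th-percentile-of-W variant is available
  (`threshold_mode="percentile"`), but note it flags ≥ 40% of OTUs by
  construction and therefore cannot be specific.
* **Dirichlet Monte-Carlo clr test.** Per sample, 128 compositions are
  drawn from Dirichlet(counts + 0.5), clr-transformed, and per-instance
  per-OTU F-tests computed; the reported statistics are the expected raw
  and expected BH-adjusted p over instances.  As counts grow the
  posterior concentrates and the expected p converges to the
  point-estimate p (tested).
* **NB-GLM.** Median-of-ratios size factors (geometric-mean reference
  over all-positive OTUs, positive-count fallback otherwise); per-OTU
  NB2 GLM with log link and offset, fitted by vectorized IRLS with
  per-OTU deviance step-halving (agrees with statsmodels to |Δz| <
  2e-4); per-OTU profile-likelihood dispersion on a grid, moderated
  toward a parametric trend `α = a₀ + a₁/mean` by log-scale averaging
  (weight 0.5); Wald test of the population-average contrast between
  two factor levels.  Deliberately simplified relative to full
  count-model pipelines: no Cox-Reid adjustment, no outlier
  replacement, no fold-change shrinkage.  Calibration caveat below.
* **Decision thresholds** (defaults): p < 0.01 for SIMPER, rotation,
  Dirichlet-clr and NB-GLM; the W cutoff for ANCOM; >95/100 UVE
  selections for the PLS route.  Community detection uses α = 0.05.

## Simulator

Counts are drawn in two steps per sample: intensities
`λ_j ~ Gamma(shape_jg, rate_jg)` for the sample's design cell g, an
integer urn `K_j = round(λ_j · 10⁶)` (auto-inflated if the depth
exceeds the urn), a depth `N` from the depth sampler, and a multivariate
hypergeometric draw of N items — so every simulated sample's counts sum
to its depth exactly.  Renormalizing intensities is a no-op for the
count distribution (the urn normalizes itself); it is kept so parameter
objects remain interpretable as relative intensities.

Parameters come either from **moment estimation** on a template count
matrix (shape = m²/v, rate = m/v per OTU × group, sample variance
floored at `1e-4 · m²`) or from the **synthetic template**: 507 OTUs,
diet (3 levels) × dose (2), 6 samples per cell, depths LogNormal(mean
5·10⁴, CV 0.25), mean intensities LogNormal(σ = 2.2 ln units; ~4% of
OTUs above 1% relative abundance, the typical gut profile), per-OTU
Gamma shapes LogNormal(median 0.4, log-sd 0.8) — i.e. biological CVs
around 1.6, the degree of overdispersion that moment estimation
recovers from real gut counts.  The four scenarios spike 10 ("few") or
254 ("many") uniformly chosen OTUs by 2^U[3,4] ("low") or 2^U[8,9]
("high") on the first diet level, with no dose effect.

What the synthetic template does **not** emulate: phylogenetic or
co-occurrence correlation between OTUs, abundance-dependent dispersion,
inter-individual subject structure, or sequencing error.  Passing tests
therefore demonstrate correctness of the pipeline and the qualitative
method ordering, not quantitative performance on any real study.

**Compositional spillover.**  Because depth is fixed, spiking OTUs
necessarily depresses every other OTU's relative abundance — strongly
so in the "many"/"high" scenarios (the clr anchor shifts by
`(n_da/m)·E[log2fc]·ln2` ≈ 1.2 ln units in many-low).  Null OTUs then
genuinely change in relative terms, and specificity of the univariate
tests degrades in the many-DA scenarios; this is a property of
fixed-depth compositional data, not an implementation artifact.  With
the synthetic template's (modest, by real-gut standards) dispersion the
spillover is detectable, so measured TNRs in the many scenarios sit
below what noisier real-data templates produce.

**Ratio bias.**  Mean realized relative abundances are
`E[λ_j/Σλ]`, not `λ̄_j/Σλ̄`; at high dispersion these differ by several
percent for dominant OTUs.  The moment-recovery tests therefore use
low-dispersion templates, where the bias is within Monte-Carlo error.

## Evaluation harness

TPR = TP/P and TNR = TN/N against the simulation truth (TPR undefined
and reported as missing when P = 0; OTUs removed by the filter count as
not-called).  Rank agreement uses Spearman correlation of evidence
ranks — rank 1 = strongest evidence, polarity harmonized (p ascending,
W and |coefficient| descending) — with average ties.  The
abundance-dependence diagnostic is the Spearman correlation between
evidence rank and log10 mean relative abundance.  Seeds derive from the
master seed by counter-based spawning keyed on (scenario, dataset), so
adding methods or scenarios never perturbs existing simulation streams;
per-dataset method failures are recorded and the run continues.

Problem sizes: the package's own study runs 30 datasets per scenario
for the community tests, 10 per scenario for the full OTU battery, 200
null datasets (40 OTUs, 24 samples) for community calibration and 30
(60 OTUs) for the OTU-method calibration, with 999 permutations
throughout (199 in the calibration runs, where only the 0.05 tail
matters).

## Known limitations

* The NB-GLM Wald test is anticonservative here (~0.11 empirical type-I
  error at nominal 0.05 on null simulations, and equally so when given
  the simulator's true dispersions): a small-sample property of plug-in
  NB Wald tests under heavy overdispersion, consistent with published
  benchmarking of count-model tools on microbiome data.  Its p-values
  should be read as rankings rather than calibrated error rates.
* ANCOM's W saturates when a large fraction of OTUs is differentially
  abundant (log-ratios change for every pair), so its power collapses in
  the many-DA scenarios — the known >25%-DA limitation of the method.
* No mixed/random-effect models: subject effects enter as fixed blocks.
* ANOSIM handles a single factor only; it is run on the combined-factor
  labels, and its "effect size" column is 100·R, not a variance share.
* No rarefaction, no alr/ilr transforms, no phylogeny-aware distances,
  no BIOM/RData input (export to TSV/CSV/XLSX first).
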