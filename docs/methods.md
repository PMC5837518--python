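# Methods

## Scope and pipeline order

`grex` implements a summary-statistic pipeline for genetic risk score
(GRS)-by-exposure interaction on a quantitative trait, in the order the
analysis runs: phenotype preparation → per-SNP interaction regression →
per-SNP meta-analysis across studies → GRS / omnibus combination and
direction enrichment → relative-risk projection. A synthetic multi-study
generator supplies data with the statistical structure the analysis
assumes, so every stage is exercised and validated without
individual-level consortium data.

## Phenotype preparation

The raw phenotype is residualized on an intercept plus covariates by
least squares (thin-QR; a rank-deficient design is rejected naming the
collinear column) and the residuals are mapped through the rank-based
inverse normal transform Φ⁻¹((r − c)/(n + 1 − 2c)). The offset c
defaults to Blom's 3/8 — the common GWAS convention; it is an argument
of `inverse_normal_transform`, since other conventions (c = 0.5, c = 0)
differ only in the extreme ranks. Ties receive average ranks and map to
equal outputs; an all-equal vector is rejected because its ranks are
undefined up to a constant. `prepare_stratified` applies both steps
independently within ever- and never-smoker strata (the replication
design), so each stratum is separately mean-zero and marginally standard
normal; each stratum must exceed the covariate count plus one.

Consequence of the transform: every downstream effect is on the
standardized-phenotype scale, and any statement about "the lowest q of
the population distribution" is invariant to monotone relabelings of the
raw phenotype.

## Per-SNP interaction estimation

The discovery-style model regresses the prepared phenotype on intercept,
dosage G, G × target exposure, and all three smoking main effects (ever,
pack-years, current) at once — the saturated exposure parameterization —
by OLS (statsmodels). Plain OLS standard errors are the default, matching
the practice of the era's consortium GWAS; HC0 robust errors sit behind
`robust=True`. Monomorphic SNPs and collinear designs (e.g. every minor
allele carrier an ever smoker) are rejected per SNP; `fit_all_snps`
records the failure and continues the batch.

The replication-style estimator takes per-stratum additive association
results and approximates the interaction as β̂_ever − β̂_never with SE
√(se²_ever + se²_never). This difference-of-strata Wald approximation
ignores the pack-years and current-smoking adjustments of the saturated
model; the two estimators agree in sign and within sampling error on
shared data with pooled normalization (tested), but the stratified route
is the weaker design and is provided for replication-style inputs only.

## Combining per-SNP statistics

With per-SNP estimates β̂ᵢ, variances σ̂ᵢ², weights wᵢ, and A = Σ wᵢβ̂ᵢ/σ̂ᵢ²,
B = Σ wᵢ²/σ̂ᵢ²: the 1-df GRS interaction chi-square is A²/B, reported with
effect A/B and SE 1/√B — the unique Gaussian summary whose Wald square
equals the chi-square. Unweighted (wᵢ = 1) and marginal-|β|-weighted
schemes mirror the unweighted and weighted risk scores; the panel's
marginal effects are a data input, never re-estimated from the
interaction data. The omnibus statistic Σ(β̂ᵢ/σ̂ᵢ)² on m df is exact for
independent loci; no LD-aware variant is provided (panel SNPs are one
per locus by construction).

Per-study records are pooled per SNP by inverse-variance fixed-effect
meta-analysis with Cochran's Q on k − 1 df. Fixed-effect was chosen
because the reference analysis reports a single combined estimate plus a
Q test and no random-effects model. The order of pooling and combining
is immaterial: meta-then-combine and combine-then-meta both reduce to
Σ_s A_s / Σ_s B_s, an identity asserted exactly (1e-10) in the tests.

Direction enrichment counts negative interaction estimates among m and
reports the exclusive upper binomial tail P(X > k) at rate ½. The
exclusive tail is the package default because it reproduces the
reference headline count's printed p-value (18/26 → 0.0145); the
inclusive one-sided (0.0378) and two-sided (0.0755) tails are computed
alongside and logged, since the field's software varies in convention.
Exact zeros are dropped with a warning before counting.

The 12-cell battery (2 traits × 2 exposures × 3 tests) applies a
Bonferroni threshold of α/12 = 4.2 × 10⁻³ at α = 0.05; missing cells
yield a partial battery with a warning rather than an error.

## Relative-risk projection

The fitted model is projected into P(Y ≤ Φ⁻¹(q) | e, GRS ∈ bin) by
integrating Φ((y_q − μ(g,e))/σ_res) against the GRS density over the
bin, normalized by the bin mass, with μ(g,e) = γ_GRS·g + γ_INT·g·e +
c_ever·e. Numerical choices:

- **GRS scale.** Default f₂ is standard normal, with γ_GRS and γ_INT
  interpreted per GRS standard deviation. An allele-count GRS is
  available via `grs_distribution`: normal by Hardy-Weinberg moments
  (mean Σ2pᵢwᵢ, variance Σ2pᵢ(1−pᵢ)wᵢ²) or the exact pmf by repeated
  convolution of per-SNP {(1−p)², 2p(1−p), p²} (integer weights only).
  For 26 loci the normal and exact quintile boundaries agree within half
  an allele (tested).
- **Composite ever-smoker shift.** c_ever = β_status + β_packyears ·
  (mean pack-years among ever smokers) + β_current · (current fraction
  among ever smokers). This is the mean phenotype offset of an average
  ever smoker implied by the marginal exposure model; with the reference
  coefficients and profile (0.56 ever, 0.15 current, 21 pack-years) it
  equals −0.0760.
- **Residual SD.** σ_res defaults to 1: the phenotype is standardized
  and a 26-SNP GRS explains ≈0.1% of its variance, so the distinction
  between marginal and residual SD is far below the projection's
  precision. Configurable in (0, 1].
- **Independence of GRS and smoking.** f₂(g|e) = f₂(g); no
  gene–smoking-behaviour dependence is modeled.
- **Quadrature.** Adaptive Gauss–Kronrod on the bin with tails truncated
  at ±8 GRS SD and absolute/relative tolerance 1e-10; verified against a
  seeded 10⁷-draw Monte-Carlo simulation of the same generative model to
  within 3 Monte-Carlo SEs in every (threshold, bin, smoking) cell.

With the reference coefficients this projection yields a 26% excess
relative risk (top GRS quintile, 1% threshold) and 18% (bottom
quintile), the package's deterministic acceptance anchors.

## Synthetic data generator

`generate_cohort` draws: genotypes ~ Binomial(2, pᵢ) independently per
locus (Hardy-Weinberg, no LD); ever smoking ~ Bernoulli(0.56); current
status among ever smokers with probability 0.15/0.56; pack-years among
ever smokers ~ Gamma(shape 2) scaled to mean 21 (only the mean is a
study condition; shape 2 gives the right-skewed, zero-bounded shape of
real pack-year distributions); age ~ U(30, 75), sex ~ Bernoulli(0.56)
(female), height normal by sex (163/177 ± 7 cm). The raw phenotype sums
covariate effects, per-SNP main effects (default: the panel's marginal
betas), the three smoking main effects (defaults from the marginal
exposure model: −0.0023 status, −0.0030 per pack-year, −0.040 current),
per-SNP × ever-smoking interactions (default: a common −0.0099 per risk
allele, the fitted GRS-level estimate), and N(0, 1) noise. The
inverse-normal transform is deliberately NOT applied in the generator —
preparation happens downstream, mirroring the analysis order.

`generate_multistudy` derives per-study seeds, sizes (default
1,000–5,000) and jittered smoking profiles deterministically from one
master seed, emulating the between-study heterogeneity of a 19-study
consortium. `generate_summary_stats` is a fast path that draws β̂ᵢ ~
N(β_int,ᵢ, seᵢ²) with seᵢ² = σ²/(n·2pᵢ(1−pᵢ)·p_e(1−p_e)) — the
large-sample OLS variance of the interaction term — for simulation
studies that need thousands of replicates of the combiners without
regressions.

The 26-locus default panel is synthetic (the reference SNP table lives
in a supplement that is not redistributable): frequencies sweep
0.12–0.88 and marginal effects −0.01 to −0.06 per allele on the
standardized phenotype, the magnitude range of reported common
pulmonary-function loci, oriented to the trait-lowering allele.

What the generator does not emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium between loci,
population stratification and other confounding, genotyping/imputation
error, relatedness (the family-based replication design is treated as
unrelated), study-specific covariate policies, and any dependence of
smoking behaviour on genotype.

## Validation design and problem sizes

Statistical properties are validated at sizes chosen to keep Monte-Carlo
error well inside the asserted bands: type-I error of the three
combiners over 2,000 null replicates at n = 10,000 (band 0.040–0.060 at
α = 0.05); CI coverage of a planted common interaction over 200 full
generate→prepare→fit→combine replicates at n = 2,000 per cohort (band
0.91–0.98); power ordering of the 1-df vs m-df test over 400 replicates
per effect size on a −0.005…−0.015 grid. The equivalence between the
summary-statistic combiner and the individual-level GRS regression is
asserted on mean chi-squares across 12 replicates at n = 20,000, because
a single draw's relative difference carries sampling noise of order
2√(m/n) ≈ 7% (the per-SNP regressions omit the other loci, so the two
routes see partly different noise) — larger than the 5% agreement being
asserted, which holds for the tests' means.

## Known limitations

- Interaction effects are planted (and primarily tested) for ever
  smoking; pack-years interactions default to zero but are configurable.
- The stratified replication estimator is an approximation; its
  limitations relative to the saturated model are inherited, not fixed.
- The omnibus and GRS tests assume independent loci; correlated panels
  require external pruning.
- Absolute risk under fixed clinical thresholds (e.g. FEV₁/FVC < 0.70)
  is out of scope: it needs the mapping from the transformed phenotype
  back to raw units, which the rank-based transform discards.
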