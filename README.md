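# grex — genetic risk score × exposure interaction testing

`grex` tests whether an environmental exposure modifies the joint effect of
established trait loci on a quantitative phenotype. The reference
application is gene-by-smoking interaction on pulmonary function
(FEV₁/FVC and FEV₁) in European-ancestry population cohorts: single
SNP-by-smoking interactions are individually weak, but when most
interaction effects share a direction, aggregating them through a genetic
risk score (GRS) yields a far more powerful 1-df test. The package is
aimed at statistical geneticists and genetic epidemiologists working from
consortium summary statistics, and ships a synthetic multi-study
generator so that the full pipeline runs and is validated without access
to individual-level consortium data.

## The model

Per-study phenotypes are residualized on age, age², sex, height (and
optional ancestry/site covariates) and mapped through a rank-based
inverse normal transform (Blom offsets). Per-SNP interactions come from
the saturated OLS model with three smoking exposures (ever/never E₁,
pack-years E₂, current E₃):

    Y ~ β₀ + β_G·G + β_{GE_k}·G·E_k + Σ_{l=1..3} β_{E_l}·E_l

Given per-SNP interaction estimates β̂ᵢ with variances σ̂ᵢ² for m
independent loci and weights wᵢ (wᵢ = 1 for the unweighted GRS, wᵢ =
|marginal βᵢ| for the weighted GRS), the 1-df GRS interaction chi-square
is

    χ²_int = ( Σᵢ wᵢ β̂ᵢ/σ̂ᵢ² )² / Σᵢ wᵢ²/σ̂ᵢ²

with implied effect γ̂_INT = A/B and SE = 1/√B (A, B the numerator and
denominator sums). The m-df omnibus alternative is χ² = Σᵢ (β̂ᵢ/σ̂ᵢ)².
Per-study statistics are pooled by inverse-variance fixed-effect
meta-analysis with Cochran's Q; direction enrichment uses an exact
binomial tail on the count of negative interactions.

The fitted model is projected into public-health terms as the relative
risk, for ever vs never smokers, of a phenotype below a population
quantile q, conditional on the GRS lying in a quantile bin:

    P(Y ≤ Φ⁻¹(q) | e, GRS∈bin) = ∫_bin Φ((y_q − μ(g,e))/σ) f₂(g) dg / ∫_bin f₂(g) dg
    μ(g,e) = γ_GRS·g + γ_INT·g·e + c_ever·e

where c_ever blends the three marginal smoking coefficients with the
cohort smoking profile.

## Worked example

Project the fitted FEV₁/FVC interaction model (GRS main effect −0.0363,
GRS×ever-smoking −0.0099; smoking profile 56% ever, 15% current, 21 mean
pack-years among ever smokers) into excess relative risk of falling in
the lowest 1% of the phenotype distribution:

```python
import math
from scipy import stats
from grex import ExposureProfile, reference_params, relative_risk, sign_enrichment_test

params = reference_params()
profile = ExposureProfile(p_ever=0.56, p_current=0.15, mean_packyears_ever=21.0)
for name, bin_ in [("top quintile", (stats.norm.ppf(0.8), math.inf)),
                   ("bottom quintile", (-math.inf, stats.norm.ppf(0.2)))]:
    cell = relative_risk(params, profile, 0.01, bin_)
    print(f"{name}: P(ever)={cell.p_ever:.4f}  P(never)={cell.p_never:.4f}  "
          f"RR={cell.rr:.3f}  excess RR={cell.excess_rr_pct:.1f}%")
enr = sign_enrichment_test([-1.0]*18 + [1.0]*8)
print(f"sign enrichment: {enr.n_negative}/{enr.n_total} negative, p={enr.p:.4f}")
```

prints

```
top quintile: P(ever)=0.0144  P(never)=0.0114  RR=1.261  excess RR=26.1%
bottom quintile: P(ever)=0.0103  P(never)=0.0087  RR=1.182  excess RR=18.2%
sign enrichment: 18/26 negative, p=0.0145
```

Ever smokers in the top GRS quintile carry a 26% excess relative risk of
a bottom-1% FEV₁/FVC compared with never smokers of the same genetic
background; in the bottom quintile the excess is 18% — the gap between
the two is the fingerprint of the GRS-by-smoking interaction. The
18-of-26 negative interaction estimates are unlikely under a fair coin
(p ≈ 0.014), which is the directional enrichment the 1-df GRS test
exploits.

The command-line pipeline runs end to end on synthetic data
(19 heterogeneous studies, ~57,000 participants, 26 loci, planted common
interaction −0.0099 per risk allele):

```bash
grex --quiet pipeline --seed 1 --out run19
head -2 run19/battery.tsv
```

```
method  exposure  trait     beta_int   ci_low    ci_high    chisq  df  p
uGRS    ever      FEV1_FVC  -0.01266   -0.01758  -0.00774   25.44  1   4.6e-07
```

The unweighted GRS test recovers the planted interaction (CI covers
−0.0099) at high significance even though no single SNP reaches
multiple-testing-corrected significance. Subcommands `simulate`,
`assoc`, `combine`, `replicate` and `project-risk` expose the individual
stages; every run writes a JSON manifest with seeds and file digests.

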