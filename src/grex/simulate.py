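"""Synthetic cohort and multi-study generation.

Emulates the statistical structure the analysis assumes: a consortium of
19 heterogeneous European-ancestry studies totalling ~50,000 adults, 26
independent risk loci, ~56% ever smokers of whom ~27% smoke currently
(15% of the whole cohort), a mean of 21 pack-years among ever smokers,
and a raw quantitative phenotype carrying covariate, genetic main,
smoking main and gene-by-ever-smoking interaction effects plus Gaussian
noise.  The inverse-normal transform is never applied here — phenotype
preparation happens downstream, mirroring the analysis order.

Genotypes are independent Binomial(2, p) dosages under Hardy-Weinberg
equilibrium; no LD, stratification or genotyping error is modelled.
Pack-years among ever smokers follow a Gamma with shape 2 scaled to the
target mean (only the mean is constrained by the design; the shape is a
documented free choice).  Everything is reproducible from a single
master seed; per-study seeds are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .data import (CohortData, ExposureProfile, InteractionStat,
                   ValidationError, VariantPanel, VariantSpec, logger)

#: Default per-allele gene-by-ever-smoking interaction effect planted at
#: every locus (the fitted unweighted-GRS interaction estimate).
DEFAULT_BETA_INT = -0.0099

#: Default smoking main effects (status, pack-years, current), matching
#: the marginal exposure model of the reference analysis.
DEFAULT_EXPOSURE_BETAS = (-0.0023, -0.0030, -0.040)

_PANEL_SIZE = 26


def default_panel(trait: str = "FEV1_FVC", m: int = _PANEL_SIZE) -> VariantPanel:
    """A synthetic risk-locus panel (the consortium's SNP table is not
    redistributable, so loci are invented with realistic frequencies and
    marginal effects, already oriented to the trait-lowering allele).

    Frequencies sweep [0.12, 0.88]; marginal per-allele effects on the
    standardized phenotype range from -0.01 to -0.06, the magnitude scale
    typical of common pulmonary-function loci.
    """
    eafs = np.linspace(0.12, 0.88, m)
    betas = -np.linspace(0.010, 0.060, m)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    variants = []
    for i in range(m):
        ea, oa = alleles[i % len(alleles)]
        variants.append(VariantSpec(
            snp_id=f"rs9{i + 1:04d}", chrom=str(i % 22 + 1),
            pos=1_000_000 + 50_000 * i, effect_allele=ea, other_allele=oa,
            eaf=float(eafs[i]), marginal_beta=float(betas[i]), trait=trait,
        ))
    return VariantPanel(variants=tuple(variants), trait=trait)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one cohort or a multi-study collection."""

    n: int = 50_047
    panel: VariantPanel = field(default_factory=default_panel)
    profile: ExposureProfile = field(default_factory=ExposureProfile)
    beta_g: Optional[np.ndarray] = None          # default: panel marginal betas
    beta_int: Optional[np.ndarray] = None        # default: common -0.0099
    exposure_betas: Tuple[float, float, float] = DEFAULT_EXPOSURE_BETAS
    covariate_betas: Tuple[float, float, float, float] = (-0.004, 0.0, -0.05, 0.004)
    noise_sd: float = 1.0
    seed: int = 0
    n_studies: int = 19
    study_size_range: Tuple[int, int] = (1_000, 5_000)
    packyears_shape: float = 2.0
    study_id: str = "sim"

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        bg = (self.panel.marginal_beta if self.beta_g is None
              else np.asarray(self.beta_g, dtype=float))
        bi = (np.full(len(self.panel), DEFAULT_BETA_INT) if self.beta_int is None
              else np.asarray(self.beta_int, dtype=float))
        if bg.shape != (len(self.panel),) or bi.shape != (len(self.panel),):
            raise ValidationError("effect vectors not aligned to the panel")
        object.__setattr__(self, "beta_g", bg)
        object.__setattr__(self, "beta_int", bi)
        p = self.panel.eaf
        planted = float(np.sum((bg**2 + bi**2) * 2 * p * (1 - p)))
        if planted >= 1.0:
            raise ValidationError(
                f"planted genetic variance {planted:.3f} >= 1 before normalization"
            )


def generate_cohort(config: SimulationConfig) -> CohortData:
    """Draw one cohort from the generative model, reproducibly from seed."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n, len(config.panel)
    prof = config.profile

    genotypes = rng.binomial(2, config.panel.eaf, size=(n, m)).astype(float)

    ever = rng.binomial(1, prof.p_ever, size=n).astype(float)
    n_ever = int(ever.sum())
    current = np.zeros(n)
    packyears = np.zeros(n)
    if n_ever and prof.p_ever > 0:
        idx = np.flatnonzero(ever == 1)
        current[idx] = rng.binomial(1, min(1.0, prof.p_current / prof.p_ever),
                                    size=n_ever)
        shape = config.packyears_shape
        packyears[idx] = rng.gamma(shape, prof.mean_packyears_ever / shape,
                                   size=n_ever)

    age = rng.uniform(30, 75, size=n)
    sex = rng.binomial(1, 0.56, size=n).astype(float)     # 1 = female
    height = np.where(sex == 1, rng.normal(163, 7, n), rng.normal(177, 7, n))
    covariates = np.column_stack([age, age**2, sex, height])
    cov_names = ["age", "age2", "sex", "height"]

    b_age, b_age2, b_sex, b_height = config.covariate_betas
    b_status, b_py, b_cur = config.exposure_betas
    phenotype = (
        b_age * age + b_age2 * age**2 + b_sex * sex + b_height * height
        + genotypes @ config.beta_g
        + b_status * ever + b_py * packyears + b_cur * current
        + (genotypes * ever[:, None]) @ config.beta_int
        + rng.normal(0.0, config.noise_sd, size=n)
    )

    return CohortData(
        sample_ids=[f"{config.study_id}_{i:06d}" for i in range(n)],
        snp_ids=config.panel.snp_ids,
        genotypes=genotypes, ever=ever, packyears=packyears, current=current,
        covariates=covariates, covariate_names=cov_names,
        phenotype_raw=phenotype, study_id=config.study_id,
    )


def derive_study_configs(config: SimulationConfig) -> List[SimulationConfig]:
    """Deterministic per-study configs: derived seeds, sizes and jittered
    smoking profiles emulating between-study heterogeneity."""
    master = np.random.default_rng(config.seed)
    lo, hi = config.study_size_range
    out = []
    for s in range(config.n_studies):
        seed_s = int(master.integers(0, 2**31))
        n_s = int(master.integers(lo, hi + 1))
        p_ever = float(np.clip(config.profile.p_ever + master.normal(0, 0.04), 0.2, 0.9))
        p_cur = float(np.clip(config.profile.p_current + master.normal(0, 0.02),
                              0.02, p_ever))
        mpy = float(max(5.0, config.profile.mean_packyears_ever + master.normal(0, 2.0)))
        out.append(replace(
            config, seed=seed_s, n=n_s, study_id=f"study_{s + 1:02d}",
            profile=ExposureProfile(p_ever=p_ever, p_current=p_cur,
                                    mean_packyears_ever=mpy),
        ))
    return out


def generate_multistudy(config: SimulationConfig) -> List[CohortData]:
    """Independent heterogeneous cohorts, one per study."""
    cohorts = [generate_cohort(c) for c in derive_study_configs(config)]
    logger.info("generated %d studies, %d samples total",
                len(cohorts), sum(c.n for c in cohorts))
    return cohorts


def interaction_se(config: SimulationConfig) -> np.ndarray:
    """Large-sample OLS standard errors of the per-SNP interaction term,
    se_i^2 ~ noise_sd^2 / (n * 2 p_i (1 - p_i) * p_ever (1 - p_ever))."""
    p = config.panel.eaf
    pe = config.profile.p_ever
    denom = config.n * 2 * p * (1 - p) * pe * (1 - pe)
    return config.noise_sd / np.sqrt(denom)


def generate_summary_stats(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    exposure: str = "ever",
) -> List[InteractionStat]:
    """Fast path: draw per-SNP interaction estimates directly from their
    sampling distribution, beta_hat_i ~ Normal(beta_int_i, se_i^2),
    without simulating genotypes or running regressions."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    se = interaction_se(config)
    draws = rng.normal(config.beta_int, se)
    return [
        InteractionStat(snp_id=sid, exposure=exposure, beta_int=float(b),
                        se_int=float(s), n=config.n, study_id=config.study_id)
        for sid, b, s in zip(config.panel.snp_ids, draws, se)
    ]
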