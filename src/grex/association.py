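"""Per-SNP interaction estimation.

Two designs are supported:

* the discovery-style saturated regression on individual-level data,
  ``Y ~ b0 + bG*G + bGE*G*Ek + b1*ever + b2*packyears + b3*current``,
  fit by OLS with the transformed phenotype; and
* the replication-style difference-of-strata approximation, where the
  interaction is inferred as the difference between per-allele effects
  estimated separately in ever and never smokers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import CohortData, InteractionStat, ValidationError, VariantPanel, logger, wald_p
from .phenotype import PreparedPhenotype

EXPOSURE_COLUMN = {"ever": 0, "packyears": 1, "current": 2}


@dataclass(frozen=True)
class SingleSnpFit:
    """Full coefficient set of the saturated single-SNP interaction model."""

    beta0: float
    beta_g: float
    beta_exposures: Tuple[float, float, float]
    beta_int: float
    se_int: float
    target_exposure: str

    def __post_init__(self):
        if not self.se_int > 0:
            raise ValidationError("se_int must be positive")
        vals = (self.beta0, self.beta_g, self.beta_int, *self.beta_exposures)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite coefficient estimate")


@dataclass(frozen=True)
class StratifiedPair:
    """Per-allele association estimates from ever and never smoker strata."""

    beta_ever: float
    se_ever: float
    beta_never: float
    se_never: float
    n_ever: int
    n_never: int

    def __post_init__(self):
        if self.se_ever <= 0 or self.se_never <= 0:
            raise ValidationError("stratified standard errors must be positive")


def fit_single_snp_interaction(
    prepared: PreparedPhenotype,
    cohort: CohortData,
    snp_index: int,
    target_exposure: str = "ever",
    robust: bool = False,
) -> Tuple[SingleSnpFit, InteractionStat]:
    """OLS fit of the saturated single-SNP interaction model.

    The design holds an intercept, the dosage G, the G x target-exposure
    product, and all three smoking main effects.  Plain OLS standard
    errors by default; HC0 robust errors behind ``robust=True``.
    """
    if target_exposure not in ("ever", "packyears"):
        raise ValidationError(f"unsupported target exposure {target_exposure!r}")
    y = np.asarray(prepared.values, dtype=float)
    if y.shape[0] != cohort.n:
        raise ValidationError("prepared phenotype not aligned with cohort rows")
    g = cohort.genotypes[:, snp_index]
    if np.var(g) == 0:
        raise ValidationError(f"monomorphic SNP {cohort.snp_ids[snp_index]}")
    E = cohort.exposure_matrix()
    ek = E[:, EXPOSURE_COLUMN[target_exposure]]
    X = np.column_stack([np.ones(cohort.n), g, g * ek, E])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            f"collinear design for SNP {cohort.snp_ids[snp_index]} "
            f"(e.g. all carriers in one exposure group)"
        )
    res = sm.OLS(y, X).fit(cov_type="HC0" if robust else "nonrobust")
    beta_int = float(res.params[2])
    se_int = float(res.bse[2])
    fit = SingleSnpFit(
        beta0=float(res.params[0]),
        beta_g=float(res.params[1]),
        beta_exposures=(float(res.params[3]), float(res.params[4]), float(res.params[5])),
        beta_int=beta_int,
        se_int=se_int,
        target_exposure=target_exposure,
    )
    stat = InteractionStat(
        snp_id=cohort.snp_ids[snp_index], exposure=target_exposure,
        beta_int=beta_int, se_int=se_int, n=cohort.n, study_id=cohort.study_id,
    )
    return fit, stat


def fit_all_snps(
    prepared: PreparedPhenotype,
    cohort: CohortData,
    panel: VariantPanel,
    target_exposure: str = "ever",
    robust: bool = False,
) -> List[InteractionStat]:
    """Fit every panel SNP, reporting per-SNP failures without aborting."""
    index = {sid: j for j, sid in enumerate(cohort.snp_ids)}
    out: List[InteractionStat] = []
    for v in panel.variants:
        if v.snp_id not in index:
            logger.warning("%s: not present in cohort %s; skipped", v.snp_id, cohort.study_id)
            continue
        try:
            _, stat = fit_single_snp_interaction(
                prepared, cohort, index[v.snp_id], target_exposure, robust=robust
            )
        except ValidationError as exc:
            logger.warning("%s: fit failed (%s)", v.snp_id, exc)
            continue
        out.append(stat)
    return out


def infer_interaction_from_strata(
    pair: StratifiedPair, snp_id: str = "snp", exposure: str = "ever",
    study_id: str = "pooled",
) -> InteractionStat:
    """Difference-of-strata interaction: beta_ever - beta_never with
    pooled standard error sqrt(se_ever^2 + se_never^2)."""
    beta = pair.beta_ever - pair.beta_never
    se = float(np.hypot(pair.se_ever, pair.se_never))
    return InteractionStat(
        snp_id=snp_id, exposure=exposure, beta_int=beta, se_int=se,
        n=pair.n_ever + pair.n_never, study_id=study_id,
    )


def wald_from_ci(beta: float, ci_low: float, ci_high: float,
                 level: float = 0.95) -> Tuple[float, float, float]:
    """Recover (se, z, p) from a symmetric normal confidence interval."""
    if not ci_low < ci_high:
        raise ValidationError(f"inverted CI ({ci_low}, {ci_high})")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    zq = stats.norm.ppf((1.0 + level) / 2.0)
    se = (ci_high - ci_low) / (2.0 * zq)
    z = beta / se
    return se, z, wald_p(beta, se)
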