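"""Phenotype preprocessing: covariate residualization and rank-based
inverse normal transformation (INT).

The discovery design residualizes the raw spirometric phenotype on age,
age squared, sex, height (and optional ancestry axes / site indicators),
then maps residual ranks through the standard normal quantile function.
The replication design applies the same two steps separately within ever-
and never-smoker strata, so each stratum is standard normal on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .data import CohortData, ValidationError, logger

#: Blom rank offset: quantile (r - 3/8) / (n + 1/4), the common GWAS choice.
BLOM_OFFSET = 3.0 / 8.0


@dataclass(frozen=True)
class PreparedPhenotype:
    """Transformed phenotype, optionally with the stratum labels used."""

    values: np.ndarray
    strata: Optional[np.ndarray] = None


def residualize(phenotype_raw: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of the phenotype on covariates plus intercept.

    Raises on a rank-deficient design, naming the collinear column(s).
    """
    y = np.asarray(phenotype_raw, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need n > {k - 1} + 1 observations, got {n}")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
    if bad.size:
        cols = ", ".join(f"covariate {j - 1}" if j else "intercept" for j in bad)
        raise ValidationError(f"rank-deficient covariate design: {cols}")
    # residual = y - X (X'X)^-1 X'y via the thin QR projection
    return y - q @ (q.T @ y)


def inverse_normal_transform(x: np.ndarray, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps average ranks r through Phi^-1((r - c) / (n + 1 - 2c)) with the
    Blom constant c = 3/8 by default, so the output is a monotone function
    of ranks with mean ~0 and variance ~1; ties share a rank and map to
    equal outputs.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("inverse normal transform needs n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in phenotype")
    if np.ptp(x) == 0:
        raise ValidationError("all-equal input: ranks undefined up to a constant")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def prepare(cohort: CohortData, offset: float = BLOM_OFFSET) -> PreparedPhenotype:
    """Pooled preparation: residualize on covariates, then transform."""
    resid = residualize(cohort.phenotype_raw, cohort.covariates)
    return PreparedPhenotype(values=inverse_normal_transform(resid, offset=offset))


def prepare_stratified(cohort: CohortData, offset: float = BLOM_OFFSET) -> PreparedPhenotype:
    """Replication-style preparation within ever/never smoking strata.

    Residualization and the inverse-normal transform are applied
    independently in each stratum, so each is separately mean-zero and
    marginally standard normal.
    """
    ever = cohort.ever.astype(bool)
    out = np.empty(cohort.n, dtype=float)
    c = cohort.covariates.shape[1]
    for label, mask in (("never", ~ever), ("ever", ever)):
        n_s = int(mask.sum())
        if n_s == 0:
            raise ValidationError(f"empty {label}-smoker stratum")
        if n_s <= c + 1:
            raise ValidationError(
                f"{label}-smoker stratum has n={n_s} <= c+1={c + 1}"
            )
        resid = residualize(cohort.phenotype_raw[mask], cohort.covariates[mask])
        out[mask] = inverse_normal_transform(resid, offset=offset)
    logger.info("stratified preparation: %d ever / %d never",
                int(ever.sum()), int((~ever).sum()))
    return PreparedPhenotype(values=out, strata=ever.astype(int))
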