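"""Summary-statistic combiners: risk-score and omnibus interaction tests,
fixed-effect meta-analysis with Cochran's Q, sign-direction enrichment,
and the 12-cell test battery.

The risk-score interaction test aggregates m per-SNP interaction
estimates into a single 1-df chi-square

    chisq = ( sum_i w_i b_i / s_i^2 )^2 / sum_i w_i^2 / s_i^2

where b_i and s_i^2 are the per-SNP interaction estimate and variance and
w_i the risk-score weight.  This equals the Wald square of the implied
risk-score interaction effect A/B with variance 1/B (A and B the
numerator sum and denominator sum above), which is what the result
reports as ``beta_int`` and ``se``.  The omnibus test instead sums the m
per-SNP Wald chi-squares into an m-df statistic, valid for independent
loci.  Both tests need only summary statistics, never raw genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .data import (EXPOSURES, TRAITS, GrsTestResult, InteractionStat,
                   ValidationError, VariantPanel, WeightScheme, logger)


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effect pooled estimate with Cochran's Q heterogeneity test."""

    beta: float
    se: float
    p: float
    k_studies: int
    q_stat: float
    q_df: int
    q_p: float

    def __post_init__(self):
        if self.se <= 0:
            raise ValidationError("pooled se must be positive")
        if self.q_df != self.k_studies - 1:
            raise ValidationError("Q df must be k - 1")


@dataclass(frozen=True)
class SignEnrichment:
    """Count of negative interaction estimates with its binomial tail p."""

    n_total: int
    n_negative: int
    p: float
    p_inclusive: float
    p_two_sided: float

    def __post_init__(self):
        if not 0 <= self.n_negative <= self.n_total:
            raise ValidationError("negative count outside [0, total]")


def _check_stats(stats_list: Sequence[InteractionStat]) -> None:
    if len(stats_list) == 0:
        raise ValidationError("no interaction statistics supplied")
    exposures = {s.exposure for s in stats_list}
    if len(exposures) > 1:
        raise ValidationError(f"mixed exposures {sorted(exposures)}")


def grs_interaction_test(
    stats_list: Sequence[InteractionStat],
    weights: WeightScheme,
) -> GrsTestResult:
    """1-df risk-score interaction test from per-SNP summary statistics."""
    _check_stats(stats_list)
    if len(weights.weights) != len(stats_list):
        raise ValidationError(
            f"{len(weights.weights)} weights for {len(stats_list)} SNPs"
        )
    b = np.array([s.beta_int for s in stats_list])
    var = np.array([s.se_int**2 for s in stats_list])
    w = weights.weights
    A = float(np.sum(w * b / var))
    B = float(np.sum(w**2 / var))
    chisq = A * A / B
    return GrsTestResult(
        method=weights.method_name,
        beta_int=A / B, se=1.0 / np.sqrt(B),
        chisq=chisq, df=1, p=float(stats.chi2.sf(chisq, 1)),
        m=len(stats_list), exposure=stats_list[0].exposure,
    )


def omnibus_test(stats_list: Sequence[InteractionStat]) -> GrsTestResult:
    """m-df omnibus interaction test: sum of per-SNP Wald chi-squares."""
    _check_stats(stats_list)
    z = np.array([s.z for s in stats_list])
    chisq = float(np.sum(z**2))
    m = len(stats_list)
    return GrsTestResult(
        method="omnibus", chisq=chisq, df=m,
        p=float(stats.chi2.sf(chisq, m)), m=m, exposure=stats_list[0].exposure,
    )


def meta_fixed_effect(estimates: Sequence[Tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Cochran's Q.

    ``estimates`` is a sequence of (beta, se) pairs, one per study.
    """
    k = len(estimates)
    if k < 2:
        raise ValidationError("meta-analysis needs at least two estimates")
    b = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValidationError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    return MetaResult(
        beta=pooled, se=pooled_se,
        p=float(2 * stats.norm.sf(abs(pooled / pooled_se))),
        k_studies=k, q_stat=q, q_df=k - 1, q_p=float(stats.chi2.sf(q, k - 1)),
    )


def meta_per_snp(stats_list: Sequence[InteractionStat]) -> List[InteractionStat]:
    """Pool per-study interaction statistics into one record per SNP.

    SNPs observed in a single study pass through unchanged.  Output
    preserves first-appearance SNP order and is tagged ``study_id='meta'``.
    """
    groups: Dict[Tuple[str, str], List[InteractionStat]] = {}
    order: List[Tuple[str, str]] = []
    for s in stats_list:
        key = (s.snp_id, s.exposure)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out: List[InteractionStat] = []
    for key in order:
        grp = groups[key]
        n_tot = int(sum(s.n for s in grp))
        if len(grp) == 1:
            out.append(grp[0])
            continue
        meta = meta_fixed_effect([(s.beta_int, s.se_int) for s in grp])
        out.append(InteractionStat(
            snp_id=key[0], exposure=key[1], beta_int=meta.beta,
            se_int=meta.se, n=n_tot, study_id="meta",
        ))
    return out


def sign_enrichment_test(betas: Sequence[float]) -> SignEnrichment:
    """Enrichment of negative interaction estimates against a fair coin.

    The reported ``p`` is the exclusive upper binomial tail
    P(X > n_negative) = P(X >= n_negative + 1) at rate 0.5; the inclusive
    one-sided and two-sided tails are carried alongside and logged.
    Exact zeros are dropped with a warning before counting.
    """
    b = np.asarray(list(betas), dtype=float)
    n_zero = int(np.sum(b == 0))
    if n_zero:
        logger.warning("dropping %d exact-zero estimates from the sign test", n_zero)
        b = b[b != 0]
    if b.size == 0:
        raise ValidationError("no nonzero estimates for the sign test")
    m = int(b.size)
    k = int(np.sum(b < 0))
    p_excl = float(stats.binom.sf(k, m, 0.5))
    p_incl = float(stats.binom.sf(k - 1, m, 0.5))
    p_two = float(min(1.0, 2.0 * min(p_incl, stats.binom.cdf(k, m, 0.5))))
    logger.info("sign test: %d/%d negative; exclusive p=%.4g, "
                "inclusive p=%.4g, two-sided p=%.4g", k, m, p_excl, p_incl, p_two)
    return SignEnrichment(n_total=m, n_negative=k, p=p_excl,
                          p_inclusive=p_incl, p_two_sided=p_two)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Familywise significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValidationError("need at least one test")
    return alpha / n_tests


def run_test_battery(
    stats_by_cell: Dict[Tuple[str, str], Sequence[InteractionStat]],
    panels: Dict[str, VariantPanel],
    alpha: float = 0.05,
) -> List[GrsTestResult]:
    """uGRS, wGRS and omnibus tests for each trait x exposure combination.

    ``stats_by_cell`` maps (trait, exposure) to that cell's per-SNP
    records; ``panels`` supplies the wGRS weights per trait.  A complete
    input yields 12 results flagged at the Bonferroni threshold
    alpha / 12; missing cells produce a partial battery with a warning.
    """
    n_cells_expected = len(TRAITS) * len(EXPOSURES) * 3
    threshold = bonferroni_threshold(alpha, n_cells_expected)
    results: List[GrsTestResult] = []
    for trait, exposure in product(TRAITS, EXPOSURES):
        cell = stats_by_cell.get((trait, exposure))
        if not cell:
            logger.warning("battery cell (%s, %s) missing; partial battery", trait, exposure)
            continue
        m = len(cell)
        # align wGRS weights to the SNPs actually present in this cell
        mb = {v.snp_id: abs(v.marginal_beta) for v in panels[trait].variants}
        missing = [s.snp_id for s in cell if s.snp_id not in mb]
        if missing:
            raise ValidationError(f"SNPs absent from the {trait} panel: {missing}")
        wgrs = WeightScheme("marginal_abs", np.array([mb[s.snp_id] for s in cell]))
        tests = [
            grs_interaction_test(cell, WeightScheme.unweighted(m)),
            grs_interaction_test(cell, wgrs),
            omnibus_test(cell),
        ]
        for t in tests:
            results.append(GrsTestResult(
                method=t.method, beta_int=t.beta_int, se=t.se, chisq=t.chisq,
                df=t.df, p=t.p, m=t.m, exposure=exposure, trait=trait,
                significant=t.p < threshold,
            ))
    return results
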