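"""Relative risk of low pulmonary function by risk-score quantile.

The fitted risk-score-by-smoking model is projected into the relative
risk, for ever vs never smokers, of falling below a population quantile
of the (inverse-normal transformed, hence marginally standard normal)
phenotype, conditional on the genetic risk score lying in a quantile bin:

    P(Y <= y_q | E = e, GRS in [g_lo, g_up])
      = int_bin Phi((y_q - mu(g, e)) / sigma_res) f2(g) dg / int_bin f2(g) dg

with the conditional mean

    mu(g, e) = gamma_GRS * g + gamma_INT * g * e + c_ever * e

where c_ever is the mean phenotype shift of an average ever smoker,
composed from the three marginal smoking coefficients and the cohort's
smoking summaries:

    c_ever = beta_status + beta_packyears * mean_packyears_ever
             + beta_current * (p_current / p_ever).

By default the GRS density f2 is standard normal (the fitted coefficients
are interpreted on the standardized-GRS scale) and is taken independent
of smoking; an allele-count GRS — normal by Hardy-Weinberg moments or the
exact convolution mass function — is available through
:func:`grs_distribution`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy import integrate, stats

from .data import ExposureProfile, ValidationError, VariantPanel, WeightScheme

#: Integrand tails are truncated this many GRS standard deviations out.
_TAIL_SD = 8.0
_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class GrsDistribution:
    """GRS density: ``normal`` (mean, sd) or ``exact`` integer-count pmf."""

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    values: Optional[np.ndarray] = None
    pmf: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("normal", "exact"):
            raise ValidationError(f"unknown GRS distribution kind {self.kind!r}")
        if self.kind == "normal" and self.sd <= 0:
            raise ValidationError("GRS sd must be positive")
        if self.kind == "exact":
            if self.values is None or self.pmf is None:
                raise ValidationError("exact distribution needs values and pmf")
            if abs(float(np.sum(self.pmf)) - 1.0) > 1e-9:
                raise ValidationError("exact pmf does not sum to 1")

    @classmethod
    def standard_normal(cls) -> "GrsDistribution":
        return cls(kind="normal", mean=0.0, sd=1.0)

    def ppf(self, q: float) -> float:
        """Quantile function (left-continuous inverse CDF for ``exact``)."""
        if self.kind == "normal":
            return float(stats.norm.ppf(q, loc=self.mean, scale=self.sd))
        cdf = np.cumsum(self.pmf)
        idx = int(np.searchsorted(cdf, q, side="left"))
        return float(self.values[min(idx, len(self.values) - 1)])

    def mass(self, lo: float, up: float) -> float:
        """P(lo < GRS <= up)."""
        if self.kind == "normal":
            return float(stats.norm.cdf(up, self.mean, self.sd)
                         - stats.norm.cdf(lo, self.mean, self.sd))
        mask = (self.values > lo) & (self.values <= up)
        return float(np.sum(self.pmf[mask]))


@dataclass(frozen=True)
class RiskModelParams:
    """Fitted model coefficients plus the GRS distribution for projection.

    ``gamma_grs`` and ``gamma_int`` are the GRS main effect and the
    GRS-by-ever-smoking interaction on the transformed phenotype;
    ``beta_status``, ``beta_packyears`` and ``beta_current`` come from the
    marginal exposure model; ``sigma_res`` is the residual SD of the
    phenotype given GRS and smoking (default 1: the risk score explains a
    negligible share of the standardized phenotype's variance).
    """

    gamma_grs: float
    gamma_int: float
    beta_status: float
    beta_packyears: float
    beta_current: float
    sigma_res: float = 1.0
    grs_dist: GrsDistribution = field(default_factory=GrsDistribution.standard_normal)

    def __post_init__(self):
        if not 0.0 < self.sigma_res <= 1.0:
            raise ValidationError("sigma_res must be in (0, 1]")


#: Reference coefficients of the fitted interaction + marginal exposure
#: models for FEV1/FVC (standardized-GRS scale).
REFERENCE_PARAMS = dict(
    gamma_grs=-0.0363, gamma_int=-0.0099,
    beta_status=-0.0023, beta_packyears=-0.0030, beta_current=-0.040,
)


def reference_params(**overrides) -> RiskModelParams:
    """The fitted FEV1/FVC risk model with a standardized-normal GRS."""
    kw = dict(REFERENCE_PARAMS)
    kw.update(overrides)
    return RiskModelParams(**kw)


@dataclass(frozen=True)
class RiskCell:
    """One (threshold, GRS bin) projection entry."""

    threshold_quantile: float
    grs_low: float
    grs_up: float
    p_ever: float
    p_never: float
    rr: float
    excess_rr_pct: float


def composite_ever_effect(params: RiskModelParams, profile: ExposureProfile) -> float:
    """Mean phenotype shift of an average ever smoker vs a never smoker.

    Blends the smoking-status, pack-years and current-smoking
    coefficients with the cohort's smoking summaries (mean pack-years
    among ever smokers; current fraction among ever smokers).
    """
    if profile.p_ever == 0:
        raise ValidationError("composite effect undefined when p_ever = 0")
    return (params.beta_status
            + params.beta_packyears * profile.mean_packyears_ever
            + params.beta_current * (profile.p_current / profile.p_ever))


def _conditional_mean(params: RiskModelParams, c_ever: float,
                      g, ever: int):
    return params.gamma_grs * g + (params.gamma_int * g + c_ever) * ever


def tail_probability(
    params: RiskModelParams,
    profile: ExposureProfile,
    threshold_quantile: float,
    grs_bin: Tuple[float, float],
    ever: int,
) -> float:
    """P(Y below the population ``threshold_quantile`` | smoking, GRS bin).

    The phenotype is marginally standard normal after the rank-based
    transform, so the threshold value is Phi^-1(threshold_quantile).
    Gaussian quadrature over the bin for a normal GRS (tails truncated at
    8 SD, absolute tolerance well below 1e-8); an exact discrete sum for
    an allele-count GRS.
    """
    if not 0.0 < threshold_quantile < 1.0:
        raise ValidationError("threshold quantile must be in (0, 1)")
    lo, up = grs_bin
    if not lo < up:
        raise ValidationError(f"invalid GRS bin ({lo}, {up})")
    y_q = stats.norm.ppf(threshold_quantile)
    c_ever = composite_ever_effect(params, profile)
    dist = params.grs_dist
    mass = dist.mass(lo, up)
    if mass <= 0:
        raise ValidationError("GRS bin carries no probability mass")

    if dist.kind == "exact":
        mask = (dist.values > lo) & (dist.values <= up)
        g = dist.values[mask]
        w = dist.pmf[mask]
        mu = _conditional_mean(params, c_ever, g, ever)
        return float(np.sum(w * stats.norm.cdf((y_q - mu) / params.sigma_res)) / mass)

    a = max(lo, dist.mean - _TAIL_SD * dist.sd)
    b = min(up, dist.mean + _TAIL_SD * dist.sd)
    if not a < b:
        raise ValidationError("GRS bin lies beyond the truncated support")

    def integrand(g):
        mu = _conditional_mean(params, c_ever, g, ever)
        return (stats.norm.cdf((y_q - mu) / params.sigma_res)
                * stats.norm.pdf(g, dist.mean, dist.sd))

    num, _ = integrate.quad(integrand, a, b, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL,
                            limit=200)
    return float(num / mass)


def relative_risk(
    params: RiskModelParams,
    profile: ExposureProfile,
    threshold_quantile: float,
    grs_bin: Tuple[float, float],
) -> RiskCell:
    """Relative risk of a low phenotype for ever vs never smokers in a bin."""
    p_ever = tail_probability(params, profile, threshold_quantile, grs_bin, ever=1)
    p_never = tail_probability(params, profile, threshold_quantile, grs_bin, ever=0)
    rr = p_ever / p_never
    return RiskCell(
        threshold_quantile=threshold_quantile,
        grs_low=grs_bin[0], grs_up=grs_bin[1],
        p_ever=p_ever, p_never=p_never, rr=rr,
        excess_rr_pct=(rr - 1.0) * 100.0,
    )


def quantile_bins(dist: GrsDistribution, n_bins: int) -> List[Tuple[float, float]]:
    """Equal-mass GRS bins (quintiles by default), outer edges infinite."""
    if n_bins < 2:
        raise ValidationError("need at least two bins")
    edges = [-math.inf] + [dist.ppf(j / n_bins) for j in range(1, n_bins)] + [math.inf]
    return [(edges[j], edges[j + 1]) for j in range(n_bins)]


def projection_grid(
    params: RiskModelParams,
    profile: ExposureProfile,
    thresholds: Sequence[float] = (0.01, 0.05, 0.20),
    n_bins: int = 5,
) -> List[RiskCell]:
    """Full projection table over thresholds x equal-mass GRS bins."""
    bins = quantile_bins(params.grs_dist, n_bins)
    return [relative_risk(params, profile, q, b) for q in thresholds for b in bins]


def grs_distribution(
    panel: VariantPanel,
    weights: Optional[WeightScheme] = None,
    method: str = "normal",
) -> GrsDistribution:
    """Allele-count GRS distribution under Hardy-Weinberg independence.

    ``normal``: moments mean = sum 2 p_i w_i and variance
    = sum 2 p_i (1 - p_i) w_i^2.  ``exact`` (integer weights only):
    the full pmf of the weighted allele-count sum by repeated convolution
    of the per-SNP genotype distributions {(1-p)^2, 2p(1-p), p^2}.
    """
    if weights is None:
        weights = WeightScheme.unweighted(len(panel))
    w = weights.weights
    if len(w) != len(panel):
        raise ValidationError("weights not aligned to panel")
    p = panel.eaf
    if method == "normal":
        return GrsDistribution(
            kind="normal",
            mean=float(np.sum(2 * p * w)),
            sd=float(np.sqrt(np.sum(2 * p * (1 - p) * w**2))),
        )
    if method != "exact":
        raise ValidationError(f"unknown GRS distribution method {method!r}")
    if not np.allclose(w, np.round(w)):
        raise ValidationError("exact GRS distribution needs integer weights")
    pmf = np.array([1.0])
    for pi, wi in zip(p, w.astype(int)):
        if wi == 0:
            continue
        geno = np.array([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2])
        per_snp = np.zeros(2 * wi + 1)
        np.add.at(per_snp, [0, wi, 2 * wi], geno)  # dosage d contributes d * w_i
        pmf = np.convolve(pmf, per_snp)
    values = np.arange(len(pmf), dtype=float)
    return GrsDistribution(kind="exact", mean=float(np.sum(values * pmf)),
                           sd=float(np.sqrt(np.sum(values**2 * pmf)
                                            - np.sum(values * pmf) ** 2)),
                           values=values, pmf=pmf)


# ---------------------------------------------------------------------------
# Parameter file and projection table I/O
# ---------------------------------------------------------------------------

def read_risk_params(path) -> Tuple[RiskModelParams, ExposureProfile]:
    """Load model coefficients and exposure profile from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    params = RiskModelParams(
        gamma_grs=float(cfg["gamma_grs"]), gamma_int=float(cfg["gamma_int"]),
        beta_status=float(cfg["beta_status"]),
        beta_packyears=float(cfg["beta_packyears"]),
        beta_current=float(cfg["beta_current"]),
        sigma_res=float(cfg.get("sigma_res", 1.0)),
    )
    profile = ExposureProfile(
        p_ever=float(cfg.get("p_ever", 0.56)),
        p_current=float(cfg.get("p_current", 0.15)),
        mean_packyears_ever=float(cfg.get("mean_packyears_ever", 21.0)),
    )
    return params, profile


def write_risk_params(params: RiskModelParams, profile: ExposureProfile, path) -> None:
    cfg = dict(gamma_grs=params.gamma_grs, gamma_int=params.gamma_int,
               beta_status=params.beta_status, beta_packyears=params.beta_packyears,
               beta_current=params.beta_current, sigma_res=params.sigma_res,
               p_ever=profile.p_ever, p_current=profile.p_current,
               mean_packyears_ever=profile.mean_packyears_ever)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_projection(cells: Sequence[RiskCell], path) -> None:
    import pandas as pd

    pd.DataFrame([vars(c) for c in cells]).to_csv(path, sep="\t", index=False)


def plot_projection(cells: Sequence[RiskCell], path) -> None:
    """Grouped bar chart of excess RR by GRS bin, one group per threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thresholds = sorted({c.threshold_quantile for c in cells})
    fig, ax = plt.subplots(figsize=(7, 4))
    n_groups = len(thresholds)
    for k, q in enumerate(thresholds):
        sub = [c for c in cells if c.threshold_quantile == q]
        sub.sort(key=lambda c: c.grs_low)
        x = np.arange(len(sub)) + k * (len(sub) + 1)
        ax.bar(x, [c.excess_rr_pct for c in sub],
               label=f"lowest {q:.0%}", width=0.8)
    ax.set_ylabel("excess RR of low phenotype, ever vs never smokers (%)")
    ax.set_xlabel("GRS quantile bins (low to high risk) per threshold group")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
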