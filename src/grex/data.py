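"""Domain types, tabular I/O, configuration and logging.

The pipeline's unit records are a variant panel (the risk-score loci), an
individual-level cohort table, per-SNP interaction summary statistics, and
combined risk-score test results.  Everything is read and written as plain
tab-separated text so that intermediate results remain inspectable.

All variants are oriented to the trait-lowering ("risk") allele at load
time: when a panel row's marginal effect is positive, the alleles are
swapped, the effect-allele frequency complemented and the sign flipped, so
that downstream sign-enrichment and risk-score logic can assume a
consistent orientation.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("grex")

TRAITS = ("FEV1", "FEV1_FVC")
EXPOSURES = ("ever", "packyears")
GRS_METHODS = ("uGRS", "wGRS", "omnibus")

#: Strand-ambiguous allele pairs (complement equals the other allele).
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class ValidationError(ValueError):
    """A record violated a domain-type invariant."""


def configure_logging(quiet: bool = False) -> None:
    """Route package logs to stderr; ``quiet`` suppresses INFO chatter."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.WARNING if quiet else logging.INFO)


def wald_p(beta: float, se: float) -> float:
    """Two-sided normal Wald p-value for ``beta/se``."""
    if se <= 0:
        raise ValidationError(f"standard error must be positive, got {se}")
    return float(2.0 * stats.norm.sf(abs(beta / se)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """One risk-score locus, oriented to the trait-lowering allele."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    marginal_beta: float
    trait: str

    def __post_init__(self):
        if not 0.0 < self.eaf < 1.0:
            raise ValidationError(
                f"{self.snp_id}: effect-allele frequency {self.eaf} outside (0, 1)"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: identical alleles")
        if self.trait not in TRAITS:
            raise ValidationError(f"{self.snp_id}: unknown trait {self.trait!r}")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be 1-based")

    @property
    def is_ambiguous(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _AMBIGUOUS


@dataclass(frozen=True)
class VariantPanel:
    """Ordered set of independent loci sharing a trait (reference size 26)."""

    variants: tuple
    trait: str

    def __post_init__(self):
        if len(self.variants) == 0:
            raise ValidationError("empty panel")
        ids = [v.snp_id for v in self.variants]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate snp_id in panel: {sorted(dup)}")
        for v in self.variants:
            if v.trait != self.trait:
                raise ValidationError(
                    f"{v.snp_id}: trait {v.trait} differs from panel trait {self.trait}"
                )

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list:
        return [v.snp_id for v in self.variants]

    @property
    def eaf(self) -> np.ndarray:
        return np.array([v.eaf for v in self.variants])

    @property
    def marginal_beta(self) -> np.ndarray:
        return np.array([v.marginal_beta for v in self.variants])


@dataclass(frozen=True)
class ExposureProfile:
    """Marginal smoking summaries of a cohort.

    ``p_ever`` and ``p_current`` are whole-cohort fractions;
    ``mean_packyears_ever`` is the mean among ever smokers only.
    """

    p_ever: float = 0.56
    p_current: float = 0.15
    mean_packyears_ever: float = 21.0

    def __post_init__(self):
        if not 0.0 <= self.p_current <= self.p_ever <= 1.0:
            raise ValidationError(
                f"need 0 <= p_current <= p_ever <= 1, got "
                f"({self.p_current}, {self.p_ever})"
            )
        if self.mean_packyears_ever < 0:
            raise ValidationError("mean pack-years must be nonnegative")


@dataclass
class CohortData:
    """Individual-level study data: dosages, smoking exposures, covariates.

    Genotypes are dosages in [0, 2] counted on the (trait-lowering) effect
    allele, one column per panel SNP.  The three smoking exposures are ever
    (binary), pack-years (continuous, zero for never smokers) and current
    (binary); current and positive pack-years imply ever.
    """

    sample_ids: list
    snp_ids: list
    genotypes: np.ndarray          # n x m
    ever: np.ndarray               # binary
    packyears: np.ndarray          # >= 0
    current: np.ndarray            # binary
    covariates: np.ndarray         # n x c
    covariate_names: list
    phenotype_raw: np.ndarray
    study_id: str = "pooled"

    def __post_init__(self):
        n = len(self.sample_ids)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.ever = np.asarray(self.ever, dtype=float)
        self.packyears = np.asarray(self.packyears, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.phenotype_raw = np.asarray(self.phenotype_raw, dtype=float)
        if self.genotypes.shape != (n, len(self.snp_ids)):
            raise ValidationError("genotype matrix shape inconsistent with ids")
        for name, vec in (("ever", self.ever), ("packyears", self.packyears),
                          ("current", self.current), ("phenotype_raw", self.phenotype_raw)):
            if vec.shape != (n,):
                raise ValidationError(f"{name} length != n")
        if self.covariates.shape[0] != n or self.covariates.shape[1] != len(self.covariate_names):
            raise ValidationError("covariate matrix shape inconsistent")
        if self.genotypes.size and (self.genotypes.min() < 0 or self.genotypes.max() > 2):
            raise ValidationError("genotype dosages outside [0, 2]")
        if np.any((self.current == 1) & (self.ever == 0)):
            raise ValidationError("current smoker marked as never smoker")
        if np.any((self.packyears > 0) & (self.ever == 0)):
            raise ValidationError("positive pack-years for a never smoker")
        if np.any(self.packyears < 0):
            raise ValidationError("negative pack-years")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def exposure_matrix(self) -> np.ndarray:
        """The three smoking main-effect columns (ever, pack-years, current)."""
        return np.column_stack([self.ever, self.packyears, self.current])


@dataclass(frozen=True)
class InteractionStat:
    """One SNP-by-exposure interaction estimate with its uncertainty."""

    snp_id: str
    exposure: str
    beta_int: float
    se_int: float
    n: int
    study_id: str = "pooled"
    p: Optional[float] = None

    def __post_init__(self):
        if self.exposure not in EXPOSURES:
            raise ValidationError(f"{self.snp_id}: unknown exposure {self.exposure!r}")
        if not self.se_int > 0:
            raise ValidationError(f"{self.snp_id}: se_int must be > 0, got {self.se_int}")
        if not np.isfinite(self.beta_int):
            raise ValidationError(f"{self.snp_id}: non-finite estimate")
        computed = wald_p(self.beta_int, self.se_int)
        if self.p is None:
            object.__setattr__(self, "p", computed)
        elif abs(self.p - computed) > 1e-6:
            logger.warning(
                "%s: supplied p=%.3g disagrees with Wald p=%.3g; overwriting",
                self.snp_id, self.p, computed,
            )
            object.__setattr__(self, "p", computed)

    @property
    def z(self) -> float:
        return self.beta_int / self.se_int


@dataclass(frozen=True)
class GrsTestResult:
    """Combined interaction test: uGRS, wGRS (1 df) or omnibus (m df)."""

    method: str
    chisq: float
    df: int
    p: float
    m: int
    beta_int: Optional[float] = None
    se: Optional[float] = None
    exposure: Optional[str] = None
    trait: Optional[str] = None
    significant: Optional[bool] = None

    def __post_init__(self):
        if self.method not in GRS_METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.chisq < 0:
            raise ValidationError("chi-square must be nonnegative")
        if self.method == "omnibus":
            if self.df != self.m:
                raise ValidationError("omnibus df must equal the SNP count")
        elif self.df != 1:
            raise ValidationError(f"{self.method} is a 1-df test")

    def ci(self, level: float = 0.95):
        if self.beta_int is None or self.se is None:
            return (None, None)
        z = stats.norm.ppf((1 + level) / 2)
        return (self.beta_int - z * self.se, self.beta_int + z * self.se)


@dataclass(frozen=True)
class WeightScheme:
    """Per-SNP weights for the risk score: unit, |marginal beta|, or custom."""

    kind: str
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if self.kind not in ("unweighted", "marginal_abs", "custom"):
            raise ValidationError(f"unknown weight scheme {self.kind!r}")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValidationError("weights must be nonnegative with at least one positive")
        if self.kind == "unweighted" and not np.allclose(w, 1.0):
            raise ValidationError("unweighted scheme requires unit weights")

    @classmethod
    def unweighted(cls, m: int) -> "WeightScheme":
        return cls("unweighted", np.ones(m))

    @classmethod
    def from_panel(cls, panel: VariantPanel) -> "WeightScheme":
        """Weights = |marginal effect| from the panel (wGRS convention)."""
        return cls("marginal_abs", np.abs(panel.marginal_beta))

    @property
    def method_name(self) -> str:
        return {"unweighted": "uGRS", "marginal_abs": "wGRS", "custom": "wGRS"}[self.kind]


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

_PANEL_COLS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
               "eaf", "marginal_beta", "trait"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def read_variant_panel(path, trait: str) -> VariantPanel:
    """Read a variant panel TSV, keeping rows for ``trait`` only.

    Rows whose marginal effect is positive are flipped to the
    trait-lowering allele (alleles swapped, eaf complemented, sign
    negated).  Strand-ambiguous A/T and C/G records pass through with a
    logged warning; no strand flipping is attempted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, _PANEL_COLS, f"variant panel {path}")
    df = df[df["trait"] == trait]
    if df.empty:
        raise ValidationError(f"empty panel: no rows for trait {trait!r} in {path}")
    variants = []
    for idx, row in df.iterrows():
        try:
            v = VariantSpec(
                snp_id=str(row["snp_id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                eaf=float(row["eaf"]), marginal_beta=float(row["marginal_beta"]),
                trait=str(row["trait"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
        if v.marginal_beta > 0:
            logger.info("%s: flipping to trait-lowering allele", v.snp_id)
            v = replace(v, effect_allele=v.other_allele, other_allele=v.effect_allele,
                        eaf=1.0 - v.eaf, marginal_beta=-v.marginal_beta)
        if v.is_ambiguous:
            logger.warning("%s: strand-ambiguous alleles %s/%s",
                           v.snp_id, v.effect_allele, v.other_allele)
        variants.append(v)
    ids = [v.snp_id for v in variants]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ValidationError(f"{path}: duplicate snp_id {dup}")
    return VariantPanel(variants=tuple(variants), trait=trait)


def write_variant_panel(panel: VariantPanel, path) -> None:
    pd.DataFrame(
        [{c: getattr(v, c) for c in _PANEL_COLS} for v in panel.variants]
    ).to_csv(path, sep="\t", index=False)


_STAT_COLS = ["snp_id", "exposure", "beta_int", "se_int", "n", "study_id"]


def read_interaction_stats(path) -> list:
    """Read per-SNP interaction summary statistics (TSV).

    A missing/blank ``p`` column is recomputed as the two-sided Wald p.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _STAT_COLS, f"interaction stats {path}")
    out = []
    for idx, row in df.iterrows():
        p = None
        if "p" in df.columns and pd.notna(row.get("p")):
            p = float(row["p"])
        try:
            out.append(InteractionStat(
                snp_id=str(row["snp_id"]), exposure=str(row["exposure"]),
                beta_int=float(row["beta_int"]), se_int=float(row["se_int"]),
                n=int(row["n"]), study_id=str(row["study_id"]), p=p,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {idx}: {exc}") from exc
    return out


def write_interaction_stats(records: Sequence[InteractionStat], path) -> None:
    pd.DataFrame(
        [{"snp_id": r.snp_id, "exposure": r.exposure, "beta_int": r.beta_int,
          "se_int": r.se_int, "n": r.n, "study_id": r.study_id, "p": r.p}
         for r in records]
    ).to_csv(path, sep="\t", index=False)


_RESULT_COLS = ["method", "exposure", "trait", "beta_int", "ci_low", "ci_high",
                "chisq", "df", "p"]


def write_result_table(results: Sequence[GrsTestResult], path) -> None:
    """Write combined-test results mirroring the main-table layout."""
    rows = []
    for r in results:
        lo, hi = r.ci()
        rows.append({"method": r.method, "exposure": r.exposure, "trait": r.trait,
                     "beta_int": r.beta_int, "ci_low": lo, "ci_high": hi,
                     "chisq": r.chisq, "df": r.df, "p": r.p, "m": r.m})
    pd.DataFrame(rows, columns=_RESULT_COLS + ["m"]).to_csv(path, sep="\t", index=False)


def read_result_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _RESULT_COLS, f"result table {path}")
    z = stats.norm.ppf(0.975)
    out = []
    for _, row in df.iterrows():
        beta = row["beta_int"] if pd.notna(row["beta_int"]) else None
        se = None
        if beta is not None and pd.notna(row["ci_low"]):
            se = (row["ci_high"] - row["ci_low"]) / (2 * z)
        out.append(GrsTestResult(
            method=str(row["method"]),
            exposure=None if pd.isna(row["exposure"]) else str(row["exposure"]),
            trait=None if pd.isna(row["trait"]) else str(row["trait"]),
            beta_int=beta, se=se, chisq=float(row["chisq"]), df=int(row["df"]),
            p=float(row["p"]), m=int(row.get("m", row["df"])),
        ))
    return out


def write_cohort(cohort: CohortData, path) -> None:
    """Write a cohort as TSV: ids, exposures, covariates, phenotype, dosages."""
    df = pd.DataFrame({"sample_id": cohort.sample_ids, "study_id": cohort.study_id,
                       "ever": cohort.ever.astype(int),
                       "packyears": cohort.packyears,
                       "current": cohort.current.astype(int)})
    for j, name in enumerate(cohort.covariate_names):
        df[f"cov_{name}"] = cohort.covariates[:, j]
    df["phenotype_raw"] = cohort.phenotype_raw
    for j, sid in enumerate(cohort.snp_ids):
        df[f"geno_{sid}"] = cohort.genotypes[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> CohortData:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample_id", "study_id", "ever", "packyears", "current",
                          "phenotype_raw"], f"cohort {path}")
    cov_names = [c[4:] for c in df.columns if c.startswith("cov_")]
    snp_ids = [c[5:] for c in df.columns if c.startswith("geno_")]
    study = df["study_id"].iloc[0] if len(df) else "pooled"
    return CohortData(
        sample_ids=df["sample_id"].tolist(),
        snp_ids=snp_ids,
        genotypes=df[[f"geno_{s}" for s in snp_ids]].to_numpy(float),
        ever=df["ever"].to_numpy(float),
        packyears=df["packyears"].to_numpy(float),
        current=df["current"].to_numpy(float),
        covariates=df[[f"cov_{c}" for c in cov_names]].to_numpy(float)
        if cov_names else np.empty((len(df), 0)),
        covariate_names=cov_names,
        phenotype_raw=df["phenotype_raw"].to_numpy(float),
        study_id=str(study),
    )


def load_config(path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
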