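"""Core Mendelian-randomization estimators.

The causal effect of an exposure (e.g. insulin resistance measured as clamp
M/I in SD-units) on a metabolite is estimated with the Wald ratio: the
instrument-metabolite regression coefficient divided by the
instrument-exposure coefficient.  Standard errors come from the first-order
delta method for a ratio of independent estimates,

    SE_IV = |b_IV| * sqrt((SE_m / b_m)^2 + (SE_e / b_e)^2),

with symmetric normal-approximation 95% confidence intervals and two-sided
normal p-values.  Study-level estimates are pooled by fixed-effects
inverse-variance weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import StructuralError, WeakInstrumentError

#: 97.5% standard-normal quantile used for every 95% CI in the package.
Z975 = 1.959964


@dataclass
class IVAssoc:
    """Association between a genetic instrument and one trait.

    beta is the SD-unit trait change per score allele, with its standard
    error and the sample size behind the fit.  ``role`` distinguishes the
    instrument-exposure leg from the instrument-metabolite leg of a Wald
    ratio.
    """

    beta: float
    se: float
    n: int | None = None
    role: str = "metabolite"  # "exposure" or "metabolite"

    def __post_init__(self):
        if self.se <= 0 or not np.isfinite(self.se):
            raise StructuralError(f"standard error must be positive, got {self.se}")


@dataclass
class MRResult:
    """A causal estimate with its uncertainty.

    Attributes mirror how such estimates are reported: point estimate
    (SD-unit metabolite change per SD of exposure), standard error, 95% CI,
    two-sided p, the estimator that produced it and the number of variants
    behind it.
    """

    beta: float
    se: float
    ci: tuple[float, float]
    p: float
    method: str
    n_snps: int | None = None
    study: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def ci_low(self) -> float:
        return self.ci[0]

    @property
    def ci_high(self) -> float:
        return self.ci[1]

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "p": self.p,
            "method": self.method,
            "n_snps": self.n_snps,
            "study": self.study,
        }

    def summary(self) -> str:
        lines = [
            f"MR estimate ({self.method})",
            "-" * 40,
            f"beta      {self.beta: .4f}",
            f"se        {self.se: .4f}",
            f"95% CI    ({self.ci[0]: .4f}, {self.ci[1]: .4f})",
            f"p         {self.p: .4g}",
        ]
        if self.n_snps is not None:
            lines.append(f"n SNPs    {self.n_snps}")
        if self.study:
            lines.append(f"study     {self.study}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def _normal_inference(beta: float, se: float) -> tuple[tuple[float, float], float]:
    ci = (beta - Z975 * se, beta + Z975 * se)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return ci, float(min(p, 1.0))


def fit_iv_assoc(
    score: np.ndarray | pd.Series,
    trait: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    role: str = "metabolite",
) -> IVAssoc:
    """Regress a trait on a genetic risk score, adjusting for covariates.

    Ordinary least squares with an intercept; the reported coefficient is
    the score term (SD-unit trait change per risk allele).  Constant
    covariate columns are dropped silently (they are absorbed by the
    intercept); genuinely collinear columns raise an error naming them.
    """
    import statsmodels.api as sm

    score = np.asarray(score, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if score.shape[0] != trait.shape[0]:
        raise StructuralError("score and trait lengths differ")

    parts = [pd.Series(score, name="score")]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        # constant columns carry no information beyond the intercept
        keep = [c for c in cov.columns if cov[c].nunique(dropna=True) > 1]
        if keep:
            parts.append(pd.get_dummies(cov[keep], drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    X = sm.add_constant(X, has_constant="add")

    mask = np.isfinite(trait) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    Xc, yc = X.loc[mask], trait[mask]
    rank = np.linalg.matrix_rank(Xc.to_numpy(dtype=float))
    if rank < Xc.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        acc = np.empty((Xc.shape[0], 0))
        for c in Xc.columns:
            cand = np.column_stack([acc, Xc[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == acc.shape[1]:
                bad.append(str(c))
            else:
                acc = cand
        raise StructuralError(f"design matrix is rank deficient; collinear columns: {bad}")

    fit = sm.OLS(yc, Xc).fit()
    return IVAssoc(beta=float(fit.params["score"]), se=float(fit.bse["score"]),
                   n=int(mask.sum()), role=role)


def wald_ratio(metabolite: IVAssoc, exposure: IVAssoc, study: str | None = None) -> MRResult:
    """Wald ratio causal estimate with delta-method standard error.

    beta_IV = b_metabolite / b_exposure;
    SE_IV = |beta_IV| * sqrt((se_m/b_m)^2 + (se_e/b_e)^2).

    A zero instrument-metabolite coefficient is handled as the analytic
    limit (beta_IV = 0, SE_IV = |se_m / b_e|) and flagged; a zero
    instrument-exposure coefficient is a weak-instrument error.
    """
    if exposure.beta == 0:
        raise WeakInstrumentError("instrument-exposure association is zero")

    notes: list[str] = []
    if metabolite.beta == 0:
        beta = 0.0
        se = abs(metabolite.se / exposure.beta)
        notes.append("metabolite association is zero; SE taken as analytic limit")
    else:
        beta = metabolite.beta / exposure.beta
        se = abs(beta) * np.sqrt(
            (metabolite.se / metabolite.beta) ** 2 + (exposure.se / exposure.beta) ** 2
        )
    ci, p = _normal_inference(beta, se)
    return MRResult(beta=float(beta), se=float(se), ci=ci, p=p,
                    method="wald", study=study, notes=notes)


def summary_score_assoc(
    stats_table: pd.DataFrame,
    weights: Sequence[float] | None = None,
    role: str = "metabolite",
) -> IVAssoc:
    """Instrument-trait association from per-SNP GWAS summary statistics.

    For an additive allele score with per-SNP weights w_j (all 1 for an
    unweighted score), per-SNP effects beta_j and standard errors s_j:

        alpha = sum(w_j beta_j / s_j^2) / sum(w_j^2 / s_j^2)
        se    = sum(w_j^2 / s_j^2) ** -0.5

    i.e. the SD-unit trait change per score allele.  The table must be
    harmonized so that beta_j refers to the risk allele.
    """
    if len(stats_table) == 0:
        raise StructuralError("empty SNP set")
    beta = stats_table["beta"].to_numpy(dtype=float)
    se = stats_table["se"].to_numpy(dtype=float)
    if np.any(se <= 0):
        raise StructuralError("all summary standard errors must be positive")
    w = np.ones_like(beta) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != beta.shape:
        raise StructuralError("weights length does not match SNP count")
    denom = np.sum(w**2 / se**2)
    alpha = np.sum(w * beta / se**2) / denom
    n = int(stats_table["n"].max()) if "n" in stats_table else None
    return IVAssoc(beta=float(alpha), se=float(denom**-0.5), n=n, role=role)


def meta_fixed(results: Sequence[MRResult], study: str = "meta") -> MRResult:
    """Fixed-effects inverse-variance-weighted meta-analysis of MR estimates."""
    if len(results) == 0:
        raise StructuralError("meta-analysis needs at least one study")
    b = np.array([r.beta for r in results], dtype=float)
    se = np.array([r.se for r in results], dtype=float)
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    ci, p = _normal_inference(pooled, pooled_se)
    n_snps = results[0].n_snps
    return MRResult(beta=pooled, se=pooled_se, ci=ci, p=p,
                    method="meta", n_snps=n_snps, study=study)


def p_from_estimate_ci(beta: float, lo: float, hi: float) -> float:
    """Two-sided normal p reconstructed from an estimate and its 95% CI.

    Inverts the usual reporting convention: se = (hi - lo) / (2 z_0.975),
    p = 2 Phi(-|beta|/se).  Warns when the estimate lies outside the CI
    (asymmetric or heavily rounded intervals).
    """
    if not lo < hi:
        raise StructuralError(f"need lo < hi, got ({lo}, {hi})")
    if not (lo <= beta <= hi):
        warnings.warn(
            f"estimate {beta} outside CI ({lo}, {hi}); interval may be asymmetric or rounded",
            stacklevel=2,
        )
    se = (hi - lo) / (2.0 * Z975)
    return float(min(2.0 * stats.norm.sf(abs(beta) / se), 1.0))
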