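"""Per-variant MR sensitivity suite for summary data.

Given per-SNP associations with the exposure (bx, sx) and the outcome
(by, sy), this module provides the standard battery used to probe the
instrumental-variable assumptions:

* per-SNP Wald ratios with first-order standard errors,
* the inverse-variance-weighted (IVW) combined estimate,
* MR-Egger regression, whose unconstrained intercept estimates average
  directional pleiotropy (consistent under the InSIDE assumption),
* a profile-likelihood estimator treating both legs as noisy,
* Cochran's Q heterogeneity test over per-SNP ratios,
* scatter / funnel / leave-one-out diagnostic tables.

`SnpSummaryMR` is the model object; its `fit` method returns a
`SensitivityResults` carrying estimate, SE, p and (for Egger) the
intercept inference, plus heterogeneity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConvergenceError, StructuralError
from .mr import Z975


@dataclass
class SnpPair:
    """Per-SNP exposure and outcome associations on the SD-unit scale."""

    rsid: str
    bx: float
    sx: float
    by: float
    sy: float

    def __post_init__(self):
        if self.sx <= 0 or self.sy <= 0:
            raise StructuralError(f"{self.rsid}: standard errors must be positive")


@dataclass
class SensitivityResults:
    """Results container for one summary-data MR fit."""

    method: str
    estimate: float
    se: float
    p: float
    ci: tuple[float, float]
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_statistic: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "p": self.p,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "n_snps": self.n_snps,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
            "q_statistic": self.q_statistic,
            "q_df": self.q_df,
            "q_p": self.q_p,
        }

    def summary(self) -> str:
        lines = [
            f"Summary-data MR ({self.method}, {self.n_snps} SNPs)",
            "-" * 44,
            f"causal estimate  {self.estimate: .4f}  (se {self.se:.4f})",
            f"95% CI           ({self.ci[0]: .4f}, {self.ci[1]: .4f})",
            f"p                {self.p: .4g}",
        ]
        if self.intercept is not None:
            lines.append(
                f"intercept        {self.intercept: .4f}  (se {self.intercept_se:.4f}, "
                f"p {self.intercept_p:.4g})"
            )
        if self.q_statistic is not None:
            lines.append(
                f"Cochran Q        {self.q_statistic:.3f} on {self.q_df} df (p {self.q_p:.4g})"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def _as_arrays(pairs: Sequence[SnpPair]):
    rsid = np.array([p.rsid for p in pairs])
    bx = np.array([p.bx for p in pairs], dtype=float)
    sx = np.array([p.sx for p in pairs], dtype=float)
    by = np.array([p.by for p in pairs], dtype=float)
    sy = np.array([p.sy for p in pairs], dtype=float)
    return rsid, bx, sx, by, sy


class SnpSummaryMR:
    """Summary-data MR model over a set of independent SNPs.

    Parameters
    ----------
    pairs
        Per-SNP exposure/outcome association pairs.  SNPs are assumed
        independent (no linkage disequilibrium between instruments).
    """

    def __init__(self, pairs: Sequence[SnpPair]):
        if len(pairs) == 0:
            raise StructuralError("no SNPs provided")
        self.pairs = list(pairs)
        self.rsid, self.bx, self.sx, self.by, self.sy = _as_arrays(self.pairs)

    @classmethod
    def from_frames(cls, exposure: pd.DataFrame, outcome: pd.DataFrame) -> "SnpSummaryMR":
        """Build from two harmonized summary-stat tables keyed by rsid."""
        merged = exposure.merge(outcome, on="rsid", suffixes=("_x", "_y"))
        if len(merged) == 0:
            raise StructuralError("no shared rsids between exposure and outcome tables")
        pairs = [
            SnpPair(r.rsid, r.beta_x, r.se_x, r.beta_y, r.se_y)
            for r in merged.itertuples()
        ]
        return cls(pairs)

    # -- individual fits ---------------------------------------------------

    def fit(self, method: str = "ivw", **kwargs) -> SensitivityResults:
        if method == "ivw":
            return self._fit_ivw(**kwargs)
        if method == "egger":
            return self._fit_egger(**kwargs)
        if method == "likelihood":
            return self._fit_likelihood(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def per_snp_ratios(self) -> pd.DataFrame:
        """Per-SNP Wald ratios with first-order SEs (sy / |bx|).

        SNPs with a zero exposure association are excluded and listed in
        the ``excluded`` attribute of the returned frame.
        """
        keep = self.bx != 0
        if not keep.any():
            raise StructuralError("all SNPs have zero exposure association")
        out = pd.DataFrame(
            {
                "rsid": self.rsid[keep],
                "estimate": self.by[keep] / self.bx[keep],
                "se": self.sy[keep] / np.abs(self.bx[keep]),
            }
        )
        out.attrs["excluded"] = list(self.rsid[~keep])
        return out

    def _fit_ivw(self, scale_se: bool = False) -> SensitivityResults:
        """Inverse-variance-weighted estimate with fixed-effect SE.

        Algebraically identical to inverse-variance pooling of the per-SNP
        Wald ratios.  With ``scale_se=True`` the SE is inflated by the
        multiplicative residual scale max(1, sqrt(Q/(J-1))).
        """
        if len(self.pairs) < 2:
            raise StructuralError("IVW needs at least 2 SNPs")
        w = self.bx**2 / self.sy**2
        est = float(np.sum(self.bx * self.by / self.sy**2) / np.sum(w))
        se = float(np.sum(w) ** -0.5)
        q, q_df, q_p = self.cochran_q(pooled=est)
        notes = []
        if scale_se:
            phi = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
            se *= phi
            notes.append(f"SE scaled by residual dispersion {phi:.3f}")
        p = float(min(2.0 * stats.norm.sf(abs(est) / se), 1.0))
        return SensitivityResults(
            method="ivw", estimate=est, se=se, p=p,
            ci=(est - Z975 * se, est + Z975 * se), n_snps=len(self.pairs),
            q_statistic=q, q_df=q_df, q_p=q_p, notes=notes,
        )

    def _fit_egger(self, p_distribution: str = "t",
                   floor_scale: bool = False) -> SensitivityResults:
        """MR-Egger: weighted regression of by on bx with free intercept.

        All pairs are re-oriented so bx > 0 before fitting; weights are
        1/sy^2.  The default uses the plain weighted-least-squares residual
        scale, under which the intercept test is exactly t with J-2 df;
        ``floor_scale=True`` bounds the scale below by 1 (the multiplicative
        random-effects convention, whose SEs never undercut the
        fixed-effect ones at the cost of a conservative intercept test).
        ``p_distribution='normal'`` switches to the normal approximation.
        """
        J = len(self.pairs)
        if J < 3:
            raise StructuralError("MR-Egger needs at least 3 SNPs (slope + intercept)")
        flip = np.sign(self.bx)
        flip[flip == 0] = 1.0
        bx, by = self.bx * flip, self.by * flip
        w = 1.0 / self.sy**2
        X = np.column_stack([np.ones(J), bx])
        WX = X * w[:, None]
        xtwx = X.T @ WX
        coef = np.linalg.solve(xtwx, WX.T @ by)
        resid = by - X @ coef
        phi = float(np.sum(w * resid**2) / (J - 2))
        if floor_scale:
            phi = max(1.0, phi)
        cov = np.linalg.inv(xtwx) * phi
        inter, slope = float(coef[0]), float(coef[1])
        se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

        if p_distribution == "t":
            pfun = lambda z: 2.0 * stats.t.sf(abs(z), J - 2)  # noqa: E731
        else:
            pfun = lambda z: 2.0 * stats.norm.sf(abs(z))  # noqa: E731
        return SensitivityResults(
            method="egger", estimate=slope, se=se_slope,
            p=float(min(pfun(slope / se_slope), 1.0)),
            ci=(slope - Z975 * se_slope, slope + Z975 * se_slope),
            n_snps=J, intercept=inter, intercept_se=se_inter,
            intercept_p=float(min(pfun(inter / se_inter), 1.0)),
        )

    def _profile_objective(self, theta: float) -> float:
        # -2 log-likelihood profiled over the per-SNP true exposure effects
        return float(np.sum((self.by - theta * self.bx) ** 2 / (self.sy**2 + theta**2 * self.sx**2)))

    def _fit_likelihood(self, rho: float = 0.0) -> SensitivityResults:
        """Profile-likelihood estimate treating bx and by as noisy.

        Model: bx_j ~ N(xi_j, sx_j^2), by_j ~ N(theta xi_j, sy_j^2),
        independent across SNPs.  The per-SNP nuisance means xi_j profile
        out analytically, leaving a one-dimensional objective minimised by
        bounded scalar optimisation from three dispersed starts; the SE
        comes from the curvature of the profile log-likelihood.
        """
        if rho != 0.0:
            raise NotImplementedError("correlated exposure/outcome sampling errors not supported")
        if len(self.pairs) < 2:
            raise StructuralError("likelihood estimator needs at least 2 SNPs")

        ivw0 = float(np.sum(self.bx * self.by / self.sy**2) / np.sum(self.bx**2 / self.sy**2))
        spread = 5.0 * (abs(ivw0) + 1.0)
        starts = [ivw0, ivw0 - spread / 2, ivw0 + spread / 2]
        best = None
        for s in starts:
            res = optimize.minimize_scalar(
                self._profile_objective,
                bounds=(s - spread, s + spread),
                method="bounded",
                options={"xatol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not best.success:
            raise ConvergenceError(
                "profile-likelihood optimisation failed",
                diagnostics={"starts": starts, "result": repr(best)},
            )
        theta = float(best.x)
        # observed information of the profile: d^2(-logL)/dtheta^2 = g''/2
        h = 1e-4 * (1.0 + abs(theta))
        g = self._profile_objective
        second = (g(theta + h) - 2.0 * g(theta) + g(theta - h)) / h**2
        if second <= 0:
            raise ConvergenceError(
                "profile curvature non-positive at optimum",
                diagnostics={"theta": theta, "curvature": second},
            )
        se = float(np.sqrt(2.0 / second))
        p = float(min(2.0 * stats.norm.sf(abs(theta) / se), 1.0))
        return SensitivityResults(
            method="likelihood", estimate=theta, se=se, p=p,
            ci=(theta - Z975 * se, theta + Z975 * se), n_snps=len(self.pairs),
        )

    # -- heterogeneity and diagnostics ------------------------------------

    def cochran_q(self, pooled: float | None = None) -> tuple[float, int, float]:
        """Cochran's Q over per-SNP ratios: sum((r_j - pooled)^2 / se_j^2)."""
        if len(self.pairs) < 2:
            raise StructuralError("Cochran's Q needs at least 2 SNPs")
        ratios = self.per_snp_ratios()
        if pooled is None:
            w = 1.0 / ratios["se"] ** 2
            pooled = float(np.sum(w * ratios["estimate"]) / np.sum(w))
        q = float(np.sum((ratios["estimate"] - pooled) ** 2 / ratios["se"] ** 2))
        df = len(ratios) - 1
        return q, df, float(stats.chi2.sf(q, df))

    def diagnostics(self) -> dict[str, pd.DataFrame]:
        """Plot-ready scatter, funnel and leave-one-out tables."""
        scatter = pd.DataFrame(
            {"rsid": self.rsid, "bx": self.bx, "sx": self.sx, "by": self.by, "sy": self.sy}
        )
        ratios = self.per_snp_ratios()
        funnel = pd.DataFrame(
            {
                "rsid": ratios["rsid"],
                "estimate": ratios["estimate"],
                "precision": 1.0 / ratios["se"],
            }
        )
        rows = []
        if len(self.pairs) >= 3:
            for i in range(len(self.pairs)):
                sub = SnpSummaryMR([p for j, p in enumerate(self.pairs) if j != i])
                fit = sub.fit("ivw")
                rows.append(
                    {"excluded_rsid": self.pairs[i].rsid, "estimate": fit.estimate,
                     "se": fit.se, "p": fit.p}
                )
        leave_one_out = pd.DataFrame(rows, columns=["excluded_rsid", "estimate", "se", "p"])
        return {"scatter": scatter, "funnel": funnel, "leave_one_out": leave_one_out}


# -- functional surface ----------------------------------------------------

def per_snp_ratios(pairs: Sequence[SnpPair]) -> pd.DataFrame:
    return SnpSummaryMR(pairs).per_snp_ratios()


def ivw(pairs: Sequence[SnpPair], scale_se: bool = False) -> SensitivityResults:
    return SnpSummaryMR(pairs).fit("ivw", scale_se=scale_se)


def egger(pairs: Sequence[SnpPair], p_distribution: str = "t",
          floor_scale: bool = False) -> SensitivityResults:
    return SnpSummaryMR(pairs).fit("egger", p_distribution=p_distribution,
                                   floor_scale=floor_scale)


def likelihood_mr(pairs: Sequence[SnpPair], rho: float = 0.0) -> SensitivityResults:
    return SnpSummaryMR(pairs).fit("likelihood", rho=rho)


def cochran_q(pairs: Sequence[SnpPair], pooled: float | None = None) -> tuple[float, int, float]:
    return SnpSummaryMR(pairs).cochran_q(pooled=pooled)


def diagnostics(pairs: Sequence[SnpPair]) -> dict[str, pd.DataFrame]:
    return SnpSummaryMR(pairs).diagnostics()
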