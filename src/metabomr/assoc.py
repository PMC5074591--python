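"""Physiologic outcomes and the metabolome-wide association scan.

Outcomes: insulin sensitivity as clamp M/I (glucose disposal per unit
insulin during a hyperinsulinemic-euglycemic clamp), the insulinogenic
index IGI30 = (ins30 - ins0) / (glu30 - glu0) over the first 30 min of an
oral glucose tolerance test, and the disposition index DI = clamp M/I x
IGI30.  IGI30 and DI are log-transformed to normality; every analysis copy
is scaled to SD-units.

The scan fits one ordinary least-squares model per metabolite (metabolite
as predictor, outcome as response, plus covariates) and controls the false
discovery rate with Benjamini-Hochberg.  `MetabolomeScan` is the model
object; `scan` is the functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import StructuralError

__all__ = [
    "compute_igi30", "compute_di", "derive_outcomes", "OutcomeSet",
    "MetabolomeScan", "ScanResults", "scan", "bh_fdr",
]


def compute_igi30(ins0, ins30, glu0, glu30):
    """Insulinogenic index: insulin increment over glucose increment, 0-30 min.

    Samples with no glucose change get NaN (the ratio is undefined); the
    caller records the exclusion.
    """
    ins0, ins30 = np.asarray(ins0, dtype=float), np.asarray(ins30, dtype=float)
    glu0, glu30 = np.asarray(glu0, dtype=float), np.asarray(glu30, dtype=float)
    dglu = glu30 - glu0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dglu != 0, (ins30 - ins0) / dglu, np.nan)
    return out


def compute_di(clamp_mi, igi30):
    """Disposition index: clamp M/I x IGI30 (log-transformed downstream)."""
    return np.asarray(clamp_mi, dtype=float) * np.asarray(igi30, dtype=float)


def _sd_units(x: np.ndarray) -> np.ndarray:
    m = np.isfinite(x)
    mu, sd = x[m].mean(), x[m].std(ddof=1)
    out = np.full_like(x, np.nan)
    out[m] = (x[m] - mu) / sd
    return out


@dataclass
class OutcomeSet:
    """Derived outcomes with exclusion bookkeeping.

    Raw values keep their laboratory units; the ``*_sd`` copies are scaled
    to mean 0, SD 1 on the included samples.  ``exclusions`` records every
    sample dropped at a log step (zero glucose change, non-positive IGI30
    or DI) with the reason.
    """

    clamp_mi: np.ndarray
    igi30: np.ndarray
    di: np.ndarray
    log_igi30: np.ndarray
    log_di: np.ndarray
    clamp_mi_sd: np.ndarray
    log_igi30_sd: np.ndarray
    log_di_sd: np.ndarray
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def outcome(self, name: str) -> np.ndarray:
        """SD-unit analysis copy: 'clamp_mi', 'log_igi30' or 'log_di'."""
        return {"clamp_mi": self.clamp_mi_sd, "log_igi30": self.log_igi30_sd,
                "log_di": self.log_di_sd}[name]


def derive_outcomes(pheno: pd.DataFrame) -> OutcomeSet:
    """Compute clamp M/I, IGI30 and DI outcomes from a phenotype table.

    Expects columns ins0, ins30, glu0, glu30, clamp_mi.  Samples with zero
    glucose change are excluded from IGI30/DI; non-positive IGI30 or DI
    values are excluded before the log, with logged reasons.
    """
    ids = pheno.index.to_numpy()
    igi = compute_igi30(pheno["ins0"], pheno["ins30"], pheno["glu0"], pheno["glu30"])
    clamp = pheno["clamp_mi"].to_numpy(dtype=float)
    di = compute_di(clamp, igi)

    rows = []
    zero_glu = ~np.isfinite(igi)
    for i in np.where(zero_glu)[0]:
        rows.append({"sample_id": ids[i], "reason": "zero_glucose_change"})
    nonpos_igi = np.isfinite(igi) & (igi <= 0)
    for i in np.where(nonpos_igi)[0]:
        rows.append({"sample_id": ids[i], "reason": "non_positive_igi30"})
    nonpos_di = np.isfinite(di) & (di <= 0) & ~nonpos_igi
    for i in np.where(nonpos_di)[0]:
        rows.append({"sample_id": ids[i], "reason": "non_positive_di"})

    with np.errstate(divide="ignore", invalid="ignore"):
        log_igi = np.where(igi > 0, np.log(np.where(igi > 0, igi, 1.0)), np.nan)
        log_di = np.where(di > 0, np.log(np.where(di > 0, di, 1.0)), np.nan)
    exclusions = pd.DataFrame(rows, columns=["sample_id", "reason"])
    return OutcomeSet(
        clamp_mi=clamp, igi30=igi, di=di, log_igi30=log_igi, log_di=log_di,
        clamp_mi_sd=_sd_units(clamp), log_igi30_sd=_sd_units(log_igi),
        log_di_sd=_sd_units(log_di), exclusions=exclusions,
    )


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: q-values and rejection flags at level q."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise StructuralError("p-values must lie in (0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


@dataclass
class ScanResults:
    """Per-metabolite association table with FDR-adjusted significance."""

    table: pd.DataFrame
    outcome_name: str
    adjusted_for_bmi: bool
    fdr_q: float
    skipped: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.table["reject"].sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Metabolome-wide scan vs {self.outcome_name}"
            + (" (BMI-adjusted)" if self.adjusted_for_bmi else ""),
            "-" * 48,
            f"metabolites tested   {len(t)}",
            f"significant at {self.fdr_q:.0%} FDR: {self.n_significant}",
        ]
        top = t.nsmallest(min(5, len(t)), "p")
        for _, r in top.iterrows():
            lines.append(
                f"  {r['metabolite']:<12} beta {r['beta']: .3f} (se {r['se']:.3f}) "
                f"p {r['p']:.3g} q {r['q']:.3g}"
            )
        if self.skipped:
            lines.append(f"skipped (rank-deficient): {self.skipped}")
        return "\n".join(lines)


class MetabolomeScan:
    """One-metabolite-at-a-time OLS scan of an outcome on metabolite levels.

    Parameters
    ----------
    metabolites
        Samples x features matrix, standardized to SD-units.
    outcome
        SD-unit outcome vector aligned with the metabolite rows.
    covariates
        Optional covariate table (age, sample-quality indicators, BMI...);
        categorical columns are dummy-coded.
    flip_sign
        Report associations in the direction of worsening physiology
        (negates the coefficients; clamp M/I and DI decrease as insulin
        resistance worsens).
    """

    def __init__(
        self,
        metabolites: pd.DataFrame,
        outcome,
        covariates: pd.DataFrame | None = None,
        flip_sign: bool = False,
    ):
        self.metabolites = metabolites
        self.outcome = np.asarray(outcome, dtype=float)
        if len(self.outcome) != len(metabolites):
            raise StructuralError("outcome length does not match metabolite rows")
        self.covariates = covariates
        self.flip_sign = flip_sign

    def fit(self, fdr_q: float = 0.05, outcome_name: str = "outcome",
            adjusted_for_bmi: bool = False) -> ScanResults:
        if self.covariates is not None:
            C = pd.get_dummies(pd.DataFrame(self.covariates), drop_first=True, dtype=float)
            C = C.to_numpy(dtype=float)
        else:
            C = np.empty((len(self.outcome), 0))
        y = self.outcome

        rows, skipped = [], []
        for name in self.metabolites.columns:
            m = self.metabolites[name].to_numpy(dtype=float)
            keep = np.isfinite(m) & np.isfinite(y) & np.isfinite(C).all(axis=1)
            X = np.column_stack([np.ones(keep.sum()), C[keep], m[keep]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                skipped.append(name)
                continue
            beta, se, p, n = _ols_last_term(X, y[keep])
            rows.append({"metabolite": name, "beta": beta, "se": se, "p": p, "n": n})
        if not rows:
            raise StructuralError("no metabolite could be fitted")
        table = pd.DataFrame(rows)
        qvals, reject = bh_fdr(table["p"].to_numpy(), q=fdr_q)
        table["q"], table["reject"] = qvals, reject
        if self.flip_sign:
            table["beta"] = -table["beta"]
        return ScanResults(table=table, outcome_name=outcome_name,
                           adjusted_for_bmi=adjusted_for_bmi, fdr_q=fdr_q, skipped=skipped)


def _ols_last_term(X: np.ndarray, y: np.ndarray):
    """beta, se, two-sided t p and n for the last column of an OLS design."""
    n, k = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    if df <= 0:
        raise StructuralError("not enough residual degrees of freedom")
    s2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(s2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    if se == 0:
        return beta, se, 0.0, n
    p = float(min(2.0 * stats.t.sf(abs(beta) / se, df), 1.0))
    return beta, se, max(p, np.finfo(float).tiny), n


def scan(
    metabolites: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    adjust_bmi: bool = False,
    bmi: pd.Series | None = None,
    fdr_q: float = 0.05,
    flip_sign: bool = False,
    outcome_name: str = "outcome",
) -> ScanResults:
    """Functional wrapper around :class:`MetabolomeScan`.

    With ``adjust_bmi=True`` the BMI column (from ``bmi`` or a ``bmi``
    column of ``covariates``) enters every model as an extra covariate.
    """
    cov = None if covariates is None else pd.DataFrame(covariates).copy()
    if adjust_bmi:
        if bmi is not None:
            cov = pd.DataFrame(index=metabolites.index) if cov is None else cov
            cov = cov.assign(bmi=np.asarray(bmi, dtype=float))
        elif cov is None or "bmi" not in cov:
            raise StructuralError("adjust_bmi=True but no BMI column supplied")
    elif cov is not None and "bmi" in cov:
        cov = cov.drop(columns=["bmi"])
    model = MetabolomeScan(metabolites, outcome, covariates=cov, flip_sign=flip_sign)
    return model.fit(fdr_q=fdr_q, outcome_name=outcome_name, adjusted_for_bmi=adjust_bmi)
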