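"""Monte-Carlo calibration studies for the MR estimators.

Each study simulates many replicate cohorts (or replicate GWAS summary
tables) under known causal structure and measures how the estimators
behave: bias and CI coverage of the Wald ratio, type-I error of the Wald
ratio and of the MR-Egger intercept under the null, recovery of injected
directional pleiotropy, and empirical FDR of the metabolome-wide scan.

These are the package's own validation experiments; the study functions
are deterministic given their seed and are reused by the acceptance
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, mr, simdata
from .sensitivity import SnpPair, SnpSummaryMR


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _leg(config: simdata.SimConfig, seed: int) -> tuple:
    c = config.with_(seed=int(seed))
    g = simdata.simulate_genotypes(c.rafs, c.n_individuals, seed=int(seed),
                                   snp_ids=c.snp_ids)
    cohort, mets = simdata.simulate_cohort(g, c)
    return g.dosage.sum(axis=1), cohort, mets


def _one_wald_replicate(config: simdata.SimConfig, seed: int) -> mr.MRResult:
    # two-sample design: the instrument-exposure leg comes from an
    # independent cohort, as when per-allele effects are taken from an
    # external GWAS; the delta-method SE assumes exactly this independence
    score_m, _, mets = _leg(config, seed)
    score_e, cohort_e, _ = _leg(config, int(seed) + 2**31)
    e = mr.fit_iv_assoc(score_e, cohort_e["exposure"].to_numpy(), role="exposure")
    m = mr.fit_iv_assoc(score_m, mets.iloc[:, 0].to_numpy(), role="metabolite")
    return mr.wald_ratio(m, e)


def wald_recovery_study(
    n_reps: int = 500,
    theta: float = -0.4,
    n_individuals: int = 5000,
    confounding: float = 0.3,
    seed: int = 0,
) -> dict:
    """Bias and 95% CI coverage of the Wald ratio under a true causal effect.

    Ten independent HWE SNPs (risk-allele frequencies 0.2-0.5) drive the
    exposure; the metabolite carries the causal effect ``theta`` plus
    confounding.  Returns the mean estimate, its Monte-Carlo SE and the
    empirical coverage of the 95% CI.
    """
    config = simdata.SimConfig.insulin_resistance(
        n_individuals=n_individuals, theta=theta,
        confounder_on_metabolite=confounding)
    ests, covered = [], 0
    for s in _child_seeds(seed, n_reps):
        res = _one_wald_replicate(config, s)
        ests.append(res.beta)
        covered += res.ci[0] <= theta <= res.ci[1]
    ests = np.asarray(ests)
    return {
        "theta": theta,
        "n_reps": n_reps,
        "mean_estimate": float(ests.mean()),
        "mc_se": float(ests.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": covered / n_reps,
    }


def wald_null_calibration(
    n_reps: int = 500, n_individuals: int = 5000, seed: int = 0
) -> dict:
    """Type-I error of the Wald ratio at alpha=0.05 when theta=0, no pleiotropy."""
    config = simdata.SimConfig.insulin_resistance(
        n_individuals=n_individuals, theta=0.0)
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        rejections += _one_wald_replicate(config, s).p < 0.05
    return {
        "n_reps": n_reps,
        "type_i_error": rejections / n_reps,
        "mc_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
    }


def _summary_pairs(config: simdata.SimConfig, seed: int,
                   n_gwas_exposure: int, n_gwas_outcome: int) -> list[SnpPair]:
    ex = simdata.simulate_summary_stats(config, n_gwas_exposure, role="exposure",
                                        seed=int(seed))
    out = simdata.simulate_summary_stats(config, n_gwas_outcome, role="outcome",
                                         seed=int(seed) + 2**31)
    return [SnpPair(r, bx, sx, by, sy) for r, bx, sx, by, sy in zip(
        ex["rsid"], ex["beta"], ex["se"], out["beta"], out["se"])]


def egger_null_calibration(
    n_reps: int = 500,
    n_gwas_exposure: int = 46186,
    n_gwas_outcome: int = 8000,
    seed: int = 0,
) -> dict:
    """Type-I error of the MR-Egger intercept test under theta=0, no pleiotropy."""
    config = simdata.SimConfig.insulin_resistance(theta=0.0)
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        pairs = _summary_pairs(config, s, n_gwas_exposure, n_gwas_outcome)
        fit = SnpSummaryMR(pairs).fit("egger")
        rejections += fit.intercept_p < 0.05
    return {
        "n_reps": n_reps,
        "intercept_type_i_error": rejections / n_reps,
        "mc_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
    }


def pleiotropy_study(
    n_reps: int = 500,
    direct_effect: float = 0.05,
    n_gwas_exposure: int = 46186,
    n_gwas_outcome: int = 8000,
    seed: int = 0,
) -> dict:
    """Directional pleiotropy with no causal effect (InSIDE holds).

    Every SNP gets the same direct effect on the metabolite; theta=0.  The
    MR-Egger intercept should average the injected effect and its slope
    should centre on zero, while IVW is biased by the pleiotropy (its
    expected displacement is the precision-weighted projection of the
    direct effects onto the instrument strengths, reported as
    ``ivw_expected_bias``).
    """
    J = 10
    config = simdata.SimConfig.insulin_resistance(
        theta=0.0, pleiotropy=np.full(J, direct_effect))
    bx_true = config.true_marginal_effects("exposure")
    sy = 1.0 / np.sqrt(2 * config.rafs * (1 - config.rafs) * n_gwas_outcome)
    w = 1.0 / sy**2
    expected_bias = float(direct_effect * np.sum(w * bx_true) / np.sum(w * bx_true**2))

    intercepts, slopes, ivws = [], [], []
    for s in _child_seeds(seed, n_reps):
        pairs = _summary_pairs(config, s, n_gwas_exposure, n_gwas_outcome)
        model = SnpSummaryMR(pairs)
        eg = model.fit("egger")
        intercepts.append(eg.intercept)
        slopes.append(eg.estimate)
        ivws.append(model.fit("ivw").estimate)
    intercepts, slopes, ivws = map(np.asarray, (intercepts, slopes, ivws))
    return {
        "n_reps": n_reps,
        "direct_effect": direct_effect,
        "egger_intercept_mean": float(intercepts.mean()),
        "egger_intercept_mc_se": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "egger_slope_mean": float(slopes.mean()),
        "egger_slope_mc_se": float(slopes.std(ddof=1) / np.sqrt(n_reps)),
        "ivw_mean": float(ivws.mean()),
        "ivw_mc_se": float(ivws.std(ddof=1) / np.sqrt(n_reps)),
        "ivw_expected_bias": expected_bias,
    }


def fdr_study(
    n_reps: int = 200,
    n_features: int = 200,
    n_true: int = 20,
    n_samples: int = 300,
    effect: float = 0.15,
    fdr_q: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical FDR and power of the scan with BH control at level q.

    Each replicate draws independent standard-normal metabolite features;
    the outcome loads on the first ``n_true`` of them with the stated
    per-feature effect plus noise scaled to unit total variance.
    """
    resid_sd = np.sqrt(max(1.0 - n_true * effect**2, 0.1))
    fdps, powers = [], []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(int(s))
        mets = pd.DataFrame(
            rng.standard_normal((n_samples, n_features)),
            columns=[f"m{k}" for k in range(n_features)],
        )
        y = mets.iloc[:, :n_true].to_numpy() @ np.full(n_true, effect)
        y = y + resid_sd * rng.standard_normal(n_samples)
        res = assoc.scan(mets, y, fdr_q=fdr_q)
        rej = res.table.set_index("metabolite")["reject"]
        true_set = {f"m{k}" for k in range(n_true)}
        n_rej = int(rej.sum())
        fp = int(sum(rej[m] for m in rej.index if m not in true_set))
        fdps.append(fp / max(n_rej, 1))
        powers.append(sum(rej[m] for m in true_set) / n_true)
    fdps = np.asarray(fdps)
    return {
        "n_reps": n_reps,
        "fdr_level": fdr_q,
        "empirical_fdr": float(fdps.mean()),
        "mc_se": float(fdps.std(ddof=1) / np.sqrt(n_reps)),
        "mean_power": float(np.mean(powers)),
    }
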