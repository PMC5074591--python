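"""Synthetic cohorts with known causal structure.

Everything downstream (risk scores, association scans, MR estimators) is
validated against data generated here, where the causal effect of the
exposure on each metabolite is known exactly.

Generative model
----------------
Genotypes are independent SNPs in Hardy-Weinberg equilibrium:
dosage_ij ~ Binomial(2, raf_j).  The exposure (think insulin resistance in
SD-units) is an additive genetic score plus confounding:

    X_i = sum_j a_j G_ij + b_U U_i + e_i,   then standardized,

with U a single standard-normal confounder.  Each metabolite is

    M_ik = theta_k X_i + c_M U_i + sum_j d_jk G_ij + eps_ik,

where theta_k is the causal effect (SD metabolite per SD exposure), c_M the
confounder loading and d_jk optional direct (pleiotropic) SNP effects.  By
default the residual SD is chosen so the metabolite has unit theoretical
variance, making theta_k itself the SD-unit causal effect after sample
standardization.

OGTT insulin/glucose and clamp M/I are monotone transforms of latent
insulin-sensitivity and secretion variables, so the derived insulinogenic
and disposition indices carry the intended sign structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, StructuralError

__all__ = [
    "SnpSpec", "SimConfig", "GenotypeMatrix",
    "simulate_genotypes", "simulate_cohort", "simulate_summary_stats",
    "inject_missingness", "simulate_feature_table",
]


@dataclass(frozen=True)
class SnpSpec:
    """One score SNP: identifier, risk-allele frequency, per-allele exposure effect."""

    rsid: str
    raf: float
    effect: float

    def __post_init__(self):
        if not 0.0 < self.raf < 1.0:
            raise InvalidParameterError(f"{self.rsid}: risk allele frequency must be in (0,1)")


@dataclass
class SimConfig:
    """Parameters of the generative model; the seed fully determines output."""

    n_individuals: int = 5000
    snps: Sequence[SnpSpec] = field(default_factory=list)
    theta: float | Sequence[float] = -0.4
    confounder_on_exposure: float = 0.3
    confounder_on_metabolite: float = 0.3
    pleiotropy: np.ndarray | None = None  # (n_snps,) or (n_snps, n_metabolites)
    noise_sd_exposure: float | str = "auto"
    noise_sd_metabolite: float | str = "auto"
    n_metabolites: int = 1
    n_plates: int = 4
    plate_effect_sd: float = 0.3
    drift_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")
        if not self.snps:
            raise InvalidParameterError("at least one score SNP is required")
        self.snps = tuple(self.snps)

    # -- canonical study conditions ---------------------------------------

    @classmethod
    def insulin_resistance(cls, **overrides) -> "SimConfig":
        """10-SNP additive score for insulin resistance.

        Risk-allele frequencies span 0.2-0.5 and the per-allele effects sum
        to a strong instrument (score explains ~2.5% of exposure variance
        at the default n).
        """
        rafs = np.linspace(0.2, 0.5, 10)
        effects = np.linspace(0.04, 0.12, 10)
        snps = [SnpSpec(f"rs_ir{i+1:02d}", float(f), float(a))
                for i, (f, a) in enumerate(zip(rafs, effects))]
        return cls(snps=snps, **overrides)

    @classmethod
    def insulin_secretion(cls, **overrides) -> "SimConfig":
        """21-SNP additive score for impaired early-phase insulin secretion."""
        rafs = np.linspace(0.15, 0.6, 21)
        effects = np.linspace(0.03, 0.08, 21)
        snps = [SnpSpec(f"rs_is{i+1:02d}", float(f), float(a))
                for i, (f, a) in enumerate(zip(rafs, effects))]
        return cls(snps=snps, **overrides)

    def with_(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)

    # -- derived quantities -------------------------------------------------

    @property
    def rafs(self) -> np.ndarray:
        return np.array([s.raf for s in self.snps], dtype=float)

    @property
    def effects(self) -> np.ndarray:
        return np.array([s.effect for s in self.snps], dtype=float)

    @property
    def snp_ids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def _dosage_variances(self) -> np.ndarray:
        f = self.rafs
        return 2.0 * f * (1.0 - f)

    def exposure_sd_raw(self) -> float:
        """Theoretical SD of the un-standardized exposure."""
        v = self._dosage_variances()
        g_var = float(np.sum(self.effects**2 * v))
        return float(np.sqrt(g_var + self.confounder_on_exposure**2 + self._sigma_e() ** 2))

    def _sigma_e(self) -> float:
        if self.noise_sd_exposure != "auto":
            return float(self.noise_sd_exposure)
        v = self._dosage_variances()
        explained = float(np.sum(self.effects**2 * v)) + self.confounder_on_exposure**2
        if explained >= 1.0:
            raise InvalidParameterError(
                "genetic + confounder variance exceeds 1; set noise_sd_exposure explicitly"
            )
        return float(np.sqrt(1.0 - explained))

    def _theta_vec(self) -> np.ndarray:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim == 0:
            th = np.full(self.n_metabolites, float(th))
        if th.shape != (self.n_metabolites,):
            raise StructuralError("theta length does not match n_metabolites")
        return th

    def _pleiotropy_mat(self) -> np.ndarray:
        J = len(self.snps)
        if self.pleiotropy is None:
            return np.zeros((J, self.n_metabolites))
        d = np.asarray(self.pleiotropy, dtype=float)
        if d.ndim == 1:
            d = np.repeat(d[:, None], self.n_metabolites, axis=1)
        if d.shape != (J, self.n_metabolites):
            raise StructuralError("pleiotropy shape must be (n_snps,) or (n_snps, n_metabolites)")
        return d

    def metabolite_residual_sds(self) -> np.ndarray:
        """Residual SDs; 'auto' solves for unit theoretical metabolite variance."""
        th = self._theta_vec()
        d = self._pleiotropy_mat()
        v = self._dosage_variances()
        s = self.exposure_sd_raw()
        c = self.confounder_on_metabolite
        var_direct = np.sum(d**2 * v[:, None], axis=0)
        cov_x_u = self.confounder_on_exposure / s
        cov_x_d = (self.effects[:, None] * d * v[:, None]).sum(axis=0) / s
        explained = th**2 + c**2 + var_direct + 2 * th * c * cov_x_u + 2 * th * cov_x_d
        if self.noise_sd_metabolite != "auto":
            return np.full(self.n_metabolites, float(self.noise_sd_metabolite))
        if np.any(explained >= 1.0):
            raise InvalidParameterError(
                "structural metabolite variance exceeds 1; set noise_sd_metabolite explicitly"
            )
        return np.sqrt(1.0 - explained)

    def true_marginal_effects(self, role: str, metabolite: int = 0) -> np.ndarray:
        """Per-allele marginal association of each SNP with a standardized trait."""
        s = self.exposure_sd_raw()
        per_allele_on_x = self.effects / s
        if role == "exposure":
            return per_allele_on_x
        if role == "outcome":
            th = self._theta_vec()[metabolite]
            d = self._pleiotropy_mat()[:, metabolite]
            return th * per_allele_on_x + d
        raise InvalidParameterError(f"role must be 'exposure' or 'outcome', got {role!r}")


@dataclass
class GenotypeMatrix:
    """Risk-allele dosages (0/1/2, NaN = missing) for samples x SNPs.

    ``counted_allele`` records, per SNP, which allele the stored dosage
    counts; ``other_allele`` the complementary one.  Both may be None for
    purely synthetic matrices where allele labels are irrelevant.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    counted_allele: dict[str, str] | None = None
    other_allele: dict[str, str] | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise StructuralError("dosage shape does not match id lists")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise StructuralError("dosages must be 0, 1, 2 or missing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def simulate_genotypes(
    raf_list: Sequence[float], n: int, seed: int, snp_ids: Sequence[str] | None = None
) -> GenotypeMatrix:
    """Draw HWE genotypes: dosage_ij ~ Binomial(2, raf_j), independent SNPs."""
    raf = np.asarray(raf_list, dtype=float)
    if raf.ndim != 1 or raf.size == 0:
        raise InvalidParameterError("raf_list must be a non-empty 1-D sequence")
    if np.any((raf <= 0) | (raf >= 1)):
        raise InvalidParameterError("all risk allele frequencies must be strictly in (0,1)")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, raf, size=(n, raf.size)).astype(float)
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j+1}" for j in range(raf.size)]
    samples = [f"id{i+1:05d}" for i in range(n)]
    alleles = {s: "A" for s in ids}
    others = {s: "G" for s in ids}
    return GenotypeMatrix(samples, ids, dosage, counted_allele=alleles, other_allele=others)


def simulate_cohort(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate phenotypes and metabolites on top of a genotype matrix.

    Returns ``(cohort, metabolites)``: a per-sample phenotype/covariate
    table (exposure in SD-units, confounder, age, sex, 3 genetic PCs,
    cohort label, BMI, OGTT insulin/glucose at 0 and 30 min, clamp M/I) and
    a samples x metabolites matrix standardized to SD-units.
    """
    if genotypes.snp_ids != config.snp_ids:
        raise StructuralError("genotype columns do not align with config.snps")
    G = genotypes.dosage
    if np.isnan(G).any():
        raise StructuralError("simulate_cohort requires complete genotypes")
    n = genotypes.n_samples
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    U = rng.standard_normal(n)
    e = rng.standard_normal(n) * config._sigma_e()
    x_raw = G @ config.effects + config.confounder_on_exposure * U + e
    exposure = (x_raw - x_raw.mean()) / x_raw.std(ddof=1)

    th = config._theta_vec()
    d = config._pleiotropy_mat()
    eps_sd = config.metabolite_residual_sds()
    eps = rng.standard_normal((n, config.n_metabolites)) * eps_sd
    M = (
        exposure[:, None] * th[None, :]
        + config.confounder_on_metabolite * U[:, None]
        + G @ d
        + eps
    )
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    metabolites = pd.DataFrame(
        M, index=genotypes.sample_ids,
        columns=[f"met{k+1:03d}" for k in range(config.n_metabolites)],
    )

    # physiologic outcomes: monotone transforms of latent sensitivity/secretion.
    # Higher exposure = worse insulin resistance = lower clamp M/I.
    sens = -exposure
    secretion = 0.5 * sens + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    clamp_mi = 5.4 * np.exp(0.35 * sens + 0.15 * rng.standard_normal(n) - 0.07)
    glu0 = rng.normal(5.1, 0.4, n)
    dglu = np.maximum(rng.normal(2.5, 0.5, n), 0.5)
    ins0 = np.maximum(rng.normal(8.0, 1.5, n), 1.0)
    igi_true = 0.46 * np.exp(0.6 * secretion + 0.2 * rng.standard_normal(n))
    ins30 = ins0 + igi_true * dglu

    cohort = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "exposure": exposure,
            "confounder": U,
            "age": rng.normal(71.0, 0.6, n).round(1),
            "sex": rng.integers(0, 2, n),
            "pc1": rng.standard_normal(n),
            "pc2": rng.standard_normal(n),
            "pc3": rng.standard_normal(n),
            "cohort": np.where(rng.random(n) < 0.4, "cohortA", "cohortB"),
            "bmi": 25.9 + 3.1 * (0.5 * U + np.sqrt(0.75) * rng.standard_normal(n)),
            "ins0": ins0,
            "ins30": ins30,
            "glu0": glu0,
            "glu30": glu0 + dglu,
            "clamp_mi": clamp_mi,
        }
    ).set_index("sample_id")
    return cohort, metabolites


def simulate_summary_stats(
    config: SimConfig,
    n_gwas: int,
    role: str = "exposure",
    seed: int | None = None,
    metabolite: int = 0,
) -> pd.DataFrame:
    """Noisy per-SNP GWAS summary statistics for the exposure or a metabolite.

    True marginal effects come from the generative model; the reported beta
    is Normal(true, se) with se = 1 / sqrt(2 f_j (1-f_j) n_gwas) for a
    unit-SD trait.  Alleles and frequencies are emitted so that allele
    harmonization can be exercised.  The true effects are stashed in
    ``result.attrs['true_beta']``.
    """
    if n_gwas < 1:
        raise InvalidParameterError("n_gwas must be >= 1")
    true = config.true_marginal_effects(role, metabolite=metabolite)
    f = config.rafs
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n_gwas)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    beta = rng.normal(true, se)
    out = pd.DataFrame(
        {
            "rsid": config.snp_ids,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": f,
            "beta": beta,
            "se": se,
            "n": n_gwas,
        }
    )
    out.attrs["true_beta"] = tuple(float(t) for t in true)
    return out


def inject_missingness(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each dosage entry missing independently with the given probability."""
    if not 0.0 <= rate < 1.0:
        raise InvalidParameterError("missingness rate must be in [0, 1)")
    dosage = g.dosage.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        dosage[rng.random(dosage.shape) < rate] = np.nan
    return GenotypeMatrix(
        list(g.sample_ids), list(g.snp_ids), dosage,
        counted_allele=dict(g.counted_allele) if g.counted_allele else None,
        other_allele=dict(g.other_allele) if g.other_allele else None,
    )


def simulate_feature_table(
    n_samples: int = 48,
    n_features: int = 120,
    n_plates: int = 4,
    plate_effect_sd: float = 0.3,
    drift_slope: float = 0.0,
    frac_noise_features: float = 0.15,
    frac_early_rt: float = 0.1,
    missing_rate: float = 0.02,
    seed: int = 0,
):
    """LC/MS-like feature intensities with plate structure and run-order drift.

    Samples come in duplicate pairs (consecutive injections of the same
    biological sample).  Most features carry a shared biological signal
    (high between-duplicate correlation); ``frac_noise_features`` are pure
    noise; ``frac_early_rt`` elute before 35 s.  Batch effects are additive
    on the log scale: plate random intercepts and a linear drift in
    acquisition order.  Returns a :class:`~metabomr.preprocess.FeatureTable`.
    """
    from .preprocess import FeatureTable

    if n_samples % 2:
        raise InvalidParameterError("n_samples must be even (duplicate pairs)")
    rng = np.random.default_rng(seed)
    n_pairs = n_samples // 2
    order = np.arange(n_samples)
    plates = order * n_plates // n_samples

    base = rng.uniform(8.0, 14.0, n_features)
    bio_sd = rng.uniform(0.5, 1.2, n_features)
    noise_sd = rng.uniform(0.05, 0.15, n_features)
    is_noise = rng.random(n_features) < frac_noise_features
    noise_sd[is_noise] = bio_sd[is_noise]  # duplicate correlation collapses

    bio = rng.standard_normal((n_pairs, n_features)) * bio_sd
    bio = np.repeat(bio, 2, axis=0)
    plate_fx = rng.standard_normal((n_plates, n_features)) * plate_effect_sd
    log_i = (
        base
        + bio * ~is_noise
        + rng.standard_normal((n_samples, n_features)) * noise_sd
        + plate_fx[plates]
        + drift_slope * order[:, None]
    )
    intensity = np.exp(log_i)
    if missing_rate > 0:
        intensity[rng.random(intensity.shape) < missing_rate] = np.nan

    rt = rng.uniform(40.0, 600.0, n_features)
    early = rng.choice(n_features, size=max(1, int(frac_early_rt * n_features)), replace=False)
    rt[early] = rng.uniform(5.0, 34.9, early.size)

    sample_ids = pd.Index([f"s{i+1:03d}" for i in range(n_samples)], name="sample_id")
    features = pd.DataFrame(
        {
            "id": [f"feat{j+1:04d}" for j in range(n_features)],
            "mz": rng.uniform(50.0, 1200.0, n_features),
            "rt_seconds": rt,
            "annotation": [None] * n_features,
        }
    )
    sample_meta = pd.DataFrame(
        {
            "plate": [f"plate{p+1}" for p in plates],
            "order": order,
            "duplicate_pair": np.repeat(np.arange(n_pairs), 2),
        },
        index=sample_ids,
    )
    intensities = pd.DataFrame(intensity, index=sample_ids, columns=list(features["id"]))
    return FeatureTable(features=features, intensities=intensities, sample_meta=sample_meta)
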