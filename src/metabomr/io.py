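"""TSV dialects, run configuration, logging and the end-to-end pipeline.

Every table is UTF-8, tab-separated, '.' decimal, single header row.
Genotype files follow the PLINK RAW-style convention: dosage columns are
named ``rsid_ALLELE`` where the suffix is the counted allele.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, ParseError
from .preprocess import FeatureTable
from .simdata import GenotypeMatrix

SUMMARY_COLUMNS = ["rsid", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]


# -- genotype dosage TSV ---------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    cols = {}
    for j, rsid in enumerate(g.snp_ids):
        allele = (g.counted_allele or {}).get(rsid)
        name = f"{rsid}_{allele}" if allele else rsid
        cols[name] = g.dosage[:, j]
    df = pd.DataFrame(cols, index=pd.Index(g.sample_ids, name="sample_id"))
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    snp_ids, counted = [], {}
    for col in df.columns:
        if "_" in col and col.rsplit("_", 1)[1] in ("A", "C", "G", "T"):
            rsid, allele = col.rsplit("_", 1)
            counted[rsid] = allele
        else:
            rsid = col
        snp_ids.append(rsid)
    return GenotypeMatrix(
        [str(s) for s in df.index], snp_ids, df.to_numpy(dtype=float),
        counted_allele=counted or None,
    )


# -- feature tables --------------------------------------------------------

def write_feature_table(t: FeatureTable, prefix: str | Path) -> None:
    """Write intensities, feature sidecar and sample sidecar TSVs."""
    prefix = Path(prefix)
    t.intensities.rename_axis("sample_id").to_csv(
        prefix.with_suffix(".intensities.tsv"), sep="\t", na_rep="NA")
    t.features.to_csv(prefix.with_suffix(".features.tsv"), sep="\t", index=False, na_rep="NA")
    t.sample_meta.rename_axis("sample_id").to_csv(
        prefix.with_suffix(".samples.tsv"), sep="\t", na_rep="NA")


def read_feature_table(prefix: str | Path, log_scale: bool = False) -> FeatureTable:
    prefix = Path(prefix)
    intensities = pd.read_csv(prefix.with_suffix(".intensities.tsv"), sep="\t",
                              index_col="sample_id", na_values=["NA"])
    features = pd.read_csv(prefix.with_suffix(".features.tsv"), sep="\t", na_values=["NA"])
    sample_meta = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t",
                              index_col="sample_id", na_values=["NA"])
    return FeatureTable(features=features, intensities=intensities,
                        sample_meta=sample_meta, log_scale=log_scale)


# -- summary statistics ----------------------------------------------------

def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a per-SNP GWAS summary table with strict validation.

    Duplicate rsids raise; a missing standard error drops the record with
    a warning; malformed numeric fields raise with the offending line
    number (1-based, header is line 1).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in SUMMARY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    dup = raw["rsid"][raw["rsid"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicated rsid {dup.iloc[0]!r}")
    rows = []
    for i, rec in raw.iterrows():
        line_no = i + 2
        if pd.isna(rec["se"]) or str(rec["se"]).upper() in ("NA", "NAN", ""):
            warnings.warn(f"{path} line {line_no}: missing se, record dropped", stacklevel=2)
            continue
        try:
            rows.append({
                "rsid": rec["rsid"],
                "effect_allele": rec["effect_allele"],
                "other_allele": rec["other_allele"],
                "eaf": float(rec["eaf"]),
                "beta": float(rec["beta"]),
                "se": float(rec["se"]),
                "n": int(float(rec["n"])),
            })
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path} line {line_no}: malformed numeric field ({exc})") from exc
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


# -- run configuration -----------------------------------------------------

@dataclass
class RunConfig:
    """Declarative configuration for the end-to-end pipeline."""

    out_dir: str = "metabomr_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "preprocess", "scan", "score", "mr", "sens", "meta")
    n_individuals: int = 2000
    n_metabolites: int = 20
    theta: float = -0.4
    score: str = "insulin_resistance"
    covariates: tuple[str, ...] = ("age", "sex", "pc1", "pc2", "pc3", "cohort")
    min_rt: float = 35.0
    dup_corr: float = 0.5
    outlier_sd: float = 3.0
    min_nonmissing: int | None = None
    fdr_q: float = 0.05
    n_gwas_exposure: int = 46186
    n_gwas_outcome: int = 8000
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        known = {"simulate", "preprocess", "scan", "score", "mr", "sens", "meta"}
        bad = set(self.stages) - known
        if bad:
            raise ConfigurationError(f"unknown stages: {sorted(bad)}")
        for key, p in (self.inputs or {}).items():
            if not Path(p).exists():
                raise ConfigurationError(f"input path for {key!r} does not exist: {p}")
        if not 0 < self.fdr_q < 1:
            raise ConfigurationError("fdr_q must be in (0,1)")


class RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
        self.lines.append(f"{stamp}  {msg}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the configured stages end-to-end on synthetic data.

    Stages: simulate -> preprocess -> scan -> score -> mr -> sens -> meta.
    Every stage writes its outputs as TSV under ``config.out_dir``; a run
    log records package version, seed, thresholds and exclusion counts.
    Deterministic given the seed.
    """
    from . import assoc, grs, mr, preprocess, sensitivity, simdata

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run.log")
    log.write(f"metabomr {__version__} seed={config.seed}")
    log.write(
        f"thresholds: min_rt={config.min_rt} dup_corr={config.dup_corr} "
        f"outlier_sd={config.outlier_sd} min_nonmissing={config.min_nonmissing} "
        f"fdr_q={config.fdr_q}"
    )
    written: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index, na_rep="NA", float_format="%.10g")
        written[name] = p

    factory = getattr(simdata.SimConfig, config.score)
    sim = factory(
        n_individuals=config.n_individuals, n_metabolites=config.n_metabolites,
        theta=config.theta, seed=config.seed,
    )

    genotypes = simdata.simulate_genotypes(sim.rafs, sim.n_individuals, seed=sim.seed,
                                           snp_ids=sim.snp_ids)
    cohort, metabolites = simdata.simulate_cohort(genotypes, sim)
    if "simulate" in config.stages:
        write_genotypes(genotypes, out / "genotypes.tsv")
        written["genotypes"] = out / "genotypes.tsv"
        emit("phenotypes", cohort, index=True)
        emit("metabolites_raw", metabolites, index=True)
        log.write(f"simulate: n={sim.n_individuals} snps={len(sim.snps)} "
                  f"metabolites={config.n_metabolites} theta={config.theta}")

    if "preprocess" in config.stages:
        ft = simdata.simulate_feature_table(seed=config.seed + 1)
        ft = preprocess.log_transform(ft)
        ft = preprocess.anova_standardize(ft)
        ft, report = preprocess.filter_features(
            ft, min_rt=config.min_rt, min_dup_corr=config.dup_corr,
            outlier_sd=config.outlier_sd, min_nonmissing=config.min_nonmissing,
        )
        emit("feature_filter_report", report)
        emit("features_clean", ft.intensities, index=True)
        log.write(f"preprocess: kept {ft.n_features} features, "
                  f"{len(report)} report rows")

    outcomes = assoc.derive_outcomes(cohort)
    if "scan" in config.stages:
        std_mets = preprocess.standardize(metabolites)
        tables = []
        for outcome_name in ("clamp_mi", "log_di"):
            for adjust_bmi in (False, True):
                res = assoc.scan(
                    std_mets, outcomes.outcome(outcome_name),
                    covariates=cohort[["age"]], adjust_bmi=adjust_bmi,
                    bmi=cohort["bmi"], fdr_q=config.fdr_q, flip_sign=True,
                    outcome_name=outcome_name,
                )
                t = res.table.assign(outcome=outcome_name, model="bmi" if adjust_bmi else "base")
                tables.append(t)
        emit("scan_results", pd.concat(tables, ignore_index=True))
        log.write(f"scan: {len(outcomes.exclusions)} samples excluded from log outcomes")

    definition = grs.ScoreDefinition(
        config.score,
        [grs.SnpDefinition(s.rsid, "A", "G", s.raf) for s in sim.snps],
    )
    oriented, harm_report = grs.harmonize_alleles(genotypes, definition)
    score = grs.build_score(oriented, definition)
    if "score" in config.stages:
        emit("score", score.to_frame(), index=True)
        emit("harmonization_report", harm_report)
        summ = grs.score_summary(score)
        log.write(f"score: mean={summ['mean']:.3f} sd={summ['sd']:.3f} "
                  f"excluded={summ['n_excluded']}")

    mr_rows = []
    if "mr" in config.stages:
        cov = cohort[list(config.covariates)]
        inc = score.included
        exp_assoc = mr.fit_iv_assoc(score.score[inc], cohort["exposure"].to_numpy()[inc],
                                    covariates=cov[inc], role="exposure")
        for met in metabolites.columns:
            met_assoc = mr.fit_iv_assoc(score.score[inc], metabolites[met].to_numpy()[inc],
                                        covariates=cov[inc], role="metabolite")
            res = mr.wald_ratio(met_assoc, exp_assoc, study="discovery")
            mr_rows.append({"metabolite": met, **res.to_dict()})
        emit("mr_results", pd.DataFrame(mr_rows))
        log.write(f"mr: {len(mr_rows)} Wald ratios, instrument beta "
                  f"{exp_assoc.beta:.4f} (se {exp_assoc.se:.4f})")

    if "sens" in config.stages:
        exp_stats = simdata.simulate_summary_stats(sim, config.n_gwas_exposure,
                                                   role="exposure", seed=config.seed + 2)
        out_stats = simdata.simulate_summary_stats(sim, config.n_gwas_outcome,
                                                   role="outcome", seed=config.seed + 3)
        write_summary_stats(exp_stats, out / "summary_exposure.tsv")
        write_summary_stats(out_stats, out / "summary_outcome.tsv")
        model = sensitivity.SnpSummaryMR.from_frames(exp_stats, out_stats)
        rows = [model.fit(m).to_dict() for m in ("ivw", "egger", "likelihood")]
        emit("sensitivity_results", pd.DataFrame(rows))
        diag = model.diagnostics()
        emit("scatter", diag["scatter"])
        emit("funnel", diag["funnel"])
        emit("leave_one_out", diag["leave_one_out"])
        log.write("sens: ivw/egger/likelihood + diagnostics written")

    if "meta" in config.stages and mr_rows:
        first = mr_rows[0]
        discovery = mr.MRResult(
            beta=first["beta"], se=first["se"], ci=(first["ci_low"], first["ci_high"]),
            p=first["p"], method="wald", study="discovery")
        # an independent replication draw of the same design
        rep_g = simdata.simulate_genotypes(sim.rafs, sim.n_individuals,
                                           seed=config.seed + 11, snp_ids=sim.snp_ids)
        rep_cohort, rep_mets = simdata.simulate_cohort(rep_g, sim.with_(seed=config.seed + 11))
        rep_oriented, _ = grs.harmonize_alleles(rep_g, definition)
        rep_score = grs.build_score(rep_oriented, definition)
        e2 = mr.fit_iv_assoc(rep_score.score, rep_cohort["exposure"].to_numpy(), role="exposure")
        m2 = mr.fit_iv_assoc(rep_score.score, rep_mets.iloc[:, 0].to_numpy(), role="metabolite")
        replication = mr.wald_ratio(m2, e2, study="replication")
        pooled = mr.meta_fixed([discovery, replication])
        emit("meta_results", pd.DataFrame([discovery.to_dict(), replication.to_dict(),
                                           pooled.to_dict()]))
        log.write(f"meta: pooled beta {pooled.beta:.4f} (se {pooled.se:.4f})")

    log.flush()
    written["log"] = log.path
    return written
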