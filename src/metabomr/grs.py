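"""Additive unweighted genetic risk scores.

A score is the per-individual sum of risk-allele dosages over a defined SNP
set.  Construction follows strict availability rules:

* dosages are first oriented so they count the risk allele
  (``harmonize_alleles``), with palindromic (A/T, C/G) SNPs resolved by
  comparing the observed allele frequency with the declared one;
* a score SNP absent from the genotype data contributes the constant
  2 x risk-allele-frequency (reference-panel imputation) for everyone;
* an individual missing exactly one genotyped score SNP has it replaced by
  that SNP's sample-mean dosage;
* individuals missing more than one genotyped score SNP are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import HarmonizationError, InvalidParameterError, StructuralError
from .simdata import GenotypeMatrix

__all__ = ["SnpDefinition", "ScoreDefinition", "ScoreVector",
           "harmonize_alleles", "build_score", "score_summary"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass(frozen=True)
class SnpDefinition:
    """One score SNP: alleles, reference frequency and availability route."""

    rsid: str
    risk_allele: str
    other_allele: str
    raf: float
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    availability: str = "genotyped"  # genotyped | proxy | frequency-imputed

    def __post_init__(self):
        if self.risk_allele.upper() == self.other_allele.upper():
            raise InvalidParameterError(f"{self.rsid}: risk and other allele identical")
        if not 0.0 < self.raf < 1.0:
            raise InvalidParameterError(f"{self.rsid}: RAF must be in (0,1)")
        if self.proxy_rsid is not None and (self.proxy_r2 is None or self.proxy_r2 <= 0.8):
            raise InvalidParameterError(
                f"{self.rsid}: proxy SNPs require linkage disequilibrium r2 > 0.8"
            )


@dataclass
class ScoreDefinition:
    """The SNP list defining an additive unweighted risk score."""

    name: str
    snps: list[SnpDefinition]

    def __post_init__(self):
        ids = [s.rsid for s in self.snps]
        if len(set(ids)) != len(ids):
            raise StructuralError(f"duplicate rsids in score definition {self.name}")

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rsid": s.rsid, "risk_allele": s.risk_allele, "other_allele": s.other_allele,
                 "raf": s.raf, "proxy_rsid": s.proxy_rsid, "proxy_r2": s.proxy_r2,
                 "availability": s.availability}
                for s in self.snps
            ]
        )

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "ScoreDefinition":
        snps = []
        for r in frame.itertuples():
            proxy = None if pd.isna(getattr(r, "proxy_rsid", None)) else r.proxy_rsid
            r2 = None if pd.isna(getattr(r, "proxy_r2", None)) else float(r.proxy_r2)
            snps.append(SnpDefinition(
                rsid=r.rsid, risk_allele=r.risk_allele, other_allele=r.other_allele,
                raf=float(r.raf), proxy_rsid=proxy, proxy_r2=r2,
                availability=getattr(r, "availability", "genotyped"),
            ))
        return cls(name=name, snps=snps)


@dataclass
class ScoreVector:
    """Per-sample score values with missingness bookkeeping."""

    sample_ids: list[str]
    score: np.ndarray
    n_missing_snps: np.ndarray
    included: np.ndarray
    n_snps: int
    constant_contribution: float = 0.0
    per_snp_missing: pd.Series = field(default_factory=pd.Series)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "score": self.score,
             "n_missing_snps": self.n_missing_snps, "included": self.included}
        ).set_index("sample_id")

    @property
    def values(self) -> np.ndarray:
        """Scores of included samples only."""
        return self.score[self.included]


def harmonize_alleles(
    g: GenotypeMatrix,
    definition: ScoreDefinition,
    ambiguity_window: float = 0.08,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Orient dosages to count each SNP's risk allele.

    The genotype matrix must declare which allele its dosage counts.  A
    dosage counting the other allele is flipped d -> 2-d.  Incompatible
    allele sets raise a harmonization error naming the SNP.  Palindromic
    (A/T, C/G) SNPs are resolved by comparing the observed allele frequency
    with the declared RAF; when either frequency lies within
    ``ambiguity_window`` of 0.5 the strand is unresolvable and the SNP is
    excluded, with a report row.
    """
    if g.counted_allele is None:
        raise HarmonizationError("genotype matrix does not declare counted alleles")
    dosage = g.dosage.copy()
    keep = np.ones(len(g.snp_ids), dtype=bool)
    counted = dict(g.counted_allele)
    others = dict(g.other_allele or {})
    rows = []
    defs = {s.rsid: s for s in definition.snps}
    for j, rsid in enumerate(g.snp_ids):
        if rsid not in defs:
            continue  # extra SNPs in the file are left untouched
        d = defs[rsid]
        file_a = counted[rsid].upper()
        file_b = others.get(rsid, "").upper()
        risk, other = d.risk_allele.upper(), d.other_allele.upper()
        file_set = {file_a, file_b} if file_b else {file_a}
        direct = file_set <= {risk, other}
        flipped_set = {_COMPLEMENT.get(a, "?") for a in file_set}
        strand = flipped_set <= {risk, other}
        if not direct and not strand:
            raise HarmonizationError(
                f"{rsid}: file alleles {sorted(file_set)} incompatible with "
                f"definition {risk}/{other}"
            )
        if _is_palindromic(risk, other):
            col = dosage[:, j]
            f_file = np.nanmean(col) / 2.0
            if abs(f_file - 0.5) < ambiguity_window or abs(d.raf - 0.5) < ambiguity_window:
                keep[j] = False
                rows.append({"rsid": rsid, "action": "excluded_palindromic",
                             "file_freq": f_file, "raf": d.raf})
                continue
            # orient by whichever of (raf, 1-raf) the observed frequency matches
            if abs(f_file - d.raf) <= abs(f_file - (1.0 - d.raf)):
                rows.append({"rsid": rsid, "action": "kept_frequency_match",
                             "file_freq": f_file, "raf": d.raf})
            else:
                dosage[:, j] = 2.0 - dosage[:, j]
                counted[rsid], others[rsid] = risk, other
                rows.append({"rsid": rsid, "action": "flipped_frequency",
                             "file_freq": f_file, "raf": d.raf})
            continue
        effective_a = file_a if direct else _COMPLEMENT[file_a]
        if effective_a == other:
            dosage[:, j] = 2.0 - dosage[:, j]
            counted[rsid], others[rsid] = d.risk_allele, d.other_allele
            rows.append({"rsid": rsid, "action": "flipped", "file_freq": np.nan, "raf": d.raf})
        else:
            counted[rsid], others[rsid] = d.risk_allele, d.other_allele
            rows.append({"rsid": rsid, "action": "unchanged", "file_freq": np.nan, "raf": d.raf})

    snp_ids = [s for s, k in zip(g.snp_ids, keep) if k]
    out = GenotypeMatrix(
        list(g.sample_ids), snp_ids, dosage[:, keep],
        counted_allele={s: counted[s] for s in snp_ids},
        other_allele={s: others[s] for s in snp_ids if s in others},
    )
    report = pd.DataFrame(rows, columns=["rsid", "action", "file_freq", "raf"])
    return out, report


def build_score(
    g: GenotypeMatrix,
    definition: ScoreDefinition,
    call_rate_warn: float = 0.95,
) -> ScoreVector:
    """Sum risk-allele dosages into an additive unweighted score.

    Availability rules: score SNPs absent from the genotype data contribute
    the constant 2 x RAF to every individual; one missing genotyped value is
    mean-imputed from the sample; more than one missing value excludes the
    individual.  Frequency-imputed SNPs are constants and do not count
    toward the missingness rule.  A genotyped SNP with call rate at or
    below ``call_rate_warn`` triggers a warning naming it.
    """
    present = [s for s in definition.snps if s.rsid in g.snp_ids]
    absent = [s for s in definition.snps if s.rsid not in g.snp_ids]
    constant = float(sum(2.0 * s.raf for s in absent))

    n = g.n_samples
    if present:
        idx = [g.snp_ids.index(s.rsid) for s in present]
        D = g.dosage[:, idx]
        miss = np.isnan(D)
        call_rates = 1.0 - miss.mean(axis=0)
        for s, cr in zip(present, call_rates):
            if cr <= call_rate_warn:
                warnings.warn(
                    f"SNP {s.rsid} call rate {cr:.3f} <= {call_rate_warn:.0%}", stacklevel=2
                )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            snp_means = np.nanmean(D, axis=0)
        if np.isnan(snp_means).any():
            bad = [present[j].rsid for j in np.where(np.isnan(snp_means))[0]]
            raise StructuralError(f"SNPs with no observed genotypes: {bad}")
        n_missing = miss.sum(axis=1)
        filled = np.where(miss, snp_means, D)
        score = filled.sum(axis=1) + constant
        included = n_missing <= 1
        score[~included] = np.nan
        per_snp = pd.Series(miss.sum(axis=0), index=[s.rsid for s in present])
    else:
        n_missing = np.zeros(n, dtype=int)
        score = np.full(n, constant)
        included = np.ones(n, dtype=bool)
        per_snp = pd.Series(dtype=int)

    return ScoreVector(
        sample_ids=list(g.sample_ids), score=score, n_missing_snps=n_missing,
        included=included, n_snps=len(definition.snps),
        constant_contribution=constant, per_snp_missing=per_snp,
    )


def score_summary(sv: ScoreVector) -> dict:
    """Call-rate and distribution report for a built score."""
    vals = sv.values
    return {
        "n_samples": len(sv.sample_ids),
        "n_excluded": int((~sv.included).sum()),
        "n_snps": sv.n_snps,
        "constant_contribution": sv.constant_contribution,
        "mean": float(vals.mean()) if vals.size else np.nan,
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        "per_snp_missing": sv.per_snp_missing.to_dict(),
    }
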