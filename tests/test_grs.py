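"""Risk-score construction: harmonization, imputation and exclusion rules."""

import numpy as np
import pytest

from metabomr import grs, simdata
from metabomr.exceptions import HarmonizationError
from metabomr.grs import ScoreDefinition, SnpDefinition
from metabomr.simdata import GenotypeMatrix


def _matrix(dosage, snp_ids, counted, other=None):
    n = np.asarray(dosage).shape[0]
    return GenotypeMatrix([f"s{i}" for i in range(n)], snp_ids,
                          np.asarray(dosage, dtype=float),
                          counted_allele=counted, other_allele=other or {})


def _definition(rsids, risk="A", other="G", raf=0.3):
    return ScoreDefinition("test", [SnpDefinition(r, risk, other, raf) for r in rsids])


class TestHarmonize:
    def test_counting_other_allele_flips(self):
        g = _matrix([[2.0], [1.0], [0.0]], ["rs1"], {"rs1": "G"}, {"rs1": "A"})
        out, report = grs.harmonize_alleles(g, _definition(["rs1"]))
        np.testing.assert_array_equal(out.dosage[:, 0], [0.0, 1.0, 2.0])
        assert report["action"].iloc[0] == "flipped"

    def test_already_oriented_unchanged(self):
        g = _matrix([[2.0], [1.0]], ["rs1"], {"rs1": "A"}, {"rs1": "G"})
        out, report = grs.harmonize_alleles(g, _definition(["rs1"]))
        np.testing.assert_array_equal(out.dosage[:, 0], [2.0, 1.0])
        assert report["action"].iloc[0] == "unchanged"

    def test_incompatible_alleles_raise_naming_snp(self):
        g = _matrix([[1.0]], ["rs1"], {"rs1": "A"}, {"rs1": "C"})
        with pytest.raises(HarmonizationError, match="rs1"):
            grs.harmonize_alleles(g, _definition(["rs1"]))  # definition is A/G

    def test_palindromic_near_half_frequency_excluded(self):
        # file frequency 0.48 cannot discriminate strands; RAF 0.10 declared
        rng = np.random.default_rng(0)
        dos = rng.binomial(2, 0.48, size=(2000, 1)).astype(float)
        g = _matrix(dos, ["rs_pal"], {"rs_pal": "A"}, {"rs_pal": "T"})
        defn = ScoreDefinition("t", [SnpDefinition("rs_pal", "A", "T", 0.10)])
        out, report = grs.harmonize_alleles(g, defn)
        assert "rs_pal" not in out.snp_ids
        assert report["action"].iloc[0] == "excluded_palindromic"

    def test_palindromic_clear_frequency_oriented(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.9, size=(2000, 1)).astype(float)  # file counts non-risk
        g = _matrix(dos, ["rs_pal"], {"rs_pal": "A"}, {"rs_pal": "T"})
        defn = ScoreDefinition("t", [SnpDefinition("rs_pal", "A", "T", 0.10)])
        out, report = grs.harmonize_alleles(g, defn)
        assert report["action"].iloc[0] == "flipped_frequency"
        assert abs(np.mean(out.dosage) / 2 - 0.1) < 0.03


class TestBuildScore:
    def test_plain_sum(self):
        g = _matrix([[2.0, 1.0, 0.0]], ["rs1", "rs2", "rs3"],
                    {f"rs{i}": "A" for i in (1, 2, 3)})
        sv = grs.build_score(g, _definition(["rs1", "rs2", "rs3"]))
        assert sv.score[0] == pytest.approx(3.0)
        assert sv.included[0]

    def test_single_missing_mean_imputed(self):
        # sample-mean dosage of rs3 over observed individuals is 1.2
        dos = [[2.0, 1.0, np.nan],
               [1.0, 1.0, 2.0],
               [0.0, 2.0, 2.0],
               [2.0, 0.0, 1.0],
               [1.0, 1.0, 0.0],
               [0.0, 2.0, 1.0]]
        g = _matrix(dos, ["rs1", "rs2", "rs3"], {f"rs{i}": "A" for i in (1, 2, 3)})
        sv = grs.build_score(g, _definition(["rs1", "rs2", "rs3"]))
        assert sv.score[0] == pytest.approx(2.0 + 1.0 + 1.2)
        assert sv.n_missing_snps[0] == 1 and sv.included[0]

    def test_ungenotyped_snp_contributes_2raf(self):
        g = _matrix([[2.0], [0.0]], ["rs1"], {"rs1": "A"})
        defn = ScoreDefinition("t", [
            SnpDefinition("rs1", "A", "G", 0.5),
            SnpDefinition("rs_absent", "A", "G", 0.3, availability="frequency-imputed"),
        ])
        sv = grs.build_score(g, defn)
        np.testing.assert_allclose(sv.score, [2.6, 0.6])
        assert sv.constant_contribution == pytest.approx(0.6)

    def test_more_than_one_missing_excludes(self):
        dos = [[np.nan, np.nan, 1.0], [1.0, 1.0, 1.0]]
        g = _matrix(dos, ["rs1", "rs2", "rs3"], {f"rs{i}": "A" for i in (1, 2, 3)})
        sv = grs.build_score(g, _definition(["rs1", "rs2", "rs3"]))
        assert not sv.included[0] and np.isnan(sv.score[0])
        assert sv.included[1]

    def test_low_call_rate_warns(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        dos[:10, 0] = np.nan  # call rate 0.90
        g = _matrix(dos, ["rs1"], {"rs1": "A"})
        with pytest.warns(UserWarning, match="rs1"):
            grs.build_score(g, _definition(["rs1"]))

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
        ids = ["rs1", "rs2", "rs3"]
        g1 = _matrix(dos, ids, {r: "A" for r in ids})
        perm = [2, 0, 1]
        g2 = _matrix(dos[:, perm], [ids[j] for j in perm], {r: "A" for r in ids})
        d = _definition(ids)
        np.testing.assert_allclose(grs.build_score(g1, d).score,
                                   grs.build_score(g2, d).score)

    def test_mean_imputation_preserves_snp_mean(self):
        rng = np.random.default_rng(4)
        dos = rng.binomial(2, 0.4, size=(200, 2)).astype(float)
        dos[rng.choice(200, 10, replace=False), 0] = np.nan
        g = _matrix(dos, ["rs1", "rs2"], {"rs1": "A", "rs2": "A"})
        sv = grs.build_score(g, _definition(["rs1", "rs2"]))
        observed_mean = np.nanmean(dos[:, 0])
        imputed_col = np.where(np.isnan(dos[:, 0]), observed_mean, dos[:, 0])
        assert imputed_col.mean() == pytest.approx(observed_mean)
        np.testing.assert_allclose(sv.score, imputed_col + dos[:, 1])


class TestScoreSummary:
    def test_counts_and_expectation(self):
        cfg = simdata.SimConfig.insulin_resistance(n_individuals=20_000, seed=9)
        rafs = [0.5] * 10
        g = simdata.simulate_genotypes(rafs, 20_000, seed=9)
        defn = ScoreDefinition("t", [SnpDefinition(s, "A", "G", 0.5) for s in g.snp_ids])
        sv = grs.build_score(g, defn)
        summ = grs.score_summary(sv)
        assert summ["n_excluded"] == 0
        assert abs(summ["mean"] - 10.0) < 0.1  # expectation 2*sum(f) = 10
        del cfg

    def test_exclusion_counted(self):
        dos = np.ones((3, 3))
        dos[0, :2] = np.nan
        g = _matrix(dos, ["rs1", "rs2", "rs3"], {f"rs{i}": "A" for i in (1, 2, 3)})
        sv = grs.build_score(g, _definition(["rs1", "rs2", "rs3"]))
        assert grs.score_summary(sv)["n_excluded"] == 1

    def test_score_recovers_average_per_allele_effect(self):
        cfg = simdata.SimConfig.insulin_resistance(n_individuals=20_000, seed=10)
        g = simdata.simulate_genotypes(cfg.rafs, cfg.n_individuals, seed=10,
                                       snp_ids=cfg.snp_ids)
        cohort, _ = simdata.simulate_cohort(g, cfg)
        from metabomr import mr
        fit = mr.fit_iv_assoc(g.dosage.sum(axis=1), cohort["exposure"].to_numpy())
        expected = np.mean(cfg.effects) / cfg.exposure_sd_raw()
        assert abs(fit.beta - expected) < 3 * fit.se
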