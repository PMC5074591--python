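"""Per-SNP sensitivity estimators against oracles and algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr import sensitivity as sens
from metabomr.exceptions import StructuralError
from metabomr.sensitivity import SnpPair, SnpSummaryMR


def _random_pairs(rng, j=10, theta=0.5, sx_scale=0.05, sy_scale=0.05):
    bx_true = rng.uniform(0.05, 0.3, j)
    sx = rng.uniform(0.5, 1.5, j) * sx_scale
    sy = rng.uniform(0.5, 1.5, j) * sy_scale
    bx = rng.normal(bx_true, sx)
    by = rng.normal(theta * bx_true, sy)
    return [SnpPair(f"rs{i}", bx[i], sx[i], by[i], sy[i]) for i in range(j)]


def grid_profile_oracle(pairs, lo=-5.0, hi=5.0, rounds=6, points=2001):
    """Independent coarse-grid + refinement maximizer of the profile likelihood."""
    bx = np.array([p.bx for p in pairs])
    sx = np.array([p.sx for p in pairs])
    by = np.array([p.by for p in pairs])
    sy = np.array([p.sy for p in pairs])

    def neg2ll(thetas):
        t = thetas[:, None]
        return np.sum((by - t * bx) ** 2 / (sy**2 + t**2 * sx**2), axis=1)

    for _ in range(rounds):
        grid = np.linspace(lo, hi, points)
        vals = neg2ll(grid)
        i = int(np.argmin(vals))
        width = grid[1] - grid[0]
        lo, hi = grid[i] - 2 * width, grid[i] + 2 * width
    return float(grid[i])


class TestPerSnpRatios:
    def test_direct_arithmetic(self):
        r = sens.per_snp_ratios([SnpPair("a", 0.2, 0.01, 0.1, 0.05)])
        assert r["estimate"].iloc[0] == pytest.approx(0.5)
        assert r["se"].iloc[0] == pytest.approx(0.25)

    def test_zero_outcome_gives_zero_ratio(self):
        r = sens.per_snp_ratios([SnpPair("a", 0.2, 0.01, 0.0, 0.05)])
        assert r["estimate"].iloc[0] == 0.0

    def test_orientation_invariance(self):
        a = sens.per_snp_ratios([SnpPair("a", 0.2, 0.01, 0.1, 0.05)])
        b = sens.per_snp_ratios([SnpPair("a", -0.2, 0.01, -0.1, 0.05)])
        assert a["estimate"].iloc[0] == pytest.approx(b["estimate"].iloc[0])
        assert a["se"].iloc[0] == pytest.approx(b["se"].iloc[0])

    def test_zero_exposure_snp_excluded(self):
        r = sens.per_snp_ratios([SnpPair("a", 0.0, 0.01, 0.1, 0.05),
                                 SnpPair("b", 0.2, 0.01, 0.1, 0.05)])
        assert list(r["rsid"]) == ["b"]
        assert r.attrs["excluded"] == ["a"]


class TestIVW:
    def test_consensus_value(self):
        pairs = [SnpPair(f"r{i}", b, 0.01, 0.5 * b, 0.02) for i, b in
                 enumerate([0.1, 0.2, 0.3])]
        assert sens.ivw(pairs).estimate == pytest.approx(0.5)

    def test_three_snp_hand_weighted_sum(self):
        pairs = [SnpPair("a", 0.1, 0.01, 0.05, 0.02),
                 SnpPair("b", 0.2, 0.01, 0.10, 0.02),
                 SnpPair("c", 0.3, 0.01, 0.15, 0.02)]
        assert sens.ivw(pairs).estimate == pytest.approx(0.5)

    def test_identity_with_pooled_per_snp_ratios(self):
        rng = np.random.default_rng(0)
        for rep in range(20):
            pairs = _random_pairs(rng)
            fit = sens.ivw(pairs)
            ratios = sens.per_snp_ratios(pairs)
            w = 1.0 / ratios["se"] ** 2
            pooled = np.sum(w * ratios["estimate"]) / np.sum(w)
            pooled_se = float(np.sum(w) ** -0.5)
            assert fit.estimate == pytest.approx(pooled, abs=1e-12)
            assert fit.se == pytest.approx(pooled_se, abs=1e-12)

    def test_fewer_than_two_snps_errors(self):
        with pytest.raises(StructuralError):
            sens.ivw([SnpPair("a", 0.2, 0.01, 0.1, 0.05)])


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = [SnpPair(f"r{i}", bx[i], 0.01, 0.02 + 0.5 * bx[i], 0.03)
                 for i in range(4)]
        fit = sens.egger(pairs)
        assert fit.intercept == pytest.approx(0.02, abs=1e-12)
        assert fit.estimate == pytest.approx(0.5, abs=1e-12)

    def test_constrained_intercept_reproduces_ivw(self):
        # WLS through the origin with weights 1/sy^2 IS the IVW estimator
        rng = np.random.default_rng(1)
        pairs = _random_pairs(rng)
        bx = np.array([p.bx for p in pairs])
        by = np.array([p.by for p in pairs])
        sy = np.array([p.sy for p in pairs])
        w = 1.0 / sy**2
        slope_origin = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert sens.ivw(pairs).estimate == pytest.approx(slope_origin, abs=1e-12)

    def test_reorientation_invariance(self):
        rng = np.random.default_rng(2)
        pairs = _random_pairs(rng)
        flipped = [SnpPair(p.rsid, -p.bx, p.sx, -p.by, p.sy) for p in pairs]
        a, b = sens.egger(pairs), sens.egger(flipped)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.intercept == pytest.approx(b.intercept)

    def test_intercept_recovers_directional_pleiotropy(self):
        # constant direct effects d=0.05 with no causal effect; InSIDE holds
        rng = np.random.default_rng(3)
        intercepts, slopes = [], []
        for _ in range(300):
            j = 10
            bx_true = rng.uniform(0.05, 0.3, j)
            sy = np.full(j, 0.02)
            pairs = [SnpPair(f"r{i}", bx_true[i], 1e-6,
                             rng.normal(0.05, sy[i]), sy[i]) for i in range(j)]
            fit = sens.egger(pairs)
            intercepts.append(fit.intercept)
            slopes.append(fit.estimate)
        mc = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts) - 0.05) < 3 * mc
        mc_s = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * mc_s

    def test_needs_three_snps(self):
        with pytest.raises(StructuralError):
            sens.egger([SnpPair("a", 0.1, 0.01, 0.1, 0.02),
                        SnpPair("b", 0.2, 0.01, 0.1, 0.02)])


class TestLikelihood:
    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(4)
        for rep in range(100):
            pairs = _random_pairs(rng, theta=rng.uniform(-1, 1))
            fit = sens.likelihood_mr(pairs)
            oracle = grid_profile_oracle(pairs)
            assert fit.estimate == pytest.approx(oracle, abs=1e-6)

    def test_sx_zero_limit_equals_ivw(self):
        rng = np.random.default_rng(5)
        pairs = _random_pairs(rng, sx_scale=1e-9)
        assert sens.likelihood_mr(pairs).estimate == pytest.approx(
            sens.ivw(pairs).estimate, abs=1e-6)

    def test_exact_proportional_data(self):
        pairs = [SnpPair(f"r{i}", b, 0.01, 0.7 * b, 0.02) for i, b in
                 enumerate([0.1, 0.2, 0.3])]
        assert sens.likelihood_mr(pairs).estimate == pytest.approx(0.7, abs=1e-8)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        pairs = [SnpPair(f"r{i}", b, 0.01, 0.5 * b, 0.02) for i, b in
                 enumerate([0.1, 0.2, 0.4])]
        q, df, p = sens.cochran_q(pairs)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_mean_equals_df_under_homogeneity(self):
        rng = np.random.default_rng(6)
        qs = []
        for _ in range(500):
            j = 10
            bx = rng.uniform(0.1, 0.3, j)
            sy = np.full(j, 0.02)
            by = rng.normal(0.5 * bx, sy)
            pairs = [SnpPair(f"r{i}", bx[i], 1e-9, by[i], sy[i]) for i in range(j)]
            qs.append(sens.cochran_q(pairs)[0])
        mc = np.std(qs, ddof=1) / np.sqrt(len(qs))
        assert abs(np.mean(qs) - 9.0) < 3 * mc

    def test_single_outlier_bound(self):
        j = 5
        pairs = [SnpPair(f"r{i}", 0.2, 0.01, 0.1, 0.02) for i in range(j - 1)]
        # one ratio displaced by 10 of its standard errors
        pairs.append(SnpPair("out", 0.2, 0.01, 0.1 + 10 * 0.02, 0.02))
        q, df, _ = sens.cochran_q(pairs)
        assert q >= 100 * (j - 1) / j


class TestDiagnostics:
    def test_cardinality_and_positivity(self):
        rng = np.random.default_rng(7)
        pairs = _random_pairs(rng, j=8)
        d = sens.diagnostics(pairs)
        assert len(d["scatter"]) == 8 and len(d["funnel"]) == 8
        assert (d["funnel"]["precision"] > 0).all()
        assert len(d["leave_one_out"]) == 8

    def test_funnel_precision_orientation_invariant(self):
        rng = np.random.default_rng(8)
        pairs = _random_pairs(rng, j=6)
        flipped = [SnpPair(p.rsid, -p.bx, p.sx, -p.by, p.sy) for p in pairs]
        a = sens.diagnostics(pairs)["funnel"]["precision"]
        b = sens.diagnostics(flipped)["funnel"]["precision"]
        np.testing.assert_allclose(a, b)

    def test_leave_one_out_moves_estimate_for_outlier(self):
        pairs = [SnpPair(f"r{i}", 0.2, 0.01, 0.1, 0.02) for i in range(5)]
        pairs.append(SnpPair("out", 0.2, 0.01, 0.5, 0.02))
        loo = sens.diagnostics(pairs)["leave_one_out"]
        without_out = loo.loc[loo["excluded_rsid"] == "out", "estimate"].iloc[0]
        assert without_out == pytest.approx(0.5)  # 0.1/0.2 consensus


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(0.2, 5.0), st.integers(0, 10_000))
def test_estimator_scale_equivariance(c, seed):
    """Scaling every (bx, sx) by c scales all causal estimates by 1/c."""
    rng = np.random.default_rng(seed)
    pairs = _random_pairs(rng)
    scaled = [SnpPair(p.rsid, c * p.bx, c * p.sx, p.by, p.sy) for p in pairs]
    assert sens.ivw(scaled).estimate == pytest.approx(sens.ivw(pairs).estimate / c)
    assert sens.egger(scaled).estimate == pytest.approx(sens.egger(pairs).estimate / c)
    assert sens.likelihood_mr(scaled).estimate == pytest.approx(
        sens.likelihood_mr(pairs).estimate / c, abs=1e-5, rel=1e-4)
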