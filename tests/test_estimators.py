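"""Univariable estimators against closed forms and generic WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from tsmr import (
    effect_to_or,
    ivw,
    ivw_headline,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_hset


class TestWald:
    def test_direct_ratio(self):
        res = wald_ratio(bx=0.2, sex=0.01, by=0.1, sey=0.02)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        res = wald_ratio(bx=0.2, sex=0.01, by=0.0, sey=0.02)
        assert res.beta == 0.0 and res.pval == 1.0

    def test_ratio_oracle(self):
        assert wald_ratio(0.033, 0.01, 0.0406, 0.02).beta == pytest.approx(
            0.0406 / 0.033
        )
        assert wald_ratio(0.033, 0.01, 0.0406, 0.02).beta == pytest.approx(1.230, abs=5e-4)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIvw:
    def test_collinear_ratios_give_exact_slope_and_zero_q(self):
        h = make_hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.01)
        fixed, mre = ivw(h)
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.extra["q"] == pytest.approx(0.0, abs=1e-20)
        assert fixed.se == mre.se

    def test_weighted_regression_through_origin(self, three_snp_hset):
        fixed, _ = ivw(three_snp_hset)
        # Hand-derived: equal weights, beta = sum(bx*by)/sum(bx^2).
        assert fixed.beta == pytest.approx(0.062 / 0.14)

    def test_se_scales_with_outcome_se(self, three_snp_hset):
        fixed, _ = ivw(three_snp_hset)
        h10 = make_hset([0.1, 0.2, 0.3], [0.06, 0.10, 0.12], 0.1)
        fixed10, _ = ivw(h10)
        assert fixed10.beta == pytest.approx(fixed.beta)
        assert fixed10.se == pytest.approx(10 * fixed.se)

    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.2], [0.1], 0.02)
        fixed, mre = ivw(h)
        w = wald_ratio(0.2, 0.01, 0.1, 0.02)
        assert fixed.beta == pytest.approx(w.beta) and fixed.se == pytest.approx(w.se)
        assert mre.se == pytest.approx(w.se)

    def test_matches_wls_origin_oracle(self):
        rng = np.random.default_rng(3)
        bx = rng.normal(0.05, 0.02, 15)
        by = 0.3 * bx + rng.normal(0, 0.01, 15)
        sey = rng.uniform(0.005, 0.02, 15)
        h = make_hset(bx, by, sey)
        fixed, _ = ivw(h)
        oracle = sm.WLS(by, bx, weights=sey**-2).fit()
        assert fixed.beta == pytest.approx(oracle.params[0], abs=1e-10)

    def test_headline_picks_mre_under_heterogeneity(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.05, 0.02, 20)
        by = 0.3 * bx + rng.normal(0, 0.05, 20)  # overdispersed
        h = make_hset(bx, by, 0.01)
        fixed, mre = ivw(h)
        head = ivw_headline(h)
        assert head.method == "ivw_mre" and head.se == mre.se
        homogeneous = make_hset([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.01)
        assert ivw_headline(homogeneous).method == "ivw_fixed"


class TestEgger:
    def test_exact_linear_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.01 + 0.5 * bx
        h = make_hset(bx, by, 0.01)
        res = mr_egger(h)
        assert res.beta == pytest.approx(0.5)
        assert res.extra["intercept"] == pytest.approx(0.01)
        assert res.extra["sigma"] == 1.0  # residual-scale floor applies

    def test_orientation_invariance(self):
        rng = np.random.default_rng(7)
        bx = rng.normal(0.1, 0.03, 10)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.01, 10)
        h = make_hset(bx, by, 0.01)
        bx2, by2 = bx.copy(), by.copy()
        bx2[3] *= -1
        by2[3] *= -1
        h2 = make_hset(bx2, by2, 0.01)
        r1, r2 = mr_egger(h), mr_egger(h2)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-14)
        assert r1.extra["intercept"] == pytest.approx(r2.extra["intercept"], abs=1e-14)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(11)
        bx = np.abs(rng.normal(0.1, 0.05, 10))
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.02, 10)
        sey = rng.uniform(0.01, 0.03, 10)
        h = make_hset(bx, by, sey)
        res = mr_egger(h)
        oracle = sm.WLS(by, sm.add_constant(bx), weights=sey**-2).fit()
        assert res.extra["intercept"] == pytest.approx(oracle.params[0], abs=1e-10)
        assert res.beta == pytest.approx(oracle.params[1], abs=1e-10)
        # statsmodels scales SEs by the residual scale with no floor; when
        # that scale exceeds 1 the two parameterizations agree.
        if res.extra["sigma"] > 1:
            assert res.se == pytest.approx(oracle.bse[1], rel=1e-10)

    def test_zero_intercept_wls_reproduces_ivw(self, three_snp_hset):
        fixed, _ = ivw(three_snp_hset)
        oracle = sm.WLS(
            three_snp_hset.beta_outcome,
            three_snp_hset.beta_exposure,
            weights=three_snp_hset.se_outcome**-2.0,
        ).fit()
        assert fixed.beta == pytest.approx(oracle.params[0], abs=1e-12)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            mr_egger(make_hset([0.1, 0.2], [0.05, 0.1], 0.01))


def _brute_force_weighted_median(theta, w):
    """Independent re-derivation: scan the weighted CDF by explicit loop."""
    pairs = sorted(zip(theta, w))
    total = sum(wi for _, wi in pairs)
    cum = 0.0
    points = []
    for t, wi in pairs:
        cum += wi
        points.append((t, (cum - 0.5 * wi) / total))
    if points[0][1] >= 0.5:
        return points[0][0]
    for (t0, c0), (t1, c1) in zip(points, points[1:]):
        if c0 < 0.5 <= c1:
            return t0 + (t1 - t0) * (0.5 - c0) / (c1 - c0)
    return points[-1][0]


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        h = make_hset([0.1, 0.1, 0.1], [0.04, 0.05, 0.06], 0.01)
        res = weighted_median(h, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.5)

    def test_resists_minority_outliers(self):
        bx = np.array([0.2] * 7 + [0.05] * 3)
        by = np.array([0.1] * 7 + [0.1] * 3)  # ratios 0.5 vs 2.0
        h = make_hset(bx, by, 0.01)
        res = weighted_median(h, n_boot=500, seed=2)
        assert abs(res.beta - 0.5) < 0.05
        theta = by / bx
        w = bx**2 / 0.01**2
        assert res.beta == pytest.approx(
            _brute_force_weighted_median(theta, w), abs=1e-12
        )

    def test_order_invariance_and_seed_determinism(self):
        rng = np.random.default_rng(13)
        bx = rng.normal(0.1, 0.02, 9)
        by = 0.5 * bx + rng.normal(0, 0.01, 9)
        h = make_hset(bx, by, 0.01)
        perm = rng.permutation(9)
        hp = make_hset(bx[perm], by[perm], 0.01)
        r1 = weighted_median(h, n_boot=300, seed=5)
        r2 = weighted_median(hp, n_boot=300, seed=5)
        assert r1.beta == pytest.approx(r2.beta, abs=1e-12)
        r3 = weighted_median(h, n_boot=300, seed=5)
        assert r1.se == r3.se  # bit-identical under the same seed

    def test_joint_sign_flip_invariance(self):
        rng = np.random.default_rng(17)
        bx = rng.normal(0.1, 0.02, 8)
        by = 0.5 * bx + rng.normal(0, 0.01, 8)
        h1 = make_hset(bx, by, 0.01)
        h2 = make_hset(-bx, -by, 0.01)
        assert weighted_median(h1, n_boot=100, seed=3).beta == pytest.approx(
            weighted_median(h2, n_boot=100, seed=3).beta, abs=1e-12
        )


class TestWeightedMode:
    def test_point_mass(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, 0.7 * bx, 0.01)
        res = weighted_mode(h, n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.7)

    def test_majority_cluster_wins(self):
        bx = np.array([0.2] * 6 + [0.2] * 2)
        by = np.array([0.1] * 6 + [0.3] * 2)  # ratios 0.5 vs 1.5
        by = by + np.array([-0.002, -0.001, 0, 0.001, 0.002, 0.0, 0.0, 0.001])
        h = make_hset(bx, by, 0.01)
        res = weighted_mode(h, n_boot=100, seed=2)
        assert abs(res.beta - 0.5) < 0.1

    def test_grid_density_oracle(self):
        rng = np.random.default_rng(23)
        bx = np.abs(rng.normal(0.15, 0.03, 10))
        by = 0.5 * bx + rng.normal(0, 0.005, 10)
        h = make_hset(bx, by, 0.01)
        res = weighted_mode(h, n_boot=100, seed=4)
        theta = by / bx
        w = bx**2 / 0.01**2
        w = w / w.sum()
        sd = np.std(theta, ddof=1)
        mad = 1.4826 * np.median(np.abs(theta - np.median(theta)))
        hbw = 0.9 * min(sd, mad) * theta.size ** (-0.2)
        grid = np.linspace(theta.min(), theta.max(), 20_000)
        dens = sum(
            wj * np.exp(-0.5 * ((grid - tj) / hbw) ** 2) for tj, wj in zip(theta, w)
        )
        assert res.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-3)

    def test_large_bandwidth_limit_approaches_weighted_mean(self):
        rng = np.random.default_rng(29)
        bx = np.abs(rng.normal(0.15, 0.03, 12))
        by = 0.5 * bx + rng.normal(0, 0.01, 12)
        h = make_hset(bx, by, 0.01)
        res = weighted_mode(h, bandwidth_factor=1e4, n_boot=100, seed=5)
        theta = by / bx
        w = bx**2 / 0.01**2
        weighted_mean = float(np.sum(w * theta) / np.sum(w))
        grid_step = np.ptp(theta) / 2047
        assert abs(res.beta - weighted_mean) < max(5 * grid_step, 0.02)


class TestOrTransform:
    def test_published_effect_and_ci(self):
        or_, lo, hi = effect_to_or(0.162, ci=(0.090, 0.234))
        assert round(or_, 2) == 1.18
        assert round(lo, 2) == 1.09 and round(hi, 2) == 1.26

    def test_null_effect(self):
        assert effect_to_or(0.0, se=0.1)[0] == 1.0

    def test_se_route_matches_ci_route(self):
        se = (0.234 - 0.090) / (2 * 1.96)
        a = effect_to_or(0.162, se=se)
        b = effect_to_or(0.162, ci=(0.162 - 1.96 * se, 0.162 + 1.96 * se))
        assert a == pytest.approx(b)
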