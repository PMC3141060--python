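"""Winsorization, bootstrap and parametric PSA, quadrants, CEAC, ellipse."""

import numpy as np
import pytest
from scipy import stats

from trialcea import cea
from trialcea.cea import (ArmSummary, PSACloud, bootstrap_psa, bootstrap_trial,
                          ceac, ceac_limit, confidence_ellipse, icer_result,
                          incremental, parametric_psa, quadrant_probs,
                          threshold_exceed_probs, winsorize_p95)

# published arm-level summaries (lifetime cost $k, lifetime QALYs)
PAC_SUMMARY = ArmSummary(cost_mean_k=191.1, cost_sd_k=8.5,
                         qaly_mean=4.54, qaly_sd=0.21)
CVC_SUMMARY = ArmSummary(cost_mean_k=176.7, cost_sd_k=7.1,
                         qaly_mean=4.83, qaly_sd=0.21)


def _cloud(dc, de):
    return PSACloud(delta_cost=np.asarray(dc, float),
                    delta_effect=np.asarray(de, float))


class TestWinsorize:
    def test_values_above_p95_replaced(self):
        values = np.arange(1.0, 101.0)
        cap = np.percentile(values, 95)
        out = winsorize_p95(values)
        assert out.max() == cap
        assert np.array_equal(out[values <= cap], values[values <= cap])
        assert np.all(out[values > cap] == cap)

    def test_constant_vector_unchanged(self):
        assert np.array_equal(winsorize_p95(np.full(10, 7.0)), np.full(10, 7.0))

    def test_mean_never_increases(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = rng.lognormal(3, 1.5, rng.integers(5, 200))
            assert winsorize_p95(v).mean() <= v.mean() + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            winsorize_p95([])


class TestIncremental:
    @pytest.mark.parametrize("a, b, expected", [
        (191.1, 176.7, 14.4),   # lifetime cost
        (93.3, 84.4, 8.9),      # hospital cost
        (46.7, 35.2, 11.5),     # post-discharge cost
        (5.0, 5.0, 0.0),
    ])
    def test_difference(self, a, b, expected):
        assert incremental(a, b) == pytest.approx(expected)


class TestBootstrap:
    def _frame(self, n=120, seed=2):
        import pandas as pd
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "arm": ["PAC"] * n + ["CVC"] * n,
            "lifetime_cost": np.concatenate([
                rng.lognormal(12.0, 0.8, n), rng.lognormal(11.9, 0.8, n)]),
            "lifetime_qalys": np.concatenate([
                rng.normal(4.5, 2.0, n), rng.normal(4.8, 2.0, n)]),
        })

    def test_single_patient_arms_are_degenerate(self):
        import pandas as pd
        df = pd.DataFrame({"arm": ["PAC", "CVC"],
                           "lifetime_cost": [100000.0, 90000.0],
                           "lifetime_qalys": [4.0, 5.0]})
        cloud = bootstrap_psa(df, n_trials=50, seed=0)
        assert np.all(cloud.delta_cost == 10.0)
        assert np.all(cloud.delta_effect == -1.0)

    def test_seed_determinism(self):
        df = self._frame()
        a = bootstrap_psa(df, n_trials=300, seed=42)
        b = bootstrap_psa(df, n_trials=300, seed=42)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)
        c = bootstrap_psa(df, n_trials=300, seed=43)
        assert not np.array_equal(a.delta_cost, c.delta_cost)

    def test_mean_converges_to_winsorized_point_estimate(self):
        """Bootstrap mean incremental cost within 3 trial-SDs of the
        winsorized cohort incremental."""
        df = self._frame(n=200)
        cloud = bootstrap_psa(df, n_trials=5000, seed=7)
        point = {}
        for arm in ("PAC", "CVC"):
            costs = df.loc[df["arm"] == arm, "lifetime_cost"].to_numpy()
            point[arm] = winsorize_p95(costs).mean() / 1e3
        target = point["PAC"] - point["CVC"]
        assert abs(cloud.delta_cost.mean() - target) \
            < 3 * cloud.delta_cost.std()

    def test_empty_arm_rejected(self):
        df = self._frame().query("arm == 'PAC'")
        with pytest.raises(ValueError, match="empty"):
            bootstrap_psa(df, n_trials=10, seed=0)

    def test_single_trial_helper_matches_structure(self):
        rng = np.random.default_rng(0)
        out = bootstrap_trial(
            {"PAC": np.array([1000.0]), "CVC": np.array([2000.0])},
            {"PAC": np.array([1.0]), "CVC": np.array([2.0])}, rng)
        assert out["PAC"] == (1.0, 1.0)
        assert out["CVC"] == (2.0, 2.0)


class TestParametricPSA:
    def test_dominance_probability_matches_analytic_oracle(self):
        """P(costlier AND less effective) under independent normals equals
        Phi(dc/sd_dc) * Phi(-de/sd_de) within Monte-Carlo error."""
        cloud = parametric_psa(PAC_SUMMARY, CVC_SUMMARY, n_trials=5000, seed=3)
        p = quadrant_probs(cloud)["dominated"]
        sd_dc = np.hypot(8.5, 7.1)
        sd_de = np.hypot(0.21, 0.21)
        analytic = stats.norm.cdf(14.4 / sd_dc) * stats.norm.cdf(0.29 / sd_de)
        se = np.sqrt(analytic * (1 - analytic) / 5000)
        assert p == pytest.approx(analytic, abs=3 * se)

    def test_correlation_parameter_bounds(self):
        with pytest.raises(ValueError):
            parametric_psa(PAC_SUMMARY, CVC_SUMMARY, correlation=1.5)

    def test_determinism(self):
        a = parametric_psa(PAC_SUMMARY, CVC_SUMMARY, n_trials=100, seed=9)
        b = parametric_psa(PAC_SUMMARY, CVC_SUMMARY, n_trials=100, seed=9)
        assert np.array_equal(a.delta_cost, b.delta_cost)


class TestQuadrantsAndThresholds:
    def test_pure_dominated_cloud(self):
        cloud = _cloud([1.0] * 5, [-1.0] * 5)
        probs = quadrant_probs(cloud)
        assert probs["dominated"] == 1.0
        exceed = threshold_exceed_probs(cloud, [0.0, 50.0, 1e9])
        assert all(v == 1.0 for v in exceed.values())

    def test_symmetric_cloud_quarters(self):
        rng = np.random.default_rng(11)
        cloud = _cloud(rng.normal(0, 1, 40000), rng.normal(0, 1, 40000))
        probs = quadrant_probs(cloud)
        for key in probs:
            assert probs[key] == pytest.approx(0.25, abs=0.01)

    def test_quadrants_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            cloud = _cloud(rng.normal(0, 5, 321), rng.normal(0, 2, 321))
            assert sum(quadrant_probs(cloud).values()) == pytest.approx(1.0,
                                                                        abs=1e-12)

    def test_dominated_trials_exceed_every_threshold(self):
        rng = np.random.default_rng(8)
        cloud = _cloud(rng.normal(10, 5, 2000), rng.normal(-0.3, 0.3, 2000))
        dominated = (cloud.delta_cost > 0) & (cloud.delta_effect < 0)
        for lam in (0.0, 50.0, 100.0, 1000.0):
            nmb = lam * cloud.delta_effect - cloud.delta_cost
            assert np.all(nmb[dominated] < 0)


class TestCEAC:
    def test_dominant_cloud_is_always_acceptable(self):
        curve = ceac(_cloud([-1.0] * 4, [1.0] * 4), [0, 10, 100])
        assert np.all(curve.probability == 1.0)

    def test_value_at_zero_is_prob_cost_nonpositive(self):
        rng = np.random.default_rng(5)
        cloud = _cloud(rng.normal(3, 10, 5000), rng.normal(0, 1, 5000))
        curve = ceac(cloud, [0.0])
        assert curve.probability[0] == np.mean(cloud.delta_cost <= 0)

    def test_large_lambda_plateau_is_effect_positive_fraction(self):
        rng = np.random.default_rng(6)
        cloud = _cloud(rng.normal(3, 10, 5000), rng.normal(-0.1, 0.4, 5000))
        curve = ceac(cloud, [1e12])
        assert curve.probability[0] == pytest.approx(ceac_limit(cloud))
        assert ceac_limit(cloud) == np.mean(cloud.delta_effect > 0)

    def test_probabilities_bounded(self):
        rng = np.random.default_rng(7)
        cloud = _cloud(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        curve = ceac(cloud)
        assert np.all((curve.probability >= 0) & (curve.probability <= 1))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(_cloud([1.0], [1.0]), [])


class TestIcerResult:
    def test_dominated_has_no_icer(self):
        res = icer_result(_cloud([10.0] * 3, [-0.5] * 3))
        assert res.classification == "dominated"
        assert res.icer is None

    def test_dominant_has_no_icer(self):
        res = icer_result(_cloud([-10.0] * 3, [0.5] * 3))
        assert res.classification == "dominant"
        assert res.icer is None

    def test_tradeoff_reports_ratio(self):
        res = icer_result(_cloud([10.0] * 3, [0.5] * 3))
        assert res.classification == "tradeoff"
        assert res.icer == pytest.approx(20.0)


class TestConfidenceEllipse:
    def test_coverage_on_isotropic_normal_cloud(self):
        """Fraction of 50000 unit-normal points inside the 95% ellipse is
        0.95 +/- 0.005."""
        rng = np.random.default_rng(12)
        cloud = _cloud(rng.normal(0, 1, 50000), rng.normal(0, 1, 50000))
        ell = confidence_ellipse(cloud, 0.95)
        inside = ell.contains(cloud.delta_effect, cloud.delta_cost)
        assert inside.mean() == pytest.approx(0.95, abs=0.005)

    def test_level_zero_degenerates_to_mean_point(self):
        rng = np.random.default_rng(13)
        cloud = _cloud(rng.normal(5, 1, 100), rng.normal(-2, 1, 100))
        ell = confidence_ellipse(cloud, 0.0)
        assert ell.semi_axes == (0.0, 0.0)
        assert ell.center[0] == pytest.approx(cloud.delta_effect.mean())
        assert ell.center[1] == pytest.approx(cloud.delta_cost.mean())

    def test_rotation_equivariance(self):
        """Rotating the cloud rotates the ellipse orientation identically."""
        rng = np.random.default_rng(14)
        x = rng.normal(0, 3, 20000)
        y = 0.5 * x + rng.normal(0, 1, 20000)
        base = confidence_ellipse(_cloud(y, x), 0.95)
        phi = 0.7
        xr = np.cos(phi) * x - np.sin(phi) * y
        yr = np.sin(phi) * x + np.cos(phi) * y
        rotated = confidence_ellipse(_cloud(yr, xr), 0.95)
        diff = (rotated.orientation - base.orientation - phi) % np.pi
        assert min(diff, np.pi - diff) < 1e-6
        assert rotated.semi_axes == pytest.approx(base.semi_axes, rel=1e-9)

    def test_degenerate_covariance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            confidence_ellipse(_cloud([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]))
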