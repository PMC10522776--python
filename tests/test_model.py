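"""Model densities against hand algebra and dense-covariance oracles."""

import numpy as np
import pytest
from scipy import stats

import sexmort as sm
from sexmort.model import curve_log_prior, hyper_log_prior
from sexmort.obs_db import ObservationRecord


@pytest.fixture()
def curve():
    return sm.GlobalCurve("0-4", np.array([-3.0, -1.0]), np.array([0.20, 0.05]))


class TestExpectedSexRatio:
    def test_exact_at_knots(self, curve):
        assert sm.expected_sex_ratio(np.exp(-3.0), curve) == pytest.approx(np.exp(0.20))
        assert sm.expected_sex_ratio(np.exp(-1.0), curve) == pytest.approx(np.exp(0.05))

    def test_linear_interpolation_midpoint(self, curve):
        # midpoint of (-3, -1) in log q: value (0.20 + 0.05) / 2 = 0.125
        assert sm.expected_sex_ratio(np.exp(-2.0), curve) == pytest.approx(
            np.exp(0.125), rel=1e-10
        )
        assert np.exp(0.125) == pytest.approx(1.13315, abs=1e-5)

    def test_flat_extrapolation(self, curve):
        low = sm.expected_sex_ratio(np.exp(-5.0), curve)
        assert low == pytest.approx(np.exp(0.20), rel=1e-12)
        assert low == pytest.approx(1.22140, abs=1e-5)

    def test_invariant_under_collinear_knot(self, curve):
        refined = sm.GlobalCurve(
            "0-4", np.array([-3.0, -2.0, -1.0]), np.array([0.20, 0.125, 0.05])
        )
        q = np.exp(np.linspace(-4.0, -0.5, 40))
        assert np.allclose(
            sm.expected_sex_ratio(q, curve), sm.expected_sex_ratio(q, refined)
        )

    def test_out_of_range_q_is_error(self, curve):
        with pytest.raises(ValueError):
            sm.expected_sex_ratio(0.0, curve)
        with pytest.raises(ValueError):
            sm.expected_sex_ratio(1.0, curve)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            sm.GlobalCurve("0-4", np.array([-1.0, -1.0]), np.array([0.1, 0.2]))


class TestMultiplierDensity:
    def test_standard_normal_at_zero(self):
        series = sm.MultiplierSeries("AAA", "0-4", [0.0], rho=0.5, tau=1.0)
        assert sm.multiplier_logdensity(series) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-9
        )
        assert sm.multiplier_logdensity(series) == pytest.approx(-0.918939, abs=1e-6)

    @pytest.mark.parametrize("length", [1, 2, 3, 4, 5])
    def test_matches_dense_multivariate_normal(self, length):
        # stationary AR(1) covariance tau^2 rho^|i-j| evaluated densely
        rng = np.random.default_rng(length)
        rho, tau = 0.85, 0.2
        delta = rng.normal(0, 0.2, size=length)
        series = sm.MultiplierSeries("AAA", "0-4", delta, rho=rho, tau=tau)
        idx = np.arange(length)
        cov = tau**2 * rho ** np.abs(np.subtract.outer(idx, idx))
        dense = stats.multivariate_normal.logpdf(delta, np.zeros(length), cov)
        assert sm.multiplier_logdensity(series) == pytest.approx(dense, abs=1e-10)

    def test_small_rho_limit_is_independence(self):
        delta = np.array([0.1, -0.05, 0.2])
        series = sm.MultiplierSeries("AAA", "0-4", delta, rho=1e-9, tau=0.3)
        independent = stats.norm.logpdf(delta, 0, 0.3).sum()
        assert sm.multiplier_logdensity(series) == pytest.approx(independent, abs=1e-6)

    def test_degenerate_tau(self):
        zero = sm.MultiplierSeries("AAA", "0-4", [0.0, 0.0], rho=0.5, tau=0.0)
        assert sm.multiplier_logdensity(zero) == 0.0
        nonzero = sm.MultiplierSeries("AAA", "0-4", [0.0, 0.1], rho=0.5, tau=0.0)
        assert sm.multiplier_logdensity(nonzero) == -np.inf

    def test_invalid_rho_is_error(self):
        series = sm.MultiplierSeries("AAA", "0-4", [0.0], rho=1.5, tau=0.1)
        with pytest.raises(ValueError, match="rho"):
            sm.multiplier_logdensity(series)


def _record(ratio=1.0, se=0.02, source="VR"):
    return ObservationRecord("AAA", 2000.0, "0-4", source, "s1", ratio, se)


class TestObservationLoglik:
    def test_zero_residual_unit_variance(self):
        rec = _record(ratio=1.2, se=np.sqrt(1.0 - 0.01))
        em = sm.ErrorModel({"VR": 0.1})
        assert sm.observation_loglik(rec, 1.2, em) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_against_scipy_density(self):
        # residual 0.1 on the log scale, total SD 0.05
        rec = _record(ratio=np.exp(0.1), se=0.02)
        em = sm.ErrorModel({"VR": np.sqrt(0.0021)})
        expected = stats.norm.logpdf(0.1, 0.0, 0.05)
        assert sm.observation_loglik(rec, 1.0, em) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.0767937, abs=1e-6)

    def test_larger_sigma_flattens_gradient(self):
        rec = _record(ratio=np.exp(0.1), se=0.02)
        eps = 1e-6

        def grad(sigma):
            em = sm.ErrorModel({"VR": sigma})
            up = sm.observation_loglik(rec, 1.0 + eps, em)
            dn = sm.observation_loglik(rec, 1.0 - eps, em)
            return (up - dn) / (2 * eps)

        assert abs(grad(0.10)) < abs(grad(0.05))

    def test_zero_total_variance_is_error(self):
        rec = _record(se=0.0)
        with pytest.raises(ValueError, match="variance"):
            sm.observation_loglik(rec, 1.0, sm.ErrorModel({"VR": 0.0}))


class TestLogPosterior:
    @pytest.fixture()
    def setup(self):
        years = np.arange(2000, 2003)
        totals = sm.TotalMortalitySeries(
            ("0-4",),
            ("AAA", "AAB"),
            years,
            np.array([[[0.05, 0.045, 0.04], [0.02, 0.019, 0.018]]]),
        )
        curve = sm.GlobalCurve(
            "0-4", np.log([0.005, 0.05, 0.3]), np.array([0.15, 0.08, 0.0])
        )
        mult = {
            ("AAA", "0-4"): sm.MultiplierSeries(
                "AAA", "0-4", [0.05, 0.02, -0.01], rho=0.8, tau=0.1
            ),
            ("AAB", "0-4"): sm.MultiplierSeries(
                "AAB", "0-4", [-0.03, 0.0, 0.04], rho=0.8, tau=0.1
            ),
        }
        em = sm.ErrorModel({"VR": 0.03, "SBH": 0.08})
        params = {"curves": {"0-4": curve}, "multipliers": mult, "error_model": em}
        config = sm.ModelConfig()
        import pandas as pd

        obs = sm.ObservationTable(
            pd.DataFrame(
                {
                    "country_code": ["AAA", "AAA", "AAB", "AAB", "AAA"],
                    "ref_year": [2000.0, 2001.4, 2000.6, 2002.0, 2002.0],
                    "age_group": ["0-4"] * 5,
                    "source_type": ["VR", "SBH", "VR", "SBH", "VR"],
                    "series_id": ["a", "b", "c", "d", "e"],
                    "sex_ratio_obs": [1.10, 1.25, 1.05, 1.30, 1.12],
                    "log_se_sampling": [0.02, 0.1, 0.03, 0.12, 0.02],
                }
            )
        )
        return params, obs, totals, config

    def test_equals_component_sum(self, setup):
        params, obs, totals, config = setup
        total = sm.log_posterior(params, obs, totals, config)
        # independent recomputation term by term
        expected = 0.0
        expected += curve_log_prior(params["curves"]["0-4"], config)
        expected += hyper_log_prior(0.8, 0.1, params["error_model"], config)
        for series in params["multipliers"].values():
            expected += sm.multiplier_logdensity(series)
        for rec in obs.to_records():
            c = totals.country_index(rec.country_code)
            t = int(np.argmin(np.abs(totals.years - rec.ref_year)))
            s_model = sm.expected_sex_ratio(
                totals.q[0, c, t], params["curves"]["0-4"]
            ) * np.exp(params["multipliers"][(rec.country_code, "0-4")].delta[t])
            expected += sm.observation_loglik(rec, s_model, params["error_model"])
        assert total == pytest.approx(expected, abs=1e-8)

    def test_empty_table_gives_prior_only(self, setup):
        params, obs, totals, config = setup
        empty = sm.ObservationTable(obs.records.iloc[:0].copy())
        prior_only = sm.log_posterior(params, empty, totals, config)
        expected = (
            curve_log_prior(params["curves"]["0-4"], config)
            + hyper_log_prior(0.8, 0.1, params["error_model"], config)
            + sum(sm.multiplier_logdensity(s) for s in params["multipliers"].values())
        )
        assert prior_only == pytest.approx(expected, abs=1e-10)

    def test_additivity_over_observations(self, setup):
        params, obs, totals, config = setup
        base = sm.log_posterior(params, obs, totals, config)
        rec = obs.records.iloc[[0]].copy()
        rec["series_id"] = "duplicate"
        import pandas as pd

        extended = sm.ObservationTable(
            pd.concat([obs.records, rec], ignore_index=True)
        )
        with_dup = sm.log_posterior(params, extended, totals, config)
        one = obs.to_records()[0]
        c = totals.country_index(one.country_code)
        t = int(np.argmin(np.abs(totals.years - one.ref_year)))
        s_model = sm.expected_sex_ratio(
            totals.q[0, c, t], params["curves"]["0-4"]
        ) * np.exp(params["multipliers"][(one.country_code, "0-4")].delta[t])
        assert with_dup - base == pytest.approx(
            sm.observation_loglik(one, s_model, params["error_model"]), abs=1e-10
        )
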