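"""Inference: quantile conventions, Kalman/FFBS oracles, recovery behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sexmort as sm
from sexmort.inference import (
    PosteriorTrajectories,
    ar1_marginal_loglik,
    summarize_ui,
)


class TestSummarizeUI:
    def test_constant_draws(self):
        s = summarize_ui(np.full(50, 3.25))
        assert (s.median, s.lower, s.upper) == (3.25, 3.25, 3.25)

    def test_type7_quantiles_on_1_to_100(self):
        s = summarize_ui(np.arange(1.0, 101.0))
        assert s.lower == pytest.approx(5.95, abs=1e-12)
        assert s.upper == pytest.approx(95.05, abs=1e-12)
        assert s.median == pytest.approx(50.5, abs=1e-12)

    def test_symmetric_sample_has_near_zero_median(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(20_000)
        s = summarize_ui(draws)
        assert abs(s.median) < 3.0 / np.sqrt(len(draws))

    def test_too_few_draws_is_error(self):
        with pytest.raises(ValueError):
            summarize_ui([])
        with pytest.raises(ValueError):
            summarize_ui([1.0])


class TestKalmanOracle:
    @pytest.mark.parametrize("gaps", [(), (1, 4)])
    def test_marginal_matches_dense_mvn(self, gaps):
        # single country, one observation per year: the marginal of the
        # residuals is N(0, tau^2 rho^|i-j| + diag(V))
        rng = np.random.default_rng(3)
        ny, rho, tau = 6, 0.7, 0.3
        V = rng.uniform(0.05, 0.2, ny)
        y = rng.normal(0, 0.3, ny)
        W = (1.0 / V)[None, :].copy()
        for g in gaps:
            W[0, g] = 0.0
        keep = [t for t in range(ny) if t not in gaps]
        idx = np.arange(ny)
        cov = tau**2 * rho ** np.abs(np.subtract.outer(idx, idx)) + np.diag(V)
        dense = stats.multivariate_normal.logpdf(
            y[keep], np.zeros(len(keep)), cov[np.ix_(keep, keep)]
        )
        assert ar1_marginal_loglik(y[None, :], W, rho, tau) == pytest.approx(
            dense, abs=1e-10
        )


class TestConjugateCase:
    def test_posterior_mean_matches_closed_form(self):
        # curve and variances fixed, one country-year, one observation:
        # delta | y ~ N( tau^2/(tau^2+v) * r, tau^2 v/(tau^2+v) )
        tau, rho, sigma, se = 0.12, 0.9, 0.03, 0.04
        curve = sm.GlobalCurve("0-4", np.log([0.005, 0.3]), np.array([0.15, 0.05]))
        totals = sm.TotalMortalitySeries(
            ("0-4",), ("AAA",), np.array([2010]), np.array([[[0.03]]])
        )
        y_ratio = 1.30
        obs = sm.ObservationTable(
            pd.DataFrame(
                {
                    "country_code": ["AAA"],
                    "ref_year": [2010.0],
                    "age_group": ["0-4"],
                    "source_type": ["VR"],
                    "series_id": ["s"],
                    "sex_ratio_obs": [y_ratio],
                    "log_se_sampling": [se],
                }
            )
        )
        config = sm.ModelConfig(
            n_draws=4000,
            seed=17,
            fixed={
                "curve": {"0-4": curve},
                "rho": rho,
                "tau": tau,
                "sigma_by_source": {"VR": sigma},
            },
        )
        traj = sm.fit_model(obs, totals, config)
        delta = traj.delta_draws[:, 0, 0, 0]
        v = se**2 + sigma**2
        r = np.log(y_ratio) - np.log(sm.expected_sex_ratio(0.03, curve))
        shrink = tau**2 / (tau**2 + v)
        post_sd = np.sqrt(shrink * v)
        assert delta.mean() == pytest.approx(
            shrink * r, abs=4 * post_sd / np.sqrt(len(delta))
        )
        assert delta.std() == pytest.approx(post_sd, rel=0.1)


class TestFitBehaviour:
    def test_bit_reproducible_under_fixed_seed(self, tiny_sim):
        _, totals, _, obs = tiny_sim
        mc = sm.ModelConfig(seed=3, n_walkers=26, n_burn=60, n_steps=50)
        a = sm.fit_model(obs, totals, mc)
        b = sm.fit_model(obs, totals, mc)
        assert np.array_equal(a.s_draws, b.s_draws)
        assert a.hyper_draws["0-4"].equals(b.hyper_draws["0-4"])

    def test_missing_age_group_is_error(self, tiny_sim):
        _, totals, _, obs = tiny_sim
        empty = sm.ObservationTable(
            obs.records[obs.records["age_group"] != "0-4"].copy()
        )
        with pytest.raises(ValueError, match="no observations"):
            sm.fit_model(empty, totals, sm.ModelConfig(seed=1))

    def test_zero_noise_recovery_tracks_true_curve(self):
        # near-noiseless observations, no country effects: the posterior
        # median sex ratio should sit within 1% of the generating surface
        cfg = sm.SimulationConfig(
            n_countries=20,
            year_start=2000,
            year_end=2011,
            tau_truth=0.0,
            totals_noise_sd=0.0,
            sigma_by_source={s: 0.01 for s in ("VR", "FBH", "SBH", "CENSUS")},
            sampling_se_range_by_source={
                s: (0.01, 0.01) for s in ("VR", "FBH", "SBH", "CENSUS")
            },
            seed=31,
        )
        totals = sm.simulate_total_mortality(cfg)
        truth = sm.simulate_truth(totals, cfg)
        obs = sm.simulate_observations(truth, cfg)
        mc = sm.ModelConfig(seed=8, n_knots=8, n_walkers=28, n_burn=500, n_steps=400)
        traj = sm.fit_model(obs, totals, mc)
        med = np.median(traj.s_draws[:, 0], axis=0)
        assert np.max(np.abs(np.log(med) - np.log(truth.s_true[0]))) < 0.01

    def test_country_without_data_follows_curve_with_wider_intervals(self, tiny_sim):
        _, totals, _, obs = tiny_sim
        gone = totals.countries[0]
        reduced = sm.ObservationTable(
            obs.records[obs.records["country_code"] != gone].copy()
        )
        mc = sm.ModelConfig(seed=9, n_walkers=26, n_burn=250, n_steps=200)
        traj = sm.fit_model(reduced, totals, mc)
        log_s = np.log(traj.s_draws[:, 0])
        widths = np.quantile(log_s, 0.95, axis=0) - np.quantile(log_s, 0.05, axis=0)
        has_data = np.array(
            [c in set(reduced.records["country_code"]) for c in totals.countries]
        )
        assert widths[0].mean() > widths[has_data].mean()
        curve_med = np.median(
            traj.curve_logvalues("0-4", np.log(totals.q[0, 0]).ravel()), axis=0
        )
        assert np.max(np.abs(np.median(log_s[:, 0], axis=0) - curve_med)) < 0.05

    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        path = tmp_path / "traj.npz"
        tiny_fit.save_npz(path)
        back = PosteriorTrajectories.load_npz(path)
        assert np.array_equal(back.s_draws, tiny_fit.s_draws)
        assert back.age_groups == tiny_fit.age_groups
        assert back.hyper_draws["0-4"].equals(tiny_fit.hyper_draws["0-4"])


def _manual_traj(s_draws, countries=("AAA",), years=(2000, 2001)):
    nd = s_draws.shape[0]
    return PosteriorTrajectories(
        age_groups=("0-4",),
        countries=tuple(countries),
        years=np.array(years),
        s_draws=s_draws,
        delta_draws=np.zeros_like(s_draws),
        curve_knots={"0-4": np.log([0.005, 0.3])},
        curve_values_draws={"0-4": np.zeros((nd, 2))},
        hyper_draws={"0-4": pd.DataFrame({"rho": np.full(nd, 0.9)})},
        seed=0,
    )


class TestSexSpecificTrajectories:
    def test_conservation_identity_with_point_totals(self):
        rng = np.random.default_rng(1)
        s_draws = np.exp(rng.normal(0.1, 0.05, size=(200, 1, 1, 2)))
        traj = _manual_traj(s_draws)
        q = np.array([[[0.04, 0.035]]])
        totals = sm.TotalMortalitySeries(("0-4",), ("AAA",), [2000, 2001], q)
        w = np.full((1, 1, 2), 0.512)
        traj = sm.trajectories_to_sex_specific(traj, totals, w)
        lhs = w[None] * traj.q_male_draws + (1 - w[None]) * traj.q_female_draws
        assert np.max(np.abs(lhs - q[None])) < 1e-12

    def test_unit_ratio_gives_equal_sexes(self):
        s_draws = np.ones((150, 1, 1, 2))
        traj = _manual_traj(s_draws)
        q = np.array([[[0.05, 0.04]]])
        totals = sm.TotalMortalitySeries(("0-4",), ("AAA",), [2000, 2001], q)
        traj = sm.trajectories_to_sex_specific(traj, totals, np.full((1, 1, 2), 0.5))
        assert np.allclose(traj.q_male_draws, q[None])
        assert np.allclose(traj.q_female_draws, q[None])

    def test_totals_uncertainty_widens_female_interval(self):
        rng = np.random.default_rng(2)
        s_draws = np.full((400, 1, 1, 2), 1.2)
        q = np.array([[[0.05, 0.04]]])

        def widths(draw_sd):
            draws = np.clip(
                q[None] * np.exp(rng.normal(0, draw_sd, size=(400, 1, 1, 2))),
                1e-6,
                0.9,
            )
            totals = sm.TotalMortalitySeries(("0-4",), ("AAA",), [2000, 2001], q, draws)
            traj = sm.trajectories_to_sex_specific(
                _manual_traj(s_draws.copy()), totals, np.full((1, 1, 2), 0.51)
            )
            qf = traj.q_female_draws[:, 0, 0, 0]
            return np.quantile(qf, 0.95) - np.quantile(qf, 0.05)

        assert widths(0.2) > widths(0.02)

    def test_missing_weight_is_error(self):
        traj = _manual_traj(np.ones((150, 1, 1, 2)))
        totals = sm.TotalMortalitySeries(
            ("0-4",), ("AAA",), [2000, 2001], np.array([[[0.05, 0.04]]])
        )
        weights = pd.DataFrame(
            {
                "country_code": ["AAA"],
                "year": [2000],
                "age_group": ["0-4"],
                "w_male": [0.51],
            }
        )  # 2001 missing
        with pytest.raises(ValueError, match="missing"):
            sm.trajectories_to_sex_specific(traj, totals, weights)
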