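"""Probabilistic model for mortality sex ratios.

The sex ratio of mortality in country ``c``, year ``t`` and age group ``a``
is modelled as

    S(c, t, a) = f_a(Q(c, t, a)) * exp(delta(c, t, a))

where ``f_a`` is a global curve giving the expected sex ratio as a function
of the total (both-sex) probability of dying ``Q``, and ``delta`` is a
country-specific log multiplier fluctuating around zero, so the multiplier
``P = exp(delta)`` fluctuates around one. ``f_a`` is piecewise linear in
(log Q, log S) with flat extrapolation beyond its end knots, which lets the
expected ratio rise as mortality declines and still reverse at very low
mortality. ``delta`` follows a stationary AR(1) process shared within an age
group: lag-one correlation ``rho`` and stationary standard deviation ``tau``.

Observed log ratios are Normal around log S with variance equal to the
observation's sampling variance plus a source-type-specific non-sampling
variance ``sigma_j^2``, so precise observations pull the posterior harder
than weakly informative ones.

All densities here are exact and cheap to evaluate; they are the oracles the
inference machinery is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .obs_db import ObservationRecord, ObservationTable, SOURCE_TYPES


@dataclass
class GlobalCurve:
    """Expected sex ratio as a function of total mortality, per age group.

    ``knots_logq`` is a strictly increasing grid on log total mortality;
    ``values_logs`` the log expected sex ratio at each knot. Between knots
    the log ratio is linear in log q; beyond the end knots it is flat.
    """

    age_group: str
    knots_logq: np.ndarray
    values_logs: np.ndarray

    def __post_init__(self) -> None:
        self.knots_logq = np.asarray(self.knots_logq, dtype=float)
        self.values_logs = np.asarray(self.values_logs, dtype=float)
        if self.knots_logq.size < 2:
            raise ValueError("a curve needs at least 2 knots")
        if self.knots_logq.size != self.values_logs.size:
            raise ValueError("knots and values must have equal length")
        if np.any(np.diff(self.knots_logq) <= 0):
            raise ValueError("knots_logq must be strictly increasing")
        if not np.all(np.isfinite(self.values_logs)):
            raise ValueError("values_logs must be finite")

    def __call__(self, q_total):
        return expected_sex_ratio(q_total, self)


def expected_sex_ratio(q_total, curve: GlobalCurve):
    """Evaluate the global curve at total mortality ``q_total`` in (0, 1)."""
    q = np.asarray(q_total, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q_total must lie strictly in (0, 1)")
    out = np.exp(np.interp(np.log(q), curve.knots_logq, curve.values_logs))
    return float(out) if out.ndim == 0 else out


@dataclass
class MultiplierSeries:
    """Country log multipliers ``delta`` on the model year grid.

    ``P = exp(delta)`` fluctuates around 1; ``rho`` and ``tau`` are the
    lag-one correlation and stationary SD of the AR(1) process.
    """

    country_code: str
    age_group: str
    delta: np.ndarray
    rho: float
    tau: float

    def __post_init__(self) -> None:
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        if not np.all(np.isfinite(self.delta)):
            raise ValueError("delta must be finite")


def multiplier_logdensity(series: MultiplierSeries) -> float:
    """Exact log density of a multiplier series under the stationary AR(1).

    delta_1 ~ Normal(0, tau^2); delta_t | delta_{t-1} ~
    Normal(rho * delta_{t-1}, tau^2 (1 - rho^2)). With tau = 0 the process is
    degenerate at zero: the density is 0 for an all-zero series and -inf
    otherwise.
    """
    if not (0 < series.rho < 1):
        raise ValueError(f"rho must lie in (0, 1), got {series.rho}")
    if series.tau < 0:
        raise ValueError("tau must be >= 0")
    d = series.delta
    if series.tau == 0:
        return 0.0 if np.all(d == 0) else -np.inf
    ld = stats.norm.logpdf(d[0], 0.0, series.tau)
    if d.size > 1:
        innov_sd = series.tau * np.sqrt(1.0 - series.rho**2)
        ld += stats.norm.logpdf(d[1:], series.rho * d[:-1], innov_sd).sum()
    return float(ld)


@dataclass
class ErrorModel:
    """Source-type-specific non-sampling standard deviations on the log scale."""

    sigma_by_source: dict[str, float]

    def __post_init__(self) -> None:
        for src, sig in self.sigma_by_source.items():
            if src not in SOURCE_TYPES:
                raise ValueError(f"unknown source type {src!r}")
            if sig < 0:
                raise ValueError(f"sigma for {src} must be >= 0")

    def sigma(self, source_type: str) -> float:
        return self.sigma_by_source[source_type]


def observation_loglik(
    record: ObservationRecord, s_model: float, error_model: ErrorModel
) -> float:
    """Normal log likelihood of one observed log ratio.

    Variance is the observation's sampling variance plus the non-sampling
    variance of its source type; a zero total variance is a degenerate
    likelihood and an error.
    """
    if s_model <= 0:
        raise ValueError("s_model must be > 0")
    total_var = record.log_se_sampling**2 + error_model.sigma(record.source_type) ** 2
    if total_var <= 0:
        raise ValueError("total observation variance must be > 0")
    return float(
        stats.norm.logpdf(
            np.log(record.sex_ratio_obs), np.log(s_model), np.sqrt(total_var)
        )
    )


@dataclass
class TotalMortalitySeries:
    """Country-year-age both-sex probabilities of dying, point and draws.

    ``q`` has shape (n_age, n_country, n_year); optional ``draws`` prepend a
    draw axis and carry the published uncertainty of the totals.
    """

    age_groups: tuple[str, ...]
    countries: tuple[str, ...]
    years: np.ndarray
    q: np.ndarray
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.q = np.asarray(self.q, dtype=float)
        shape = (len(self.age_groups), len(self.countries), len(self.years))
        if self.q.shape != shape:
            raise ValueError(f"q must have shape {shape}, got {self.q.shape}")
        if np.any((self.q <= 0) | (self.q >= 1)):
            raise ValueError("q must lie strictly in (0, 1)")
        if self.draws is not None:
            self.draws = np.asarray(self.draws, dtype=float)
            if self.draws.shape[1:] != shape:
                raise ValueError("draws must match (age, country, year) shape")

    def age_index(self, age_group: str) -> int:
        return self.age_groups.index(age_group)

    def country_index(self, country_code: str) -> int:
        return self.countries.index(country_code)

    def to_frame(self) -> pd.DataFrame:
        na, nc, ny = self.q.shape
        ages = np.repeat(self.age_groups, nc * ny)
        countries = np.tile(np.repeat(self.countries, ny), na)
        years = np.tile(self.years, na * nc)
        return pd.DataFrame(
            {
                "country_code": countries,
                "year": years,
                "age_group": ages,
                "q_total": self.q.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, draws: pd.DataFrame | None = None):
        ages = tuple(pd.unique(df["age_group"]))
        countries = tuple(pd.unique(df["country_code"]))
        years = np.sort(pd.unique(df["year"]))
        wide = df.set_index(["age_group", "country_code", "year"])["q_total"]
        q = np.empty((len(ages), len(countries), len(years)))
        for i, a in enumerate(ages):
            for j, c in enumerate(countries):
                q[i, j] = wide.loc[a, c].reindex(years).to_numpy()
        if np.isnan(q).any():
            raise ValueError("totals do not cover the full (age, country, year) grid")
        draw_arr = None
        if draws is not None:
            nd = int(draws["draw"].max()) + 1
            draw_arr = np.empty((nd, len(ages), len(countries), len(years)))
            dwide = draws.set_index(["draw", "age_group", "country_code", "year"])["q_total"]
            for d in range(nd):
                for i, a in enumerate(ages):
                    for j, c in enumerate(countries):
                        draw_arr[d, i, j] = dwide.loc[d, a, c].reindex(years).to_numpy()
        return cls(ages, countries, years, q, draw_arr)

    @classmethod
    def read_csv(cls, path, draws_path=None):
        draws = pd.read_csv(draws_path) if draws_path is not None else None
        return cls.from_frame(pd.read_csv(path), draws)


@dataclass
class ModelConfig:
    """Knot rule, priors and inference settings.

    Defaults are weakly informative on the log-ratio scale: half-Normal(0.5)
    scales for ``tau`` and each ``sigma_j``, Uniform(0, 1) for ``rho``,
    Normal(0, 1) on the first knot value and Normal(0, ``smoothness_sd``) on
    second differences of the knot values (a random-walk-2-style smoothness
    prior).
    """

    n_knots: int = 6
    knot_quantiles: tuple[float, float] = (0.01, 0.99)
    smoothness_sd: float = 0.1
    first_value_sd: float = 1.0
    tau_scale: float = 0.5
    sigma_scale: float = 0.5
    n_draws: int = 500
    n_walkers: int = 28
    n_burn: int = 1500
    n_steps: int = 1200
    seed: int = 0
    #: optionally fix components: keys among {"curve", "rho", "tau", "sigma_by_source"};
    #: "curve" maps age_group -> GlobalCurve
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("smoothness_sd", "first_value_sd", "tau_scale", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_draws < 500:
            raise ValueError("n_draws must be >= 500")
        if self.n_knots < 2:
            raise ValueError("n_knots must be >= 2")


def nearest_year_index(years: np.ndarray, ref_year) -> np.ndarray:
    """Map decimal reference years to the nearest model year (ties -> earlier)."""
    years = np.asarray(years)
    ref = np.atleast_1d(np.asarray(ref_year, dtype=float))
    idx = np.abs(ref[:, None] - years[None, :]).argmin(axis=1)
    return idx if np.ndim(ref_year) else int(idx[0])


def curve_log_prior(curve: GlobalCurve, config: ModelConfig) -> float:
    """Smoothness prior on the knot values of the global curve."""
    v = curve.values_logs
    lp = stats.norm.logpdf(v[0], 0.0, config.first_value_sd)
    if v.size > 2:
        lp += stats.norm.logpdf(np.diff(v, n=2), 0.0, config.smoothness_sd).sum()
    return float(lp)


def hyper_log_prior(
    rho: float, tau: float, error_model: ErrorModel, config: ModelConfig
) -> float:
    """Half-Normal priors for tau and the sigmas; Uniform(0,1) for rho."""
    if not (0 < rho < 1):
        return -np.inf
    lp = stats.halfnorm.logpdf(tau, scale=config.tau_scale)
    for sig in error_model.sigma_by_source.values():
        lp += stats.halfnorm.logpdf(sig, scale=config.sigma_scale)
    return float(lp)


def log_posterior(
    params: dict,
    data: ObservationTable,
    totals: TotalMortalitySeries,
    config: ModelConfig,
) -> float:
    """Unnormalised log posterior of the full parameter set.

    ``params`` holds ``curves`` (age_group -> GlobalCurve), ``multipliers``
    ((country, age_group) -> MultiplierSeries) and ``error_model``. The value
    is the exact sum of all observation log likelihoods, all multiplier log
    densities, the curve smoothness priors and the hyperpriors — the oracle
    the marginalised inference path is checked against.
    """
    curves: dict[str, GlobalCurve] = params["curves"]
    multipliers: dict[tuple[str, str], MultiplierSeries] = params["multipliers"]
    error_model: ErrorModel = params["error_model"]

    lp = 0.0
    for curve in curves.values():
        lp += curve_log_prior(curve, config)
    seen_hyper: set[str] = set()
    for series in multipliers.values():
        lp += multiplier_logdensity(series)
        if series.age_group not in seen_hyper:
            lp += hyper_log_prior(series.rho, series.tau, error_model, config)
            seen_hyper.add(series.age_group)
    if not np.isfinite(lp):
        return float(lp)

    for rec in data.to_records():
        a = totals.age_index(rec.age_group)
        c = totals.country_index(rec.country_code)
        t = nearest_year_index(totals.years, rec.ref_year)
        q = totals.q[a, c, t]
        series = multipliers[(rec.country_code, rec.age_group)]
        s_model = expected_sex_ratio(q, curves[rec.age_group]) * np.exp(series.delta[t])
        lp += observation_loglik(rec, s_model, error_model)
    return float(lp)
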