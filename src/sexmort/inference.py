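"""Posterior inference for the sex-ratio model.

The model is conditionally linear-Gaussian: given the curve knot values and
the hyperparameters (rho, tau, sigma_j), the country multiplier series and
the observed log ratios are jointly Gaussian. Inference exploits this
exactly:

1. the AR(1) multiplier series are integrated out analytically with a
   scalar Kalman filter, giving the exact marginal likelihood of the curve
   values and hyperparameters;
2. that low-dimensional marginal posterior is sampled with an
   affine-invariant ensemble sampler (emcee);
3. for each retained hyperparameter draw, the multiplier trajectories are
   drawn exactly by forward-filter backward-sampling (FFBS).

The result is a set of posterior trajectories of the sex ratio S(c, t, a)
on the full estimation grid, including countries without data (for which
the posterior follows the global curve with full AR(1) prior width).
Summaries use 90% intervals from the 5th and 95th percentiles, with the
linear-interpolation ("type 7") quantile convention throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .model import (
    GlobalCurve,
    ModelConfig,
    TotalMortalitySeries,
    nearest_year_index,
)
from .obs_db import ObservationTable, SOURCE_TYPES

logger = logging.getLogger(__name__)

_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# interval summaries


@dataclass(frozen=True)
class IntervalSummary:
    """Posterior median with a 90% uncertainty interval (5th/95th percentiles)."""

    median: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("require lower <= median <= upper")


def summarize_ui(draws, level: float = 0.90) -> IntervalSummary:
    """Median and equal-tail interval of a sample under the type-7 quantile rule."""
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least 2 draws to summarise")
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(arr, [alpha, 0.5, 1.0 - alpha], method="linear")
    return IntervalSummary(float(med), float(lo), float(hi))


# ---------------------------------------------------------------------------
# Kalman filter / FFBS for the stationary AR(1) multiplier block


def ar1_marginal_loglik(m: np.ndarray, W: np.ndarray, rho: float, tau: float) -> float:
    """Marginal log likelihood of per-cell pseudo-observations under the AR(1).

    ``m`` and ``W`` are (n_country, n_year) precision-weighted means and total
    precisions of the cell residuals (W = 0 marks cells without data). The
    state is the scalar log multiplier with stationary initialisation
    N(0, tau^2); the filter is vectorised over countries.
    """
    nc, ny = m.shape
    a = np.zeros(nc)
    P = np.full(nc, tau * tau)
    innov = tau * tau * (1.0 - rho * rho)
    ll = 0.0
    for t in range(ny):
        w = W[:, t]
        obs = w > 0
        if obs.any():
            S = P[obs] + 1.0 / w[obs]
            e = m[obs, t] - a[obs]
            ll -= 0.5 * np.sum(_LOG_2PI + np.log(S) + e * e / S)
            K = P[obs] / S
            a[obs] += K * e
            P[obs] *= 1.0 - K
        if t < ny - 1:
            a *= rho
            P = rho * rho * P + innov
    return float(ll)


def ar1_ffbs(
    m: np.ndarray,
    W: np.ndarray,
    rho: np.ndarray,
    tau: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward-filter backward-sample the multiplier series, per posterior draw.

    ``m``, ``W``: (n_draw, n_country, n_year); ``rho``, ``tau``: (n_draw,).
    Returns exact conditional draws of delta with the same leading shape.
    """
    nd, nc, ny = m.shape
    af = np.empty((ny, nd, nc))
    Pf = np.empty((ny, nd, nc))
    a = np.zeros((nd, nc))
    P = np.broadcast_to((tau * tau)[:, None], (nd, nc)).copy()
    rho_c = rho[:, None]
    rho2 = (rho * rho)[:, None]
    innov = (tau * tau * (1.0 - rho * rho))[:, None]
    for t in range(ny):
        Wt = W[:, :, t]
        obs = Wt > 0
        if obs.any():
            Wsafe = np.where(obs, Wt, 1.0)
            S = P + np.where(obs, 1.0 / Wsafe, np.inf)
            K = np.where(obs, P / S, 0.0)
            e = np.where(obs, m[:, :, t] - a, 0.0)
            a = a + K * e
            P = P * (1.0 - K)
        af[t] = a
        Pf[t] = P
        if t < ny - 1:
            a = rho_c * a
            P = rho2 * P + innov
    delta = np.empty((nd, nc, ny))
    delta[:, :, ny - 1] = af[ny - 1] + np.sqrt(np.maximum(Pf[ny - 1], 0.0)) * (
        rng.standard_normal((nd, nc))
    )
    for t in range(ny - 2, -1, -1):
        Ppred = rho2 * Pf[t] + innov
        safe = Ppred > 0
        G = np.where(safe, rho_c * Pf[t] / np.where(safe, Ppred, 1.0), 0.0)
        mean = af[t] + G * (delta[:, :, t + 1] - rho_c * af[t])
        var = np.maximum(Pf[t] * (1.0 - G * rho_c), 0.0)
        delta[:, :, t] = mean + np.sqrt(var) * rng.standard_normal((nd, nc))
    return delta


# ---------------------------------------------------------------------------
# per-age-group data preparation and parameter bookkeeping


def _interp_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation as a design matrix (flat extrapolation).

    Rows reproduce ``np.interp(x, knots, values)`` as ``A @ values``.
    """
    n, K = len(x), len(knots)
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, K - 2)
    t = np.clip((x - knots[j]) / (knots[j + 1] - knots[j]), 0.0, 1.0)
    A = np.zeros((n, K))
    rows = np.arange(n)
    A[rows, j] = 1.0 - t
    A[rows, j + 1] += t
    return A


class _AgeData:
    """Observation arrays, knot grid and design matrices for one age group."""

    def __init__(
        self,
        records: pd.DataFrame,
        totals: TotalMortalitySeries,
        age_index: int,
        config: ModelConfig,
    ):
        self.age_group = totals.age_groups[age_index]
        country_index = {c: i for i, c in enumerate(totals.countries)}
        unknown = set(records["country_code"]) - set(totals.countries)
        if unknown:
            raise ValueError(
                f"observations for countries absent from the totals grid: {sorted(unknown)[:5]}"
            )
        self.nc = len(totals.countries)
        self.ny = len(totals.years)
        self.c_idx = records["country_code"].map(country_index).to_numpy(int)
        self.t_idx = nearest_year_index(totals.years, records["ref_year"].to_numpy(float))
        self.cell = self.c_idx * self.ny + self.t_idx
        self.y = np.log(records["sex_ratio_obs"].to_numpy(float))
        self.v = records["log_se_sampling"].to_numpy(float) ** 2
        self.sources = [s for s in SOURCE_TYPES if s in set(records["source_type"])]
        src_index = {s: i for i, s in enumerate(self.sources)}
        self.src_idx = records["source_type"].map(src_index).to_numpy(int)

        logq_grid = np.log(totals.q[age_index]).ravel()
        fixed_curve = config.fixed.get("curve", {})
        if self.age_group in fixed_curve:
            curve: GlobalCurve = fixed_curve[self.age_group]
            self.knots = curve.knots_logq
            self.fixed_values = curve.values_logs
        else:
            qlo, qhi = config.knot_quantiles
            knots = np.quantile(logq_grid, np.linspace(qlo, qhi, config.n_knots))
            if np.any(np.diff(knots) <= 0):
                raise ValueError("degenerate knot grid: totals have too little spread")
            self.knots = knots
            self.fixed_values = None
        x_obs = np.log(totals.q[age_index])[self.c_idx, self.t_idx]
        self.A_obs = _interp_design(x_obs, self.knots)
        self.A_grid = _interp_design(logq_grid, self.knots)


class _ParamMap:
    """Packs the free parameters of one age-group fit into a flat vector.

    Layout: curve knot values (if free), logit(rho) (if free), log(tau)
    (if free), log(sigma_j) per source present (if free).
    """

    def __init__(self, data: _AgeData, config: ModelConfig):
        self.config = config
        self.K = len(data.knots)
        self.sources = data.sources
        fixed = config.fixed
        self.curve_free = data.fixed_values is None
        self.rho_free = "rho" not in fixed
        self.tau_free = "tau" not in fixed
        self.sigma_free = "sigma_by_source" not in fixed
        self.fixed_values = data.fixed_values
        self.fixed_rho = fixed.get("rho")
        self.fixed_tau = fixed.get("tau")
        if not self.sigma_free:
            self.fixed_sigma = np.array(
                [fixed["sigma_by_source"][s] for s in self.sources]
            )
        self.names: list[str] = []
        if self.curve_free:
            self.names += [f"beta_{k}" for k in range(self.K)]
        if self.rho_free:
            self.names.append("logit_rho")
        if self.tau_free:
            self.names.append("log_tau")
        if self.sigma_free:
            self.names += [f"log_sigma_{s}" for s in self.sources]
        self.ndim = len(self.names)

    def unpack(self, theta: np.ndarray):
        """theta -> (beta, rho, tau, sigmas); supports a leading draw axis."""
        theta = np.atleast_2d(theta)
        nd = theta.shape[0]
        pos = 0
        if self.curve_free:
            beta = theta[:, pos : pos + self.K]
            pos += self.K
        else:
            beta = np.broadcast_to(self.fixed_values, (nd, self.K))
        if self.rho_free:
            rho = 1.0 / (1.0 + np.exp(-theta[:, pos]))
            pos += 1
        else:
            rho = np.full(nd, self.fixed_rho)
        if self.tau_free:
            tau = np.exp(theta[:, pos])
            pos += 1
        else:
            tau = np.full(nd, self.fixed_tau)
        if self.sigma_free:
            sigmas = np.exp(theta[:, pos : pos + len(self.sources)])
        else:
            sigmas = np.broadcast_to(self.fixed_sigma, (nd, len(self.sources)))
        return beta, rho, tau, sigmas

    def log_prior(self, beta, rho, tau, sigmas) -> float:
        """Priors plus log Jacobians of the unconstraining transforms."""
        cfg = self.config
        lp = 0.0
        if self.curve_free:
            lp += -0.5 * (beta[0] / cfg.first_value_sd) ** 2 - np.log(cfg.first_value_sd)
            if self.K > 2:
                d2 = np.diff(beta, n=2)
                lp += np.sum(
                    -0.5 * (d2 / cfg.smoothness_sd) ** 2 - np.log(cfg.smoothness_sd)
                )
        if self.rho_free:
            # Uniform(0,1) density plus logistic Jacobian
            lp += np.log(rho) + np.log1p(-rho)
        if self.tau_free:
            lp += -0.5 * (tau / cfg.tau_scale) ** 2 + np.log(tau)
        if self.sigma_free:
            lp += np.sum(-0.5 * (sigmas / cfg.sigma_scale) ** 2 + np.log(sigmas))
        return float(lp)


def _marginal_loglik(
    data: _AgeData, beta: np.ndarray, rho: float, tau: float, sigmas: np.ndarray
) -> float:
    """Exact log p(y | beta, rho, tau, sigma) with multipliers integrated out."""
    r = data.y - data.A_obs @ beta
    V = data.v + (sigmas**2)[data.src_idx]
    w = 1.0 / V
    ncell = data.nc * data.ny
    W = np.bincount(data.cell, weights=w, minlength=ncell)
    Mw = np.bincount(data.cell, weights=w * r, minlength=ncell)
    obs_cells = W > 0
    m = np.zeros(ncell)
    m[obs_cells] = Mw[obs_cells] / W[obs_cells]
    const = (
        -0.5 * np.sum(_LOG_2PI + np.log(V))
        - 0.5 * (np.sum(w * r * r) - np.sum(W[obs_cells] * m[obs_cells] ** 2))
        + 0.5 * np.sum(_LOG_2PI - np.log(W[obs_cells]))
    )
    return const + ar1_marginal_loglik(
        m.reshape(data.nc, data.ny), W.reshape(data.nc, data.ny), rho, tau
    )


def _cell_stats_per_draw(data: _AgeData, beta, sigmas):
    """Per-draw precision-weighted cell means and precisions for FFBS."""
    nd = beta.shape[0]
    ncell = data.nc * data.ny
    r = data.y[None, :] - beta @ data.A_obs.T
    V = data.v[None, :] + (sigmas**2)[:, data.src_idx]
    w = 1.0 / V
    W = np.empty((nd, ncell))
    m = np.zeros((nd, ncell))
    for d in range(nd):
        Wd = np.bincount(data.cell, weights=w[d], minlength=ncell)
        Md = np.bincount(data.cell, weights=w[d] * r[d], minlength=ncell)
        obs = Wd > 0
        W[d] = Wd
        m[d, obs] = Md[obs] / Wd[obs]
    return m.reshape(nd, data.nc, data.ny), W.reshape(nd, data.nc, data.ny)


# ---------------------------------------------------------------------------
# the fit


@dataclass
class PosteriorTrajectories:
    """Posterior draws of sex ratios (and, once filled, sex-specific rates)."""

    age_groups: tuple[str, ...]
    countries: tuple[str, ...]
    years: np.ndarray
    s_draws: np.ndarray  # (n_draw, n_age, n_country, n_year)
    delta_draws: np.ndarray
    curve_knots: dict[str, np.ndarray]
    curve_values_draws: dict[str, np.ndarray]  # age -> (n_draw, K)
    hyper_draws: dict[str, pd.DataFrame]
    diagnostics: dict = field(default_factory=dict)
    seed: int = 0
    q_male_draws: np.ndarray | None = None
    q_female_draws: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.s_draws.shape[0]

    def curve_logvalues(self, age_group: str, logq) -> np.ndarray:
        """Posterior draws of the log expected ratio at given log total mortality."""
        logq = np.atleast_1d(np.asarray(logq, dtype=float))
        A = _interp_design(logq, self.curve_knots[age_group])
        return self.curve_values_draws[age_group] @ A.T

    def expected_ratio_draws(self, totals: TotalMortalitySeries) -> np.ndarray:
        """Draws of the expected sex ratio f(Q) on the grid (no multiplier)."""
        nd = self.n_draws
        na, nc, ny = totals.q.shape
        out = np.empty((nd, na, nc, ny))
        for i, age in enumerate(self.age_groups):
            A = _interp_design(np.log(totals.q[i]).ravel(), self.curve_knots[age])
            out[:, i] = np.exp(self.curve_values_draws[age] @ A.T).reshape(nd, nc, ny)
        return out

    def summary_frame(self, level: float = 0.90) -> pd.DataFrame:
        """Long per-(country, year, age) summary of S and any filled q draws."""
        alpha = (1.0 - level) / 2.0
        quantiles = [alpha, 0.5, 1.0 - alpha]
        blocks = {"s": self.s_draws}
        if self.q_male_draws is not None:
            blocks["q_male"] = self.q_male_draws
            blocks["q_female"] = self.q_female_draws
        na, nc, ny = self.s_draws.shape[1:]
        base = pd.DataFrame(
            {
                "age_group": np.repeat(self.age_groups, nc * ny),
                "country_code": np.tile(np.repeat(self.countries, ny), na),
                "year": np.tile(self.years, na * nc),
            }
        )
        for name, draws in blocks.items():
            lo, med, hi = np.quantile(draws, quantiles, axis=0).reshape(3, -1)
            base[f"{name}_median"] = med
            base[f"{name}_lower"] = lo
            base[f"{name}_upper"] = hi
        return base

    def save_npz(self, path) -> None:
        payload: dict[str, np.ndarray] = {
            "s_draws": self.s_draws,
            "delta_draws": self.delta_draws,
            "years": self.years,
            "countries": np.array(self.countries),
            "age_groups": np.array(self.age_groups),
            "seed": np.array(self.seed),
            "diagnostics_json": np.array(json.dumps(self.diagnostics)),
        }
        if self.q_male_draws is not None:
            payload["q_male_draws"] = self.q_male_draws
            payload["q_female_draws"] = self.q_female_draws
        for age in self.age_groups:
            key = age.replace("-", "_")
            payload[f"curve_knots__{key}"] = self.curve_knots[age]
            payload[f"curve_values__{key}"] = self.curve_values_draws[age]
            hyper = self.hyper_draws[age]
            payload[f"hyper_cols__{key}"] = np.array(list(hyper.columns))
            payload[f"hyper__{key}"] = hyper.to_numpy()
        np.savez_compressed(path, **payload)

    @classmethod
    def load_npz(cls, path) -> "PosteriorTrajectories":
        with np.load(path, allow_pickle=False) as z:
            age_groups = tuple(str(a) for a in z["age_groups"])
            curve_knots, curve_values, hyper = {}, {}, {}
            for age in age_groups:
                key = age.replace("-", "_")
                curve_knots[age] = z[f"curve_knots__{key}"]
                curve_values[age] = z[f"curve_values__{key}"]
                hyper[age] = pd.DataFrame(
                    z[f"hyper__{key}"], columns=[str(c) for c in z[f"hyper_cols__{key}"]]
                )
            return cls(
                age_groups=age_groups,
                countries=tuple(str(c) for c in z["countries"]),
                years=z["years"],
                s_draws=z["s_draws"],
                delta_draws=z["delta_draws"],
                curve_knots=curve_knots,
                curve_values_draws=curve_values,
                hyper_draws=hyper,
                diagnostics=json.loads(str(z["diagnostics_json"])),
                seed=int(z["seed"]),
                q_male_draws=z["q_male_draws"] if "q_male_draws" in z else None,
                q_female_draws=z["q_female_draws"] if "q_female_draws" in z else None,
            )


#: split-chain convergence threshold above which a fit is flagged (not failed)
RHAT_WARN = 1.05


def _init_theta(data: _AgeData, pmap: _ParamMap, config: ModelConfig) -> np.ndarray:
    """Data-driven starting point: ridge fit of the curve, moment-scale hypers."""
    theta = []
    if pmap.curve_free:
        w0 = 1.0 / (data.v + 0.05**2 + config.fixed.get("tau", 0.1) ** 2)
        Aw = data.A_obs * w0[:, None]
        lhs = data.A_obs.T @ Aw + 1e-3 * np.eye(pmap.K)
        beta0 = np.linalg.solve(lhs, Aw.T @ data.y)
        theta += list(beta0)
    if pmap.rho_free:
        theta.append(np.log(0.85 / 0.15))
    if pmap.tau_free:
        theta.append(np.log(0.1))
    if pmap.sigma_free:
        theta += [np.log(0.05)] * len(pmap.sources)
    return np.array(theta)


def _fit_age_group(
    data: _AgeData, config: ModelConfig, rng: np.random.Generator
) -> dict:
    pmap = _ParamMap(data, config)
    diagnostics: dict = {"n_obs": int(data.y.size), "sources": list(data.sources)}

    if pmap.ndim == 0:
        thetas = np.zeros((config.n_draws, 0))
    else:

        def log_prob(theta):
            if np.any(np.abs(theta) > 30):
                return -np.inf
            beta, rho, tau, sigmas = pmap.unpack(theta)
            beta, rho, tau, sigmas = beta[0], rho[0], tau[0], sigmas[0]
            lp = pmap.log_prior(beta, rho, tau, sigmas)
            if not np.isfinite(lp):
                return -np.inf
            ll = _marginal_loglik(data, beta, rho, tau, sigmas)
            return lp + ll if np.isfinite(ll) else -np.inf

        theta0 = _init_theta(data, pmap, config)
        nw = max(config.n_walkers, 2 * pmap.ndim + 2)
        p0 = theta0[None, :] + 0.02 * rng.standard_normal((nw, pmap.ndim))
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]  # differential-evolution moves mix far faster here than stretch moves
        sampler = emcee.EnsembleSampler(nw, pmap.ndim, log_prob, moves=moves)
        sampler._random = np.random.RandomState(
            int(rng.integers(0, 2**31 - 1))
        )  # reproducible ensemble moves
        sampler.run_mcmc(p0, config.n_burn + config.n_steps, progress=False)
        chain = sampler.get_chain()[config.n_burn :]  # (steps, walkers, ndim)

        import arviz as az  # deferred: slow import

        rhat = {
            name: float(az.rhat(np.swapaxes(chain[:, :, d], 0, 1)))
            for d, name in enumerate(pmap.names)
        }
        diagnostics["rhat"] = rhat
        diagnostics["acceptance_fraction"] = float(sampler.acceptance_fraction.mean())
        worst = max(rhat.values())
        diagnostics["converged"] = bool(worst < RHAT_WARN)
        if worst >= RHAT_WARN:
            logger.warning(
                "age group %s: split-chain R-hat %.3f above %.2f; treat estimates "
                "with caution",
                data.age_group,
                worst,
                RHAT_WARN,
            )
        flat = chain.reshape(-1, pmap.ndim)
        idx = np.linspace(0, len(flat) - 1, config.n_draws).astype(int)
        thetas = flat[idx]

    beta, rho, tau, sigmas = pmap.unpack(thetas)
    beta = np.array(beta, dtype=float)
    m, W = _cell_stats_per_draw(data, beta, np.asarray(sigmas, dtype=float))
    delta = ar1_ffbs(m, W, np.asarray(rho, float), np.asarray(tau, float), rng)
    f_grid = beta @ data.A_grid.T  # (n_draw, nc*ny)
    s_draws = np.exp(f_grid.reshape(-1, data.nc, data.ny) + delta)
    hyper = pd.DataFrame({"rho": rho, "tau": tau})
    for k, src in enumerate(pmap.sources):
        hyper[f"sigma_{src}"] = sigmas[:, k]
    return {
        "s_draws": s_draws,
        "delta_draws": delta,
        "knots": data.knots,
        "curve_values_draws": beta,
        "hyper": hyper,
        "diagnostics": diagnostics,
    }


def fit_model(
    data: ObservationTable, totals: TotalMortalitySeries, config: ModelConfig
) -> PosteriorTrajectories:
    """Fit the hierarchical model and return posterior trajectory draws.

    Each age group on the totals grid is fitted with its own curve and
    hyperparameters. Observations are assigned to the model year nearest
    their decimal reference year. Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    na, nc, ny = totals.q.shape
    s_draws = np.empty((config.n_draws, na, nc, ny))
    delta_draws = np.empty_like(s_draws)
    curve_knots: dict[str, np.ndarray] = {}
    curve_values: dict[str, np.ndarray] = {}
    hyper: dict[str, pd.DataFrame] = {}
    diagnostics: dict = {}
    for i, age in enumerate(totals.age_groups):
        sub = data.records[data.records["age_group"] == age]
        if sub.empty:
            raise ValueError(f"no observations for modelled age group {age!r}")
        age_data = _AgeData(sub, totals, i, config)
        res = _fit_age_group(age_data, config, rng)
        s_draws[:, i] = res["s_draws"]
        delta_draws[:, i] = res["delta_draws"]
        curve_knots[age] = res["knots"]
        curve_values[age] = res["curve_values_draws"]
        hyper[age] = res["hyper"]
        diagnostics[age] = res["diagnostics"]
    return PosteriorTrajectories(
        age_groups=totals.age_groups,
        countries=totals.countries,
        years=totals.years,
        s_draws=s_draws,
        delta_draws=delta_draws,
        curve_knots=curve_knots,
        curve_values_draws=curve_values,
        hyper_draws=hyper,
        diagnostics=diagnostics,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# sex-specific trajectories


def weights_to_array(
    weights: pd.DataFrame, totals: TotalMortalitySeries
) -> np.ndarray:
    """Pivot a long (country, year, age_group, w_male) frame onto the grid."""
    wide = weights.set_index(["age_group", "country_code", "year"])["w_male"]
    na, nc, ny = totals.q.shape
    out = np.empty((na, nc, ny))
    for i, a in enumerate(totals.age_groups):
        for j, c in enumerate(totals.countries):
            try:
                out[i, j] = wide.loc[a, c].reindex(totals.years).to_numpy()
            except KeyError as exc:
                raise ValueError(f"missing weights for ({c}, {a})") from exc
    if np.isnan(out).any():
        raise ValueError("missing w_male for part of the (age, country, year) grid")
    return out


def trajectories_to_sex_specific(
    traj: PosteriorTrajectories,
    totals: TotalMortalitySeries,
    weights,
    seed: int | None = None,
) -> PosteriorTrajectories:
    """Fill sex-specific mortality draws by splitting total-mortality draws.

    Each sex-ratio draw is paired with one total-mortality draw (after an
    independent shuffle driven by the run seed), so the marginal uncertainty
    of q_male and q_female reflects both the sex-ratio posterior and the
    published uncertainty of the totals. With point totals the split is
    applied draw-wise to the single total.
    """
    from .derived import sex_split  # local import to avoid a module cycle

    if isinstance(weights, pd.DataFrame):
        w = weights_to_array(weights, totals)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != totals.q.shape:
            raise ValueError(f"weights must have shape {totals.q.shape}")
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("w_male must lie in (0, 1)")
    nd = traj.n_draws
    if totals.draws is None:
        q_tot = np.broadcast_to(totals.q, (nd,) + totals.q.shape)
    else:
        rng = np.random.default_rng(traj.seed if seed is None else seed)
        nt = totals.draws.shape[0]
        order = rng.permutation(nt)
        idx = order[np.arange(nd) % nt]
        q_tot = totals.draws[idx]
    q_male, q_female = sex_split(q_tot, traj.s_draws, w[None, ...])
    traj.q_male_draws = q_male
    traj.q_female_draws = q_female
    return traj
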