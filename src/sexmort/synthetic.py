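"""Synthetic study inputs with known ground truth.

Generates the three inputs the pipeline needs — declining total-mortality
trajectories, a true global sex-ratio-vs-mortality curve with AR(1) country
multipliers, and noisy multi-source observations — so every downstream stage
can be tested against a known truth without external downloads.

Default parameters describe a plausible multi-country study: 60 countries
followed over 1990-2021 in the under-5 age group, country multipliers with
lag-one correlation 0.9 and stationary SD 0.1 on the log scale, and a source
mix dominated by vital registration and full birth histories. Non-sampling
SDs grow from VR (0.025) through FBH (0.05) and SBH (0.075) to census
reports (0.10); sampling SEs are drawn per observation from source-specific
ranges (VR small, surveys larger), mirroring the error structure real
multi-source mortality databases exhibit.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .model import GlobalCurve, TotalMortalitySeries, expected_sex_ratio
from .obs_db import (
    ObservationTable,
    REPORTING_AGE_GROUPS,
    SOURCE_TYPES,
    YEAR_MAX,
    YEAR_MIN,
)

_DEFAULT_CURVES = {
    # log total mortality knots; the expected ratio rises as mortality falls,
    # with a mild reversal at very low mortality
    "0-4": (
        np.log([3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1, 3e-1]),
        np.log([1.18, 1.22, 1.20, 1.15, 1.10, 1.05, 1.00]),
    ),
    "5-14": (
        np.log([1e-4, 3e-4, 1e-3, 3e-3, 1e-2, 3e-2, 1e-1]),
        np.log([1.40, 1.45, 1.40, 1.28, 1.15, 1.06, 1.00]),
    ),
    "15-24": (
        np.log([2e-4, 5e-4, 1.5e-3, 5e-3, 1.5e-2, 5e-2, 1.5e-1]),
        np.log([2.40, 2.50, 2.20, 1.80, 1.40, 1.12, 1.00]),
    ),
}

_Q0_RANGES = {"0-4": (0.02, 0.25), "5-14": (0.004, 0.05), "15-24": (0.006, 0.08)}


def default_true_curve(age_group: str) -> GlobalCurve:
    """The generating expected-sex-ratio curve for an age group."""
    knots, values = _DEFAULT_CURVES[age_group]
    return GlobalCurve(age_group, knots.copy(), values.copy())


def _country_codes(n: int) -> tuple[str, ...]:
    letters = string.ascii_uppercase
    codes = ["".join(t) for t in product(letters, repeat=3)]
    return tuple(codes[:n])


@dataclass
class SimulationConfig:
    """Ground-truth parameters and sampling design of a synthetic study."""

    n_countries: int = 60
    year_start: int = 1990
    year_end: int = 2021
    age_groups: tuple[str, ...] = ("0-4",)
    curve_truth: dict[str, GlobalCurve] = field(default_factory=dict)
    rho_truth: float = 0.9
    tau_truth: float = 0.1
    sigma_by_source: dict[str, float] = field(
        default_factory=lambda: {"VR": 0.025, "FBH": 0.05, "SBH": 0.075, "CENSUS": 0.10}
    )
    source_mix: dict[str, float] = field(
        default_factory=lambda: {"VR": 0.4, "FBH": 0.3, "SBH": 0.2, "CENSUS": 0.1}
    )
    #: per-observation sampling SE drawn uniformly from the source's range
    sampling_se_range_by_source: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "VR": (0.01, 0.05),
            "FBH": (0.05, 0.15),
            "SBH": (0.05, 0.15),
            "CENSUS": (0.03, 0.10),
        }
    )
    obs_per_country_year: float = 1.0
    q0_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_Q0_RANGES)
    )
    decline_range: tuple[float, float] = (0.01, 0.04)
    totals_noise_sd: float = 0.03
    #: when > 0, also emit that many uncertainty draws around the totals
    total_draws: int = 0
    total_draw_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        for a in self.age_groups:
            if a not in REPORTING_AGE_GROUPS:
                raise ValueError(f"unknown age group {a!r}")
            if a not in self.curve_truth:
                self.curve_truth[a] = default_true_curve(a)
        if not (0 < self.rho_truth < 1):
            raise ValueError("rho_truth must lie in (0, 1)")
        if self.tau_truth < 0:
            raise ValueError("tau_truth must be >= 0")
        for src, sig in self.sigma_by_source.items():
            if src not in SOURCE_TYPES or sig < 0:
                raise ValueError(f"bad sigma for source {src!r}")
        mix_total = sum(self.source_mix.values())
        if abs(mix_total - 1.0) > 1e-12:
            raise ValueError(f"source_mix must sum to 1, got {mix_total}")
        if self.obs_per_country_year < 0:
            raise ValueError("obs_per_country_year must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def countries(self) -> tuple[str, ...]:
        return _country_codes(self.n_countries)


@dataclass
class SyntheticTruth:
    """The generated ground truth: totals, true ratios and true multipliers.

    Satisfies ``s_true = f_truth(Q) * exp(delta_true)`` element-wise.
    """

    totals: TotalMortalitySeries
    s_true: np.ndarray
    delta_true: np.ndarray
    config: SimulationConfig


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def simulate_total_mortality(config: SimulationConfig) -> TotalMortalitySeries:
    """Declining both-sex mortality trajectories per country and age group.

    log q(t) = log q0 - r (t - t0) + noise, with country-level starting level
    q0 (log-uniform in the age group's range) and annual decline rate r
    (uniform in ``decline_range``); clipped to (1e-6, 0.9).
    """
    rng = _rng(config, 0)
    years = config.years
    na, nc, ny = len(config.age_groups), config.n_countries, len(years)
    q = np.empty((na, nc, ny))
    for i, age in enumerate(config.age_groups):
        lo, hi = config.q0_range[age]
        q0 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=nc))
        r = rng.uniform(*config.decline_range, size=nc)
        noise = rng.normal(0.0, config.totals_noise_sd, size=(nc, ny))
        t = years - years[0]
        q[i] = np.exp(np.log(q0)[:, None] - r[:, None] * t[None, :] + noise)
    q = np.clip(q, 1e-6, 0.9)
    draws = None
    if config.total_draws > 0:
        eps = rng.normal(0.0, config.total_draw_sd, size=(config.total_draws, na, nc, ny))
        draws = np.clip(q[None] * np.exp(eps), 1e-6, 0.9)
    return TotalMortalitySeries(config.age_groups, config.countries, years, q, draws)


def simulate_truth(
    totals: TotalMortalitySeries, config: SimulationConfig
) -> SyntheticTruth:
    """True sex-ratio surface: global curve times stationary AR(1) multipliers."""
    if config.tau_truth < 0:
        raise ValueError("tau_truth must be >= 0")
    rng = _rng(config, 1)
    na, nc, ny = totals.q.shape
    delta = np.zeros((na, nc, ny))
    if config.tau_truth > 0:
        rho, tau = config.rho_truth, config.tau_truth
        innov_sd = tau * np.sqrt(1.0 - rho**2)
        delta[:, :, 0] = rng.normal(0.0, tau, size=(na, nc))
        for t in range(1, ny):
            delta[:, :, t] = rho * delta[:, :, t - 1] + rng.normal(
                0.0, innov_sd, size=(na, nc)
            )
    s_true = np.empty_like(delta)
    for i, age in enumerate(config.age_groups):
        s_true[i] = expected_sex_ratio(totals.q[i], config.curve_truth[age]) * np.exp(
            delta[i]
        )
    return SyntheticTruth(totals, s_true, delta, config)


def simulate_observations(
    truth: SyntheticTruth, config: SimulationConfig
) -> ObservationTable:
    """Noisy multi-source observations of the true sex-ratio surface.

    Per (country, year, age) cell the number of observations is Poisson with
    mean ``obs_per_country_year``. Each observation draws a source type from
    ``source_mix``, a sampling SE from that source's range, and an observed
    log ratio equal to the true log ratio plus independent sampling and
    non-sampling Normal errors.
    """
    mix_total = sum(config.source_mix.values())
    if abs(mix_total - 1.0) > 1e-12:
        raise ValueError("source_mix must sum to 1")
    rng = _rng(config, 2)
    totals = truth.totals
    sources = [s for s in SOURCE_TYPES if config.source_mix.get(s, 0.0) > 0]
    probs = np.array([config.source_mix[s] for s in sources])
    probs = probs / probs.sum()
    rows = []
    na, nc, ny = totals.q.shape
    counts = rng.poisson(config.obs_per_country_year, size=(na, nc, ny))
    for i, age in enumerate(config.age_groups):
        for j, country in enumerate(totals.countries):
            for t, year in enumerate(totals.years):
                for k in range(counts[i, j, t]):
                    src = sources[rng.choice(len(sources), p=probs)]
                    lo, hi = config.sampling_se_range_by_source[src]
                    se = rng.uniform(lo, hi)
                    log_obs = (
                        np.log(truth.s_true[i, j, t])
                        + (rng.normal(0.0, se) if se > 0 else 0.0)
                        + (
                            rng.normal(0.0, config.sigma_by_source[src])
                            if config.sigma_by_source[src] > 0
                            else 0.0
                        )
                    )
                    jitter = 0.0 if src == "VR" else rng.uniform(-0.4, 0.4)
                    ref_year = float(np.clip(year + jitter, YEAR_MIN, YEAR_MAX))
                    rows.append(
                        {
                            "country_code": country,
                            "ref_year": round(ref_year, 2),
                            "age_group": age,
                            "source_type": src,
                            "series_id": f"{src}-{k}",
                            "sex_ratio_obs": float(np.exp(log_obs)),
                            "log_se_sampling": float(se),
                            "deaths_male": np.nan,
                            "deaths_female": np.nan,
                        }
                    )
    table = ObservationTable(
        pd.DataFrame(rows),
        provenance={"generator": "sexmort.synthetic", "seed": int(config.seed)},
    )
    return table


def simulate_exposures(config: SimulationConfig) -> pd.DataFrame:
    """Exposure inputs: male entry shares and female entrant counts.

    For ages 0-4 the male share comes from a sex ratio at birth of 1.05
    (share SRB/(1+SRB)); for older groups it is a population share near 0.51
    with small country jitter. Female entrants per (country, year, age) give
    the denominators that convert rates to death counts downstream.
    """
    rng = _rng(config, 3)
    years = config.years
    rows = []
    for age in config.age_groups:
        for j, country in enumerate(config.countries):
            base_pop = np.exp(rng.uniform(np.log(2e4), np.log(2e6)))
            growth = rng.uniform(-0.005, 0.02)
            if age == "0-4":
                w_male = 1.05 / 2.05
            else:
                w_male = float(np.clip(0.51 + rng.normal(0.0, 0.003), 0.45, 0.55))
            for t, year in enumerate(years):
                rows.append(
                    {
                        "country_code": country,
                        "year": int(year),
                        "age_group": age,
                        "w_male": w_male,
                        "female_exposure": float(base_pop * np.exp(growth * t)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_region_map(config: SimulationConfig, n_regions: int = 6) -> pd.DataFrame:
    """Round-robin assignment of synthetic countries to regions."""
    return pd.DataFrame(
        {
            "country_code": list(config.countries),
            "region": [f"region_{i % n_regions + 1}" for i in range(config.n_countries)],
        }
    )
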