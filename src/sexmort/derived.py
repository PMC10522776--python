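"""Deterministic demographic transforms.

Sex-specific probabilities of dying from a total probability and a sex
ratio, expected vs estimated female mortality under the male-reference
convention, excess female mortality rates and death counts, the
two-condition outlier rule, and survival from birth to age 25.

All operations are vectorised over numpy arrays and exact; the randomised
identities they must satisfy (exposure-weighted conservation,
``q_f_est / q_f_exp = s_exp / s_est``, the sign rule) are enforced in the
test suite to 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # annotation-only; avoids a circular import with inference
    from .inference import IntervalSummary


@dataclass(frozen=True)
class SexSplitWeights:
    """Male share of exposure entering an age group (for 0-4: SRB/(1+SRB))."""

    country_code: str
    year: int
    age_group: str
    w_male: float

    def __post_init__(self) -> None:
        if not (0 < self.w_male < 1):
            raise ValueError("w_male must lie in (0, 1)")


#: demographic-convention sex ratio at birth when no country value is supplied
DEFAULT_SRB = 1.05


def srb_to_w_male(srb: float = DEFAULT_SRB) -> float:
    """Male share of births implied by a sex ratio at birth."""
    if srb <= 0:
        raise ValueError("sex ratio at birth must be > 0")
    return srb / (1.0 + srb)


def _validate_split_inputs(q_total, s, w_male) -> None:
    if np.any((np.asarray(q_total) <= 0) | (np.asarray(q_total) >= 1)):
        raise ValueError("q_total must lie strictly in (0, 1)")
    if np.any(np.asarray(s) <= 0):
        raise ValueError("sex ratio must be > 0")
    if np.any((np.asarray(w_male) <= 0) | (np.asarray(w_male) >= 1)):
        raise ValueError("w_male must lie in (0, 1)")


def sex_split(q_total, s, w_male):
    """Split a total probability of dying by sex given the sex ratio.

    Solves q_male = s * q_female and the exposure-weighted conservation
    w * q_male + (1 - w) * q_female = q_total, giving
    q_female = q_total / (w s + 1 - w). Returns ``(q_male, q_female)``.
    """
    _validate_split_inputs(q_total, s, w_male)
    q_total = np.asarray(q_total, dtype=float)
    s = np.asarray(s, dtype=float)
    w = np.asarray(w_male, dtype=float)
    q_female = q_total / (w * s + 1.0 - w)
    q_male = s * q_female
    if np.any(q_male >= 1):
        raise ValueError("inconsistent inputs: implied q_male >= 1")
    if q_male.ndim == 0:
        return float(q_male), float(q_female)
    return q_male, q_female


def excess_female_rate(q_total, s_est, s_exp, w_male):
    """Expected and estimated female mortality with male mortality as reference.

    Male mortality is pinned at its estimated level; the expected female rate
    is what that male rate would imply under the expected sex ratio. Returns
    ``(q_female_est, q_female_exp, excess_rate)`` with
    excess = estimated - expected (negative = female advantage). The identity
    q_female_est / q_female_exp = s_exp / s_est holds exactly.
    """
    if np.any(np.asarray(s_exp) <= 0):
        raise ValueError("s_exp must be > 0")
    q_male_est, q_female_est = sex_split(q_total, s_est, w_male)
    q_female_exp = np.asarray(q_male_est) / np.asarray(s_exp, dtype=float)
    excess = np.asarray(q_female_est) - q_female_exp
    if np.ndim(excess) == 0:
        return float(q_female_est), float(q_female_exp), float(excess)
    return q_female_est, q_female_exp, excess


def excess_deaths(female_deaths_est, ratio_est_exp):
    """Excess female deaths implied by the estimated:expected mortality ratio.

    Per draw: deaths * (1 - 1/R) with R = q_female_est / q_female_exp;
    negative when R < 1 (fewer deaths than expected).
    """
    r = np.asarray(ratio_est_exp, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ratio_est_exp must be > 0")
    if female_deaths_est < 0:
        raise ValueError("female_deaths_est must be >= 0")
    out = female_deaths_est * (1.0 - 1.0 / r)
    return float(out) if out.ndim == 0 else out


def flag_outlier(
    excess_rate_draws,
    prob_threshold: float = 0.95,
    magnitude_threshold: float = 0.001,
):
    """Two-condition outlier rule on posterior draws of the excess rate.

    A country-year is outlying iff (1) the posterior probability that excess
    female mortality is positive, or that it is negative, reaches
    ``prob_threshold`` and (2) the absolute median excess exceeds
    ``magnitude_threshold`` (one death per 1000 at the default). Returns
    ``(prob_excess_positive, prob_excess_negative, outlier_flag)``.
    """
    draws = np.asarray(excess_rate_draws, dtype=float)
    if draws.ndim != 1 or draws.size < 100:
        raise ValueError("need at least 100 draws of the excess rate")
    p_pos = float(np.mean(draws > 0))
    p_neg = float(np.mean(draws < 0))
    median = float(np.median(draws))
    flag = (max(p_pos, p_neg) >= prob_threshold) and (abs(median) > magnitude_threshold)
    return p_pos, p_neg, bool(flag)


def survival_to_25(q_0_4, q_5_14, q_15_24):
    """Probability a newborn reaches age 25: product of interval survivals."""
    qs = [np.asarray(q, dtype=float) for q in (q_0_4, q_5_14, q_15_24)]
    for q in qs:
        if np.any((q < 0) | (q > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
    out = (1.0 - qs[0]) * (1.0 - qs[1]) * (1.0 - qs[2])
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class ExcessResult:
    """Excess-female-mortality summary for one (country, year, age group)."""

    country_code: str
    year: int
    age_group: str
    q_female_est: IntervalSummary
    q_female_exp: IntervalSummary
    ratio_est_exp: IntervalSummary
    excess_rate_per_1000: IntervalSummary
    excess_deaths: IntervalSummary
    prob_excess_positive: float
    prob_excess_negative: float
    outlier_flag: bool


def excess_table(
    traj,
    totals,
    exposures,
    prob_threshold: float = 0.95,
    magnitude_threshold: float = 0.001,
    level: float = 0.90,
):
    """Excess-female-mortality summary for every (country, year, age group).

    Applies the male-reference convention draw-wise: the estimated male rate
    is held fixed, the expected female rate is what it would imply under the
    expected sex ratio (the fitted curve without the country multiplier),
    and excess = estimated - expected. Excess deaths convert the
    estimated:expected ratio into counts via the estimated female deaths.
    Returns a long DataFrame with medians, 90% intervals, tail probabilities
    and the two-condition outlier flag.
    """
    import pandas as pd

    from .inference import weights_to_array

    w = weights_to_array(exposures, totals)
    fem = exposures.set_index(["age_group", "country_code", "year"])["female_exposure"]
    na, nc, ny = totals.q.shape
    fem_arr = np.empty((na, nc, ny))
    for i, a in enumerate(totals.age_groups):
        for j, c in enumerate(totals.countries):
            fem_arr[i, j] = fem.loc[a, c].reindex(totals.years).to_numpy()
    if np.isnan(fem_arr).any():
        raise ValueError("missing female_exposure for part of the grid")

    s_est = traj.s_draws
    s_exp = traj.expected_ratio_draws(totals)
    q_tot = np.broadcast_to(totals.q, s_est.shape)
    q_f_est, q_f_exp, excess = excess_female_rate(q_tot, s_est, s_exp, w[None])
    ratio = q_f_est / q_f_exp
    fde_point = np.median(q_f_est, axis=0) * fem_arr
    deaths = fde_point[None] * (1.0 - 1.0 / ratio)

    alpha = (1.0 - level) / 2.0
    qs = [alpha, 0.5, 1.0 - alpha]
    p_pos = np.mean(excess > 0, axis=0)
    p_neg = np.mean(excess < 0, axis=0)
    med_excess = np.median(excess, axis=0)
    flag = (np.maximum(p_pos, p_neg) >= prob_threshold) & (
        np.abs(med_excess) > magnitude_threshold
    )

    base = pd.DataFrame(
        {
            "age_group": np.repeat(totals.age_groups, nc * ny),
            "country_code": np.tile(np.repeat(totals.countries, ny), na),
            "year": np.tile(totals.years, na * nc),
        }
    )
    for name, draws, scale in [
        ("s_est", s_est, 1.0),
        ("s_exp", s_exp, 1.0),
        ("q_female_est", q_f_est, 1.0),
        ("q_female_exp", q_f_exp, 1.0),
        ("ratio_est_exp", ratio, 1.0),
        ("excess_rate_per_1000", excess, 1000.0),
        ("excess_deaths", deaths, 1.0),
    ]:
        lo, med, hi = np.quantile(draws * scale, qs, axis=0).reshape(3, -1)
        base[f"{name}_median"] = med
        base[f"{name}_lower"] = lo
        base[f"{name}_upper"] = hi
    base["prob_excess_positive"] = p_pos.ravel()
    base["prob_excess_negative"] = p_neg.ravel()
    base["outlier_flag"] = flag.ravel()
    return base
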