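"""Country-to-region and world aggregation of sex-specific mortality.

Regional sex-specific rates are obtained by applying the proportions of
sex-specific deaths within a region to the region's aggregate total
mortality; death counts are summed draw-wise across member countries so
that every summary preserves within-draw coherence, and crisis-related
deaths can be added post-model per sex.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .inference import PosteriorTrajectories, weights_to_array
from .model import TotalMortalitySeries


def load_region_map(path) -> pd.DataFrame:
    """Read a country -> region map CSV (columns country_code, region)."""
    df = pd.read_csv(path)
    for col in ("country_code", "region"):
        if col not in df.columns:
            raise ValueError(f"region map missing column {col!r}")
    if df.empty:
        raise ValueError("region map is empty")
    if df["country_code"].duplicated().any():
        raise ValueError("region map assigns a country to more than one region")
    return df


def regions_for(region_map: pd.DataFrame, countries) -> np.ndarray:
    """Region label per country; every modelled country must be mapped."""
    lookup = dict(zip(region_map["country_code"], region_map["region"]))
    missing = [c for c in countries if c not in lookup]
    if missing:
        raise ValueError(f"countries missing from the region map: {missing[:5]}")
    return np.array([lookup[c] for c in countries])


def aggregate_region_rates(
    deaths_female, deaths_male, q_total_region, exposure_shares
):
    """Regional sex-specific probabilities from death shares and exposure shares.

    q_female = q_total * (female death share) / (female exposure share), and
    analogously for males, so that the exposure-weighted mean of the two
    sex-specific probabilities reproduces the regional total exactly.
    """
    c_female, c_male = exposure_shares
    if np.any(np.asarray(c_female) <= 0) or np.any(np.asarray(c_male) <= 0):
        raise ValueError("exposure shares must lie in (0, 1)")
    if np.any(np.abs(np.asarray(c_female) + np.asarray(c_male) - 1.0) > 1e-9):
        raise ValueError("exposure shares must sum to 1")
    df = np.asarray(deaths_female, dtype=float)
    dm = np.asarray(deaths_male, dtype=float)
    if np.any(df < 0) or np.any(dm < 0):
        raise ValueError("death counts must be >= 0")
    total = df + dm
    if np.any(total <= 0):
        raise ValueError("total deaths must be > 0 to form death shares")
    q_female = q_total_region * (df / total) / c_female
    q_male = q_total_region * (dm / total) / c_male
    if np.ndim(q_female) == 0:
        return float(q_female), float(q_male)
    return q_female, q_male


def male_share_of_deaths(deaths_female, deaths_male) -> float:
    """Percentage of deaths that are male, summed over the supplied age groups."""
    df = float(np.sum(deaths_female))
    dm = float(np.sum(deaths_male))
    if df + dm <= 0:
        raise ValueError("total deaths must be > 0")
    return 100.0 * dm / (df + dm)


def apply_crisis_adjustment(deaths_female, deaths_male, crisis=None):
    """Add sex-specific crisis death counts to modelled counts (identity if None).

    ``crisis`` is a (crisis_female, crisis_male) pair; the sex split of
    crisis deaths must be supplied by the caller.
    """
    if crisis is None:
        return deaths_female, deaths_male
    crisis_female, crisis_male = crisis
    if np.any(np.asarray(crisis_female) < 0) or np.any(np.asarray(crisis_male) < 0):
        raise ValueError("crisis death counts must be >= 0")
    return deaths_female + crisis_female, deaths_male + crisis_male


def load_global_death_counts() -> pd.DataFrame:
    """Published global sex-specific death counts (thousands) by age group.

    Columns: year, age_group, deaths_female_thousands, deaths_male_thousands
    for 1990 and 2021 — the inputs for the male-share-of-deaths identity.
    """
    with resources.files("sexmort.data").joinpath("global_deaths_by_sex.csv").open() as fh:
        return pd.read_csv(fh)


def region_aggregates(
    traj: PosteriorTrajectories,
    totals: TotalMortalitySeries,
    exposures: pd.DataFrame,
    region_map: pd.DataFrame,
    level: float = 0.90,
) -> pd.DataFrame:
    """Draw-wise regional death counts, rates and male shares of deaths.

    Requires sex-specific draws (run ``trajectories_to_sex_specific`` first).
    Country deaths are q_sex * sex-specific entrants; regional counts are
    within-draw sums over member countries, and regional rates follow from
    the death shares and exposure shares.
    """
    if traj.q_female_draws is None:
        raise ValueError("sex-specific draws missing; fill them before aggregating")
    w = weights_to_array(exposures.rename(columns={"w_male": "w_male"}), totals)
    fem = (
        exposures.set_index(["age_group", "country_code", "year"])["female_exposure"]
    )
    na, nc, ny = totals.q.shape
    fem_arr = np.empty((na, nc, ny))
    for i, a in enumerate(totals.age_groups):
        for j, c in enumerate(totals.countries):
            fem_arr[i, j] = fem.loc[a, c].reindex(totals.years).to_numpy()
    if np.isnan(fem_arr).any():
        raise ValueError("missing female_exposure for part of the grid")
    male_arr = fem_arr * w / (1.0 - w)

    deaths_f = traj.q_female_draws * fem_arr[None]
    deaths_m = traj.q_male_draws * male_arr[None]

    regions = regions_for(region_map, totals.countries)
    labels = list(pd.unique(regions)) + ["world"]
    alpha = (1.0 - level) / 2.0
    rows = []
    for label in labels:
        members = np.ones(nc, dtype=bool) if label == "world" else regions == label
        rf = deaths_f[:, :, members, :].sum(axis=2)  # (nd, na, ny)
        rm = deaths_m[:, :, members, :].sum(axis=2)
        fem_tot = fem_arr[:, members, :].sum(axis=1)
        male_tot = male_arr[:, members, :].sum(axis=1)
        entrants = fem_tot + male_tot
        c_f = fem_tot / entrants
        q_region = (
            (totals.q[:, members, :] * (fem_arr + male_arr)[:, members, :]).sum(axis=1)
            / entrants
        )
        share = 100.0 * rm / (rf + rm)
        qf_region, qm_region = aggregate_region_rates(
            rf, rm, q_region[None], (c_f[None], 1.0 - c_f[None])
        )
        for i, age in enumerate(totals.age_groups):
            for t, year in enumerate(totals.years):
                lo_f, med_f, hi_f = np.quantile(rf[:, i, t], [alpha, 0.5, 1 - alpha])
                lo_m, med_m, hi_m = np.quantile(rm[:, i, t], [alpha, 0.5, 1 - alpha])
                lo_s, med_s, hi_s = np.quantile(share[:, i, t], [alpha, 0.5, 1 - alpha])
                rows.append(
                    {
                        "region": label,
                        "year": int(year),
                        "age_group": age,
                        "deaths_female_median": med_f,
                        "deaths_female_lower": lo_f,
                        "deaths_female_upper": hi_f,
                        "deaths_male_median": med_m,
                        "deaths_male_lower": lo_m,
                        "deaths_male_upper": hi_m,
                        "male_share_pct_median": med_s,
                        "male_share_pct_lower": lo_s,
                        "male_share_pct_upper": hi_s,
                        "q_total_region": q_region[i, t],
                        "q_female_region_median": np.median(qf_region[:, i, t]),
                        "q_male_region_median": np.median(qm_region[:, i, t]),
                    }
                )
    return pd.DataFrame(rows)
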