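"""Out-of-sample validation of the fitted model.

Holds out a fraction of the observation database (stratified by age group),
refits on the remainder, and checks whether 90% predictive intervals for the
held-out observed log ratios — posterior of log S plus the observation's
sampling and non-sampling noise — cover them at the nominal rate. A
well-calibrated (or conservative) model covers at least ~90%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorTrajectories
from .model import ErrorModel, nearest_year_index
from .obs_db import ObservationTable


@dataclass
class ValidationReport:
    """Predictive coverage and error metrics on held-out observations."""

    holdout_fraction: float
    n_holdout: int
    coverage: float
    mean_error: float
    median_error: float
    by_source: pd.DataFrame
    level: float = 0.90

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")
        if self.n_holdout <= 0:
            raise ValueError("n_holdout must be > 0")

    def to_frame(self) -> pd.DataFrame:
        head = pd.DataFrame(
            {
                "source_type": ["ALL"],
                "n": [self.n_holdout],
                "coverage": [self.coverage],
                "mean_error": [self.mean_error],
                "median_error": [self.median_error],
            }
        )
        return pd.concat([head, self.by_source], ignore_index=True)


def holdout_split(
    table: ObservationTable,
    fraction: float = 0.20,
    seed: int = 0,
    scheme: str = "random",
) -> tuple[ObservationTable, ObservationTable]:
    """Partition the observation table into train and holdout sets.

    ``scheme='random'`` draws the holdout uniformly at random within each age
    group (size ``round(fraction * n)`` per stratum); ``scheme='recent'``
    holds out the latest observations by reference year instead, which
    exercises the model's short-term projection behaviour.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    if len(table) == 0:
        raise ValueError("cannot split an empty table")
    df = table.records
    holdout_mask = np.zeros(len(df), dtype=bool)
    rng = np.random.default_rng(seed)
    for age in table.age_groups:
        idx = np.flatnonzero((df["age_group"] == age).to_numpy())
        k = int(round(fraction * idx.size))
        if k == 0:
            continue
        if scheme == "random":
            chosen = rng.permutation(idx)[:k]
        elif scheme == "recent":
            order = np.argsort(df["ref_year"].to_numpy()[idx], kind="stable")
            chosen = idx[order[-k:]]
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        holdout_mask[chosen] = True
    train = ObservationTable(df.loc[~holdout_mask].reset_index(drop=True), dict(table.provenance))
    holdout = ObservationTable(df.loc[holdout_mask].reset_index(drop=True), dict(table.provenance))
    return train, holdout


def coverage_report(
    fitted: PosteriorTrajectories,
    holdout: ObservationTable,
    error_model: ErrorModel,
    level: float = 0.90,
    seed: int | None = None,
    holdout_fraction: float = float("nan"),
) -> ValidationReport:
    """Predictive-interval coverage of held-out observed log ratios.

    For each held-out record the predictive draws are log S at the record's
    (country, year, age) cell plus Normal noise with variance equal to the
    record's sampling variance plus its source's non-sampling variance from
    ``error_model``; the interval is the equal-tail ``level`` interval of
    those draws. Errors are observed log ratio minus posterior median log S.
    """
    df = holdout.records
    if df.empty:
        raise ValueError("holdout table is empty")
    country_index = {c: i for i, c in enumerate(fitted.countries)}
    age_index = {a: i for i, a in enumerate(fitted.age_groups)}
    rng = np.random.default_rng(fitted.seed if seed is None else seed)
    alpha = (1.0 - level) / 2.0
    covered = np.zeros(len(df), dtype=bool)
    errors = np.zeros(len(df))
    for k, rec in enumerate(df.itertuples()):
        if rec.age_group not in age_index or rec.country_code not in country_index:
            raise ValueError(
                f"holdout record ({rec.country_code}, {rec.age_group}) outside fitted grid"
            )
        a = age_index[rec.age_group]
        c = country_index[rec.country_code]
        t = nearest_year_index(fitted.years, float(rec.ref_year))
        log_s = np.log(fitted.s_draws[:, a, c, t])
        sd = np.sqrt(rec.log_se_sampling**2 + error_model.sigma(rec.source_type) ** 2)
        pred = log_s + (sd * rng.standard_normal(log_s.size) if sd > 0 else 0.0)
        lo, hi = np.quantile(pred, [alpha, 1.0 - alpha])
        y = np.log(rec.sex_ratio_obs)
        covered[k] = lo <= y <= hi
        errors[k] = y - np.median(log_s)
    by_source = (
        pd.DataFrame(
            {
                "source_type": df["source_type"].to_numpy(),
                "covered": covered,
                "error": errors,
            }
        )
        .groupby("source_type")
        .agg(n=("covered", "size"), coverage=("covered", "mean"),
             mean_error=("error", "mean"), median_error=("error", "median"))
        .reset_index()
    )
    return ValidationReport(
        holdout_fraction=holdout_fraction,
        n_holdout=len(df),
        coverage=float(covered.mean()),
        mean_error=float(errors.mean()),
        median_error=float(np.median(errors)),
        by_source=by_source,
        level=level,
    )
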