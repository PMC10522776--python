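"""Multi-source observation database for sex ratios of mortality.

One observation is the ratio of the male to the female mortality rate for a
country, reference period and age group, extracted from vital registration
(VR), survey full birth histories (FBH), survey sibling histories (SBH) or
census reports on household deaths (CENSUS), together with the standard
error of its logarithm from sampling/stochastic variation.

This module defines the record schema, CSV input/output with row-level
validation, the Poisson delta-method sampling variance for count-backed
ratios, the aggregation of fine age groups to the three reporting groups,
and the removal of extreme (physically implausible) ratios.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FINE_AGE_GROUPS = ("U1", "1-4", "5-9", "10-14", "15-19", "20-24")
REPORTING_AGE_GROUPS = ("0-4", "5-14", "15-24")
AGE_GROUPS = FINE_AGE_GROUPS + REPORTING_AGE_GROUPS

#: fine age groups that exactly tile each reporting group
FINE_CONSTITUENTS = {
    "0-4": ("U1", "1-4"),
    "5-14": ("5-9", "10-14"),
    "15-24": ("15-19", "20-24"),
}

SOURCE_TYPES = ("VR", "FBH", "SBH", "CENSUS")

# earliest data year in scope and the end of the estimation horizon
YEAR_MIN = 1954.0
YEAR_MAX = 2021.0

SCHEMA_VERSION = "1"
REQUIRED_COLUMNS = [
    "country_code",
    "ref_year",
    "age_group",
    "source_type",
    "series_id",
    "sex_ratio_obs",
    "log_se_sampling",
]
OPTIONAL_COLUMNS = ["deaths_male", "deaths_female"]
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS
KEY_COLUMNS = ["country_code", "ref_year", "age_group", "series_id"]


class SchemaError(ValueError):
    """The observation file does not match the expected schema."""


@dataclass(frozen=True)
class ObservationRecord:
    """A single observed male:female mortality-rate ratio.

    ``log_se_sampling`` is the standard deviation of ``log(sex_ratio_obs)``
    attributable to sampling/stochastic error only; source-specific
    non-sampling error is modelled separately (see :mod:`sexmort.model`).
    """

    country_code: str
    ref_year: float
    age_group: str
    source_type: str
    series_id: str
    sex_ratio_obs: float
    log_se_sampling: float
    deaths_male: float | None = None
    deaths_female: float | None = None

    def validation_error(self) -> str | None:
        """Return the first invariant violation, or None if valid."""
        if not self.country_code:
            return "empty country_code"
        if self.age_group not in AGE_GROUPS:
            return f"unknown age_group {self.age_group!r}"
        if self.source_type not in SOURCE_TYPES:
            return f"unknown source_type {self.source_type!r}"
        if not np.isfinite(self.ref_year) or not (YEAR_MIN <= self.ref_year <= YEAR_MAX):
            return f"ref_year {self.ref_year} outside [{YEAR_MIN}, {YEAR_MAX}]"
        if not np.isfinite(self.sex_ratio_obs) or self.sex_ratio_obs <= 0:
            return f"sex_ratio_obs {self.sex_ratio_obs} not a positive finite ratio"
        if not np.isfinite(self.log_se_sampling) or self.log_se_sampling < 0:
            return f"log_se_sampling {self.log_se_sampling} not finite and >= 0"
        return None


@dataclass
class ObservationTable:
    """Validated collection of observation records with provenance metadata.

    ``records`` is a DataFrame with the columns of the CSV schema; rows are
    kept in input order. Duplicate (country, ref_year, age_group, series_id)
    keys are rejected.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        for col in OPTIONAL_COLUMNS:
            if col not in self.records.columns:
                self.records[col] = np.nan
        self.records = self.records[ALL_COLUMNS].reset_index(drop=True)
        df = self.records
        if len(df):
            if df.duplicated(KEY_COLUMNS).any():
                dups = df[df.duplicated(KEY_COLUMNS)].iloc[0]
                raise ValueError(
                    "duplicate observation key "
                    f"{tuple(dups[k] for k in KEY_COLUMNS)}"
                )
            bad = _row_errors(df)
            first_bad = next((r for r in bad if r is not None), None)
            if first_bad is not None:
                raise ValueError(f"invalid observation row: {first_bad}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["age_group"]))

    def subset(self, age_group: str) -> "ObservationTable":
        sub = self.records[self.records["age_group"] == age_group]
        return ObservationTable(sub.copy(), dict(self.provenance))

    def to_records(self) -> list[ObservationRecord]:
        return [
            ObservationRecord(
                country_code=r.country_code,
                ref_year=float(r.ref_year),
                age_group=r.age_group,
                source_type=r.source_type,
                series_id=str(r.series_id),
                sex_ratio_obs=float(r.sex_ratio_obs),
                log_se_sampling=float(r.log_se_sampling),
                deaths_male=None if pd.isna(r.deaths_male) else float(r.deaths_male),
                deaths_female=None if pd.isna(r.deaths_female) else float(r.deaths_female),
            )
            for r in self.records.itertuples()
        ]


def _row_errors(df: pd.DataFrame) -> list[str | None]:
    """Per-row invariant check; vectorised, returns a reason or None per row."""
    n = len(df)
    reasons: list[str | None] = [None] * n
    ratio = pd.to_numeric(df["sex_ratio_obs"], errors="coerce").to_numpy(float)
    se = pd.to_numeric(df["log_se_sampling"], errors="coerce").to_numpy(float)
    year = pd.to_numeric(df["ref_year"], errors="coerce").to_numpy(float)
    age_ok = df["age_group"].isin(AGE_GROUPS).to_numpy()
    src_ok = df["source_type"].isin(SOURCE_TYPES).to_numpy()
    for i in range(n):
        if not age_ok[i]:
            reasons[i] = f"unknown age_group {df['age_group'].iat[i]!r}"
        elif not src_ok[i]:
            reasons[i] = f"unknown source_type {df['source_type'].iat[i]!r}"
        elif not np.isfinite(year[i]) or not (YEAR_MIN <= year[i] <= YEAR_MAX):
            reasons[i] = f"ref_year {year[i]} outside [{YEAR_MIN}, {YEAR_MAX}]"
        elif not np.isfinite(ratio[i]) or ratio[i] <= 0:
            reasons[i] = f"sex_ratio_obs {ratio[i]} not a positive finite ratio"
        elif not np.isfinite(se[i]) or se[i] < 0:
            reasons[i] = f"log_se_sampling {se[i]} not finite and >= 0"
    return reasons


def load_observations(path, schema_version: str = SCHEMA_VERSION) -> ObservationTable:
    """Read and validate an observation CSV.

    Invalid rows are rejected (not fatal) and reported through the logger and
    in ``table.provenance['rejections']`` with one reason per rejected row.
    A missing required column or an empty file is fatal.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty observation file {path}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if raw.empty:
        raise SchemaError(f"{path}: no observation rows")
    for col in OPTIONAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    for col in ["ref_year", "sex_ratio_obs", "log_se_sampling"] + OPTIONAL_COLUMNS:
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    raw["series_id"] = raw["series_id"].astype(str)

    # fill sampling SE from death counts where absent
    need_se = raw["log_se_sampling"].isna()
    have_counts = raw["deaths_male"].gt(0) & raw["deaths_female"].gt(0)
    fill = need_se & have_counts
    if fill.any():
        raw.loc[fill, "log_se_sampling"] = np.sqrt(
            compute_sampling_variance(
                raw.loc[fill, "deaths_male"].to_numpy(),
                raw.loc[fill, "deaths_female"].to_numpy(),
            )
        )

    reasons = _row_errors(raw)
    dup = raw.duplicated(KEY_COLUMNS).to_numpy()
    for i in np.flatnonzero(dup):
        if reasons[i] is None:
            reasons[i] = "duplicate (country, ref_year, age_group, series_id) key"
    keep = np.array([r is None for r in reasons])
    rejections = pd.DataFrame(
        {
            "row": np.flatnonzero(~keep),
            "reason": [reasons[i] for i in np.flatnonzero(~keep)],
        }
    )
    for _, row in rejections.iterrows():
        logger.warning("rejected observation row %d: %s", row["row"], row["reason"])
    table = ObservationTable(
        raw.loc[keep].reset_index(drop=True),
        provenance={
            "path": str(path),
            "loaded_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "schema_version": schema_version,
            "n_rejected": int((~keep).sum()),
            "rejections": rejections,
        },
    )
    return table


def write_observations(table: ObservationTable, path) -> None:
    """Write an observation table back to the CSV schema."""
    table.records.to_csv(path, index=False)


def compute_sampling_variance(deaths_male, deaths_female):
    """Sampling variance of the log sex ratio from backing death counts.

    Treats the sex-specific death counts as independent Poisson counts; the
    delta method then gives Var(log rate ratio) = 1/D_male + 1/D_female.
    Both counts must be strictly positive. Accepts scalars or arrays.
    """
    dm = np.asarray(deaths_male, dtype=float)
    df = np.asarray(deaths_female, dtype=float)
    if np.any(dm <= 0) or np.any(df <= 0):
        raise ValueError(
            "death counts must be > 0; supply log_se_sampling directly for "
            "observations without usable counts"
        )
    out = 1.0 / dm + 1.0 / df
    return out if out.ndim else float(out)


def aggregate_fine_to_reporting(
    q_male_by_fine: Mapping[str, float],
    q_female_by_fine: Mapping[str, float],
    reporting_group: str,
) -> tuple[float, float, float]:
    """Combine fine-age probabilities of dying into a reporting age group.

    Uses the life-table convention: the probability of dying across adjacent
    age intervals is ``1 - prod(1 - q_fine)`` per sex, and the sex ratio is
    the ratio of the aggregated probabilities. Passing the reporting group
    itself as the single fine group is an identity.
    """
    if reporting_group not in REPORTING_AGE_GROUPS:
        raise ValueError(f"unknown reporting group {reporting_group!r}")
    if set(q_male_by_fine) == {reporting_group} and set(q_female_by_fine) == {reporting_group}:
        groups: tuple[str, ...] = (reporting_group,)
    else:
        groups = FINE_CONSTITUENTS[reporting_group]
        for g in groups:
            if g not in q_male_by_fine or g not in q_female_by_fine:
                raise ValueError(
                    f"missing fine group {g!r} for reporting group {reporting_group!r}"
                )
    qm_parts = np.array([q_male_by_fine[g] for g in groups], dtype=float)
    qf_parts = np.array([q_female_by_fine[g] for g in groups], dtype=float)
    for name, parts in (("male", qm_parts), ("female", qf_parts)):
        if np.any((parts <= 0) | (parts >= 1)):
            raise ValueError(f"{name} fine-group probabilities must lie in (0, 1)")
    q_male = 1.0 - np.prod(1.0 - qm_parts)
    q_female = 1.0 - np.prod(1.0 - qf_parts)
    return float(q_male), float(q_female), float(q_male / q_female)


def filter_extremes(
    table: ObservationTable, lower: float = 0.2, upper: float = 5.0
) -> tuple[ObservationTable, dict[str, float]]:
    """Drop observations with sex ratios outside ``[lower, upper]``.

    The bounds are symmetric on the log scale by default and remove
    physically implausible ratios. Returns the filtered table (input order
    preserved) and the removed fraction per age group present in the input.
    """
    if not (0 < lower < upper):
        raise ValueError(f"require 0 < lower < upper, got ({lower}, {upper})")
    df = table.records
    ratio = df["sex_ratio_obs"].to_numpy(float)
    keep = (ratio >= lower) & (ratio <= upper)
    removed_fraction: dict[str, float] = {}
    for age in table.age_groups:
        in_age = (df["age_group"] == age).to_numpy()
        removed_fraction[age] = float((in_age & ~keep).sum() / in_age.sum())
    out = ObservationTable(df.loc[keep].reset_index(drop=True), dict(table.provenance))
    out.provenance["extreme_bounds"] = (lower, upper)
    out.provenance["extreme_removed_fraction"] = removed_fraction
    return out, removed_fraction
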