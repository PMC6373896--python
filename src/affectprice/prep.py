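"""Cohort eligibility filtering and exposure construction.

Takes raw participant-by-wave records (income band, drinking frequency,
per-beverage quantities, affect-scale item responses, demographics, and
exclusion flags), applies the analytic-sample rules, and produces a panel
with the two exposures used by the affect equations: alcohol intake in
grams of ethanol per day and the natural log of household income.

Filters are applied at the participant level in a fixed, documented order —
item refusals, neurological condition, non-drinkers, alcohol-dependence
history, then case-wise deletion on any missing covariate (and, in
longitudinal mode, incomplete panels). The per-rule counts in the exclusion
log depend on this order; the final eligible set does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REFUSED",
    "BeverageTable",
    "ExclusionLog",
    "PanelDataset",
    "DEFAULT_BAND_VALUES",
    "BEVERAGE_COLUMNS",
    "PHQ4_COLUMNS",
    "NEUROTICISM_COLUMNS",
    "COVARIATE_COLUMNS",
    "WEEKLY_FREQUENCIES",
    "MONTHLY_FREQUENCIES",
    "apply_eligibility_filters",
    "compute_grams_per_day",
    "encode_income",
    "build_balanced_panel",
]

#: Sentinel for "I don't know" / "I do not wish to answer" item responses
#: and for a refused income band.
REFUSED = -1

PHQ4_COLUMNS = tuple(f"phq4_{k}" for k in range(1, 5))
NEUROTICISM_COLUMNS = tuple(f"neur_{k}" for k in range(1, 13))
ITEM_COLUMNS = PHQ4_COLUMNS + NEUROTICISM_COLUMNS

COVARIATE_COLUMNS = (
    "sex_male",
    "age",
    "townsend",
    "college_degree",
    "employed",
    "smoker",
    "fruit_veg_5plus",
    "white_ethnicity",
    "bmi_class",
    "longterm_illness",
    "n_children",
)

WEEKLY_FREQUENCIES = frozenset({"daily", "3-4_per_week", "1-2_per_week"})
# "special occasions only" drinkers report monthly quantities here
MONTHLY_FREQUENCIES = frozenset({"1-3_per_month", "special_occasions"})

#: Pound value assigned to each of the five census income bands
#: (<18k, 18-31k, 31-52k, 52-100k, >100k). Interior bands use arithmetic
#: midpoints; the open-ended bands use conventional anchors. All values are
#: configuration, not assertions about any census source.
DEFAULT_BAND_VALUES: dict[int, float] = {
    1: 9_000.0,
    2: 24_500.0,
    3: 41_500.0,
    4: 76_000.0,
    5: 125_000.0,
}


@dataclass(frozen=True)
class BeverageTable:
    """Grams of ethanol per reported serving of each beverage category.

    Defaults are anchored to a pint of beer at 20.45 g of ethanol and a
    125 ml wine glass at 12.5 g (75 g per 750 ml bottle); the remaining
    entries are explicit configuration.
    """

    beer_pints: float = 20.45
    white_wine_glasses: float = 12.5
    red_wine_glasses: float = 12.5
    fortified_wine_glasses: float = 8.0
    spirits_measures: float = 11.0
    other_glasses: float = 12.0

    def __post_init__(self):
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"grams per serving must be positive ({f.name})")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


BEVERAGE_COLUMNS = tuple(f.name for f in dc_fields(BeverageTable))

_RULES = ("refusals", "neurological", "non_drinker", "dependence", "casewise", "incomplete_panel")


@dataclass
class ExclusionLog:
    """Ordered per-rule counts of participants removed from the raw cohort."""

    mode: str
    raw_n: int
    eligible_n: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.counts.values())
        if self.eligible_n + total != self.raw_n:
            raise ValueError(
                f"exclusion log does not conserve participants: "
                f"{self.eligible_n} + {total} != {self.raw_n}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {"mode": self.mode, "raw_n": self.raw_n, "eligible_n": self.eligible_n,
             "excluded": self.counts},
            indent=2,
        )


@dataclass
class PanelDataset:
    """Participant-by-wave table ready for model fitting."""

    data: pd.DataFrame
    n_waves: int
    balanced: bool

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.data.groupby("participant_id").size()


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------


def apply_eligibility_filters(
    records: pd.DataFrame, mode: str
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the analytic-sample rules; returns eligible records + log.

    ``cross_sectional`` evaluates rules on the baseline wave only and
    returns baseline rows; ``longitudinal`` evaluates item refusals and
    missing covariates at every wave and keeps only participants present at
    all waves.
    """
    if mode not in ("cross_sectional", "longitudinal"):
        raise ValueError(f"unknown mode {mode!r}")
    required = (
        list(ITEM_COLUMNS)
        + list(COVARIATE_COLUMNS)
        + ["participant_id", "wave", "income_band", "drink_frequency",
           "neurological_condition", "alcohol_dependence"]
    )
    missing_cols = [c for c in required if c not in records.columns]
    if missing_cols:
        raise KeyError(f"records are missing required columns: {missing_cols}")

    if mode == "cross_sectional":
        df = records.loc[records["wave"] == records["wave"].min()].copy()
    else:
        df = records.copy()

    n_waves = df["wave"].nunique()

    # per-rule participant-level flags
    item_refusal = (df[list(ITEM_COLUMNS)] == REFUSED).any(axis=1)
    refusal_pid = item_refusal.groupby(df["participant_id"]).any()
    neuro_pid = (df["neurological_condition"] == 1).groupby(df["participant_id"]).any()
    nondrink_pid = (df["drink_frequency"] == "never").groupby(df["participant_id"]).any()
    dep_pid = (df["alcohol_dependence"] == 1).groupby(df["participant_id"]).any()
    casewise_row = (
        df[list(COVARIATE_COLUMNS)].isna().any(axis=1)
        | (df["income_band"] == REFUSED)
        | (df["drink_frequency"] == "refused")
    )
    casewise_pid = casewise_row.groupby(df["participant_id"]).any()
    present_all = df.groupby("participant_id")["wave"].nunique() == n_waves

    alive = pd.Series(True, index=refusal_pid.index)
    counts: dict[str, int] = {}

    def drop(rule: str, flag: pd.Series):
        nonlocal alive
        hit = alive & flag
        counts[rule] = int(hit.sum())
        alive = alive & ~flag

    drop("refusals", refusal_pid)
    drop("neurological", neuro_pid)
    drop("non_drinker", nondrink_pid)
    drop("dependence", dep_pid)
    drop("casewise", casewise_pid)
    if mode == "longitudinal":
        drop("incomplete_panel", ~present_all)

    keep_ids = alive.index[alive]
    out = df.loc[df["participant_id"].isin(keep_ids)].copy()
    log = ExclusionLog(
        mode=mode,
        raw_n=int(refusal_pid.size),
        eligible_n=int(alive.sum()),
        counts=counts,
    )
    return out, log


# ---------------------------------------------------------------------------
# Exposures
# ---------------------------------------------------------------------------


def compute_grams_per_day(
    records: pd.DataFrame, table: BeverageTable | None = None
) -> pd.Series:
    """Grams of ethanol per day from beverage counts and reporting period.

    Weekly reporters' totals are divided by 7, monthly reporters' by 30.44
    (the mean month length in days). Non-drinkers must be filtered before
    this step — a "never" frequency here indicates a filter violation.
    """
    table = table or BeverageTable()
    freq = records["drink_frequency"]
    if (freq == "never").any():
        raise ValueError("'never' frequency reached grams/day computation; filter non-drinkers first")
    unknown = set(freq.unique()) - WEEKLY_FREQUENCIES - MONTHLY_FREQUENCIES
    if unknown:
        raise ValueError(f"unknown drinking frequency categories: {sorted(unknown)}")
    counts = records[list(BEVERAGE_COLUMNS)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative beverage count")
    grams = counts.to_numpy(dtype=float) @ np.array(
        [getattr(table, c) for c in BEVERAGE_COLUMNS]
    )
    divisor = np.where(freq.isin(list(WEEKLY_FREQUENCIES)), 7.0, 30.44)
    return pd.Series(grams / divisor, index=records.index, name="alcohol_gday")


def encode_income(
    income_band: pd.Series, band_value_map: Mapping[int, float] | None = None
) -> pd.Series:
    """Natural log of the pound value assigned to each income band."""
    values = dict(DEFAULT_BAND_VALUES if band_value_map is None else band_value_map)
    band = pd.Series(income_band)
    if (band == REFUSED).any():
        raise ValueError("refused income band reached encoding; filter upstream")
    unknown = set(band.unique()) - set(values)
    if unknown:
        raise ValueError(f"unknown income bands: {sorted(unknown)}")
    return pd.Series(
        np.log(band.map(values).to_numpy(dtype=float)), index=band.index, name="ln_income"
    )


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------


def build_balanced_panel(records: pd.DataFrame, n_waves: int | None = None) -> PanelDataset:
    """Keep only participants observed at every wave.

    Raises on duplicate (participant, wave) pairs. The result is sorted by
    participant and wave so downstream output is reproducible.
    """
    if records.duplicated(["participant_id", "wave"]).any():
        dup = records.loc[
            records.duplicated(["participant_id", "wave"]), ["participant_id", "wave"]
        ]
        raise ValueError(f"duplicate (participant, wave) rows: {dup.values[:5].tolist()}")
    n_waves = int(n_waves if n_waves is not None else records["wave"].nunique())
    per = records.groupby("participant_id")["wave"].nunique()
    keep = per.index[per == n_waves]
    data = (
        records.loc[records["participant_id"].isin(keep)]
        .sort_values(["participant_id", "wave"], kind="mergesort")
        .reset_index(drop=True)
    )
    return PanelDataset(data=data, n_waves=n_waves, balanced=True)
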