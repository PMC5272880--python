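"""Person-period panel construction at unequally spaced measurement years.

The analysis follows persons who were Jobless at baseline across a handful
of measurement years chosen to bracket swings of the national unemployment
rate (default 1995, 1997, 2001, 2005, 2008, 2010, indexed p0…p5).  Each
transition observation pairs the state at period *p* with the state at
*p − 1*; rows whose previous state is censored are excluded because
censoring is absorbing.  Covariates attached to a row:

* sex and country of birth, fixed;
* age group from age at the baseline year (20–25, 26–30, 31–35, 36–40 —
  the first group spans six years, matching the published reference
  categories);
* education measured at the *previous* period's calendar year (lagged);
* inpatient-care days in the two calendar years before the outcome year,
  categorised none / ≤ median / > median, the median taken per period over
  rows with any such care.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .position_classifier import State
from .transition_predict import TransitionTable

__all__ = [
    "PeriodMap",
    "DEFAULT_PERIOD_MAP",
    "select_baseline",
    "categorize_inpatient",
    "build_person_periods",
    "states_wide",
    "empirical_transition_table",
]

AGE_GROUPS = (("20-25", 20, 25), ("26-30", 26, 30), ("31-35", 31, 35), ("36-40", 36, 40))


@dataclass(frozen=True)
class PeriodMap:
    """Mapping from consecutive period indices p0, p1, … to calendar years."""

    years: tuple[int, ...] = (1995, 1997, 2001, 2005, 2008, 2010)

    def __post_init__(self) -> None:
        if len(self.years) < 2 or any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing, length >= 2")

    def year(self, p: int) -> int:
        return self.years[p]

    @property
    def n_periods(self) -> int:
        """Number of transition periods (p = 1 … n_periods)."""
        return len(self.years) - 1

    @property
    def baseline_year(self) -> int:
        return self.years[0]

    def period_label(self, p: int) -> str:
        return f"{self.years[p - 1]}-{self.years[p]}"


DEFAULT_PERIOD_MAP = PeriodMap()


def select_baseline(states: pd.DataFrame, baseline_year: int) -> np.ndarray:
    """Person ids whose state at ``baseline_year`` is Jobless.

    ``states`` has columns ``person_id, year, state``; every person must
    have a row at the baseline year.
    """
    at_base = states[states["year"] == baseline_year]
    missing = set(states["person_id"].unique()) - set(at_base["person_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} persons lack a state at baseline year {baseline_year}"
        )
    sel = at_base.loc[at_base["state"] == str(State.JOBLESS), "person_id"]
    return sel.to_numpy()


def categorize_inpatient(days_prev_2yrs, period_median: float):
    """0 → none; 0 < days ≤ median → le_median; days > median → gt_median."""
    days = np.asarray(days_prev_2yrs)
    if np.any(days < 0):
        raise ValueError("inpatient days must be non-negative")
    out = np.where(days == 0, "none", np.where(days <= period_median, "le_median", "gt_median"))
    return out if out.ndim else str(out)


def _age_group(age: np.ndarray) -> np.ndarray:
    out = np.full(age.shape, "", dtype=object)
    for label, lo, hi in AGE_GROUPS:
        out[(age >= lo) & (age <= hi)] = label
    return out


@dataclass
class PanelReport:
    """Accounting of rows dropped during panel construction."""

    n_rows: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    period_medians: dict[int, float] = field(default_factory=dict)

    def drop(self, reason: str, count: int) -> None:
        if count:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(count)


def states_wide(states: pd.DataFrame, period_map: PeriodMap) -> pd.DataFrame:
    """Person × period table of states at the mapped calendar years."""
    sub = states[states["year"].isin(period_map.years)]
    wide = sub.pivot(index="person_id", columns="year", values="state")
    missing_years = [y for y in period_map.years if y not in wide.columns]
    if missing_years:
        raise ValueError(f"no states recorded for mapped years {missing_years}")
    wide = wide[list(period_map.years)]
    wide.columns = range(len(period_map.years))
    return wide


def build_person_periods(
    states: pd.DataFrame,
    covariates: pd.DataFrame,
    inpatient: pd.DataFrame,
    period_map: PeriodMap = DEFAULT_PERIOD_MAP,
) -> tuple[pd.DataFrame, PanelReport]:
    """Build the estimation panel.

    Parameters
    ----------
    states
        ``person_id, year, state`` covering every mapped year per person.
    covariates
        Per person-year: ``person_id, year, sex, birth_year,
        country_of_birth, education`` (education may change over time; the
        value at the previous period's year is used).
    inpatient
        Per person-year countable inpatient days: ``person_id, year, days``.
        Years absent from the table count as zero days.

    Returns the panel (one row per person per period with a non-censored
    previous state) and a :class:`PanelReport` with drop counts and the
    per-period medians used for the inpatient category.
    """
    report = PanelReport()
    wide = states_wide(states, period_map)

    cov = covariates.set_index(["person_id", "year"]).sort_index()
    inp = (
        inpatient.set_index(["person_id", "year"])["days"].sort_index()
        if len(inpatient)
        else pd.Series(dtype=float)
    )

    fixed = covariates.sort_values("year").groupby("person_id").first()
    age = period_map.baseline_year - fixed["birth_year"].astype(int)
    fixed = fixed.assign(age_group=_age_group(age.to_numpy()))

    chunks = []
    for p in range(1, len(period_map.years)):
        t_prev, t = period_map.year(p - 1), period_map.year(p)
        sub = wide[[p - 1, p]].dropna()
        sub = sub[sub[p - 1] != str(State.CENSORED)]
        if not len(sub):
            continue
        ids = sub.index
        # lagged education at the previous period's calendar year
        edu_key = pd.MultiIndex.from_product([ids, [t_prev]])
        try:
            edu = cov.loc[edu_key, "education"].to_numpy()
        except KeyError:
            edu_series = cov["education"].reindex(edu_key)
            missing = edu_series.isna()
            report.drop(f"missing_education_at_{t_prev}", int(missing.sum()))
            sub = sub[~missing.to_numpy()]
            ids = sub.index
            edu = edu_series[~missing.to_numpy()].to_numpy()
        fx = fixed.reindex(ids)
        bad_fixed = fx[["sex", "country_of_birth"]].isna().any(axis=1) | (
            fx["age_group"] == ""
        )
        if bad_fixed.any():
            report.drop("missing_fixed_covariates", int(bad_fixed.sum()))
            keep = ~bad_fixed.to_numpy()
            sub, fx, edu = sub[keep], fx[keep], edu[keep]
            ids = sub.index
        days = np.zeros(len(ids))
        for yr in (t - 1, t - 2):
            got = inp.reindex(pd.MultiIndex.from_product([ids, [yr]])).fillna(0.0)
            days += got.to_numpy()
        chunks.append(
            pd.DataFrame(
                {
                    "person_id": ids,
                    "period": p,
                    "state": sub[p].to_numpy(),
                    "state_prev": sub[p - 1].to_numpy(),
                    "sex": fx["sex"].to_numpy(),
                    "age_group": fx["age_group"].to_numpy(),
                    "country": fx["country_of_birth"].to_numpy(),
                    "education_prev": edu,
                    "inpatient_days": days,
                }
            )
        )
    if not chunks:
        panel = pd.DataFrame(
            columns=[
                "person_id", "period", "state", "state_prev", "sex", "age_group",
                "country", "education_prev", "inpatient_days", "inpatient_cat",
            ]
        )
        return panel, report
    panel = pd.concat(chunks, ignore_index=True)

    # per-period median among rows with any care, then three-way category
    cats = np.empty(len(panel), dtype=object)
    for p, grp in panel.groupby("period"):
        pos = grp.loc[grp["inpatient_days"] > 0, "inpatient_days"]
        median = float(pos.median()) if len(pos) else 0.0
        report.period_medians[int(p)] = median
        cats[grp.index.to_numpy()] = categorize_inpatient(
            grp["inpatient_days"].to_numpy(), median
        )
    panel["inpatient_cat"] = cats
    report.n_rows = len(panel)
    return panel, report


def empirical_transition_table(
    wide: pd.DataFrame, from_period: int, to_period: int
) -> TransitionTable:
    """Empirical column-per cent transition table between two periods.

    ``wide`` is the person × period state table from :func:`states_wide`.
    Origins are the three live states at ``from_period``; destinations
    include censored.  Each origin column sums to 100 (before rounding).
    """
    if not 0 <= from_period < to_period < wide.shape[1]:
        raise ValueError("need 0 <= from_period < to_period within the mapped range")
    origins = ("self_sufficient", "jobless", "disabled")
    dests = ("self_sufficient", "jobless", "disabled", "censored")
    sub = wide[[from_period, to_period]].dropna()
    sub = sub[sub[from_period] != str(State.CENSORED)]
    counts = pd.crosstab(sub[to_period], sub[from_period])
    counts = counts.reindex(index=list(dests), columns=list(origins), fill_value=0)
    totals = counts.sum(axis=0)
    pct = counts.divide(totals.where(totals > 0, np.nan), axis=1) * 100.0
    pct.index.name = "destination"
    pct.columns.name = "origin"
    return TransitionTable(data=pct, kind="empirical")
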