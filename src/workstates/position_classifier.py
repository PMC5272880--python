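"""Two-step classification of annual register records into labour-market states.

Each person-year is first assigned one of nine fine-grained labour-market
positions (plus death and emigration markers) from its earnings, compensated
benefit days and income shares.  The positions are then collapsed into four
mutually exclusive analysis states:

* ``JOBLESS`` — long-term unemployed, on social assistance, or with minimal
  income from work or social security;
* ``SELF_SUFFICIENT`` — employed, on long-term parental leave, or a student;
* ``DISABLED`` — on disability pension or long-term (medically certified)
  sickness absence;
* ``CENSORED`` — died, emigrated, or old-age pensioner.  Censoring is
  absorbing: once a person is censored they never re-enter the cohort, even
  if later records exist (re-immigration does not re-enter).

The rule families are evaluated in a fixed precedence order:

1. death, then emigration (vital-status flags);
2. the benefit-day rule: if the annual *sum* of compensated days across the
   four programmes (unemployment, sickness, disability pension, parental
   leave) reaches the long-term cut (default 183 days ~ six months), the
   person is assigned to the programme with the most days (ties broken
   disability > sickness > unemployment > parental);
3. the income-share rule: more than half (configurable) of annual disposable
   income from social assistance, student allowance, or old-age pension;
4. the employment rule: earnings above the fixed threshold;
5. minimal income (residual).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LabourMarketPosition",
    "State",
    "ClassificationConfig",
    "classify_position",
    "classify_records",
    "collapse_to_state",
    "classify_cohort",
]


class LabourMarketPosition(enum.StrEnum):
    LONG_TERM_UNEMPLOYED = "long_term_unemployed"
    SOCIAL_ASSISTANCE = "social_assistance"
    MINIMAL_INCOME = "minimal_income"
    EMPLOYED = "employed"
    PARENTAL_LEAVE = "parental_leave"
    STUDENT = "student"
    DISABILITY_PENSION = "disability_pension"
    LONG_TERM_SICK = "long_term_sick"
    OLD_AGE_PENSION = "oldage_pension"
    DIED = "died"
    EMIGRATED = "emigrated"


class State(enum.StrEnum):
    JOBLESS = "jobless"
    SELF_SUFFICIENT = "self_sufficient"
    DISABLED = "disabled"
    CENSORED = "censored"


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the classification rules.

    ``earnings_threshold`` is in the same (abstract) currency units as the
    register earnings; ``long_term_days`` is the "six months" day cut of the
    benefit-day rule; ``income_share_cut`` is the fraction of disposable
    income above which a single social-security source dominates.
    """

    earnings_threshold: float = 1.0
    long_term_days: int = 183
    income_share_cut: float = 0.5

    def __post_init__(self) -> None:
        if not self.earnings_threshold > 0:
            raise ValueError("earnings_threshold must be > 0")
        if not 150 <= self.long_term_days <= 200:
            raise ValueError("long_term_days must lie in [150, 200]")
        if not 0.0 < self.income_share_cut < 1.0:
            raise ValueError("income_share_cut must lie in (0, 1)")


# benefit programme day-count fields, in tie-break precedence order
BENEFIT_FIELDS = (
    "disability_days",
    "sickness_days",
    "unemployment_days",
    "parental_days",
)
BENEFIT_POSITION = {
    "disability_days": LabourMarketPosition.DISABILITY_PENSION,
    "sickness_days": LabourMarketPosition.LONG_TERM_SICK,
    "unemployment_days": LabourMarketPosition.LONG_TERM_UNEMPLOYED,
    "parental_days": LabourMarketPosition.PARENTAL_LEAVE,
}

# income-share sources, in tie-break precedence order
SHARE_FIELDS = (
    "social_assistance_income",
    "student_allowance_income",
    "oldage_pension_income",
)
SHARE_POSITION = {
    "social_assistance_income": LabourMarketPosition.SOCIAL_ASSISTANCE,
    "student_allowance_income": LabourMarketPosition.STUDENT,
    "oldage_pension_income": LabourMarketPosition.OLD_AGE_PENSION,
}

_COLLAPSE = {
    LabourMarketPosition.LONG_TERM_UNEMPLOYED: State.JOBLESS,
    LabourMarketPosition.SOCIAL_ASSISTANCE: State.JOBLESS,
    LabourMarketPosition.MINIMAL_INCOME: State.JOBLESS,
    LabourMarketPosition.EMPLOYED: State.SELF_SUFFICIENT,
    LabourMarketPosition.PARENTAL_LEAVE: State.SELF_SUFFICIENT,
    LabourMarketPosition.STUDENT: State.SELF_SUFFICIENT,
    LabourMarketPosition.DISABILITY_PENSION: State.DISABLED,
    LabourMarketPosition.LONG_TERM_SICK: State.DISABLED,
    LabourMarketPosition.OLD_AGE_PENSION: State.CENSORED,
    LabourMarketPosition.DIED: State.CENSORED,
    LabourMarketPosition.EMIGRATED: State.CENSORED,
}


def collapse_to_state(position: LabourMarketPosition | str) -> State:
    """Collapse a fine-grained position into one of the four analysis states.

    Total function over the position enum.
    """
    return _COLLAPSE[LabourMarketPosition(position)]


def classify_position(
    record: Mapping[str, object], config: ClassificationConfig | None = None
) -> LabourMarketPosition:
    """Classify one person-year record into a labour-market position.

    ``record`` is any mapping with the register field names (a dict, a
    ``pandas`` row, ...).  Raises ``ValueError`` when the income-share rule
    must be evaluated but disposable income is missing or non-positive.
    """
    cfg = config or ClassificationConfig()
    if record["died_this_year"]:
        return LabourMarketPosition.DIED
    if record["emigrated_this_year"]:
        return LabourMarketPosition.EMIGRATED

    days = {f: int(record[f]) for f in BENEFIT_FIELDS}
    if sum(days.values()) >= cfg.long_term_days:
        best = max(BENEFIT_FIELDS, key=lambda f: days[f])  # first max wins ties
        return BENEFIT_POSITION[best]

    incomes = {f: float(record[f]) for f in SHARE_FIELDS}
    if any(v > 0 for v in incomes.values()):
        disposable = record.get("disposable_income")
        if disposable is None or not np.isfinite(float(disposable)) or float(disposable) <= 0:
            raise ValueError(
                "disposable_income missing or non-positive while a social-security "
                "income share must be evaluated"
            )
        disposable = float(disposable)
        best = max(SHARE_FIELDS, key=lambda f: incomes[f])
        if incomes[best] > cfg.income_share_cut * disposable:
            return SHARE_POSITION[best]

    if float(record["earnings"]) > cfg.earnings_threshold:
        return LabourMarketPosition.EMPLOYED
    return LabourMarketPosition.MINIMAL_INCOME


def classify_records(
    records: pd.DataFrame, config: ClassificationConfig | None = None
) -> pd.DataFrame:
    """Vectorised classification of a record table.

    Returns a frame with columns ``position``, ``state`` and
    ``triggered_rule`` aligned with ``records``.  Semantics identical to
    :func:`classify_position` applied row-wise.
    """
    cfg = config or ClassificationConfig()
    n = len(records)
    days = records[list(BENEFIT_FIELDS)].to_numpy(dtype=np.int64)
    total_days = days.sum(axis=1)
    best_benefit = np.argmax(days, axis=1)  # argmax → first max = precedence order

    incomes = records[list(SHARE_FIELDS)].to_numpy(dtype=float)
    disposable = records["disposable_income"].to_numpy(dtype=float)
    best_share = np.argmax(incomes, axis=1)
    best_share_income = incomes[np.arange(n), best_share]

    died = records["died_this_year"].to_numpy(dtype=bool)
    emig = records["emigrated_this_year"].to_numpy(dtype=bool)
    benefit_hit = total_days >= cfg.long_term_days

    share_relevant = (incomes > 0).any(axis=1) & ~died & ~emig & ~benefit_hit
    bad_disposable = share_relevant & (~np.isfinite(disposable) | (disposable <= 0))
    if bad_disposable.any():
        idx = records.index[bad_disposable][:5].tolist()
        raise ValueError(
            "disposable_income missing or non-positive while a social-security "
            f"income share must be evaluated (rows {idx}...)"
        )
    with np.errstate(invalid="ignore"):
        share_hit = share_relevant & (
            best_share_income > cfg.income_share_cut * disposable
        )
    employed = records["earnings"].to_numpy(dtype=float) > cfg.earnings_threshold

    benefit_pos = np.array(
        [str(BENEFIT_POSITION[f]) for f in BENEFIT_FIELDS], dtype=object
    )[best_benefit]
    share_pos = np.array(
        [str(SHARE_POSITION[f]) for f in SHARE_FIELDS], dtype=object
    )[best_share]

    conditions = [died, emig, benefit_hit, share_hit, employed]
    positions = np.select(
        conditions,
        [
            str(LabourMarketPosition.DIED),
            str(LabourMarketPosition.EMIGRATED),
            benefit_pos,
            share_pos,
            str(LabourMarketPosition.EMPLOYED),
        ],
        default=str(LabourMarketPosition.MINIMAL_INCOME),
    )
    rules = np.select(
        conditions,
        ["death", "emigration", "benefit_days", "income_share", "employed"],
        default="minimal_income",
    )
    states = np.array([str(_COLLAPSE[LabourMarketPosition(p)]) for p in positions])
    return pd.DataFrame(
        {"position": positions, "state": states, "triggered_rule": rules},
        index=records.index,
    )


def classify_cohort(
    records: pd.DataFrame,
    config: ClassificationConfig | None = None,
    years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Classify a whole cohort and enforce absorbing censoring.

    ``records`` holds one row per person-year (columns as in the synthetic
    registry).  Within each person, years must be contiguous from the first
    observed year.  The result has one row per person per year from that
    person's first observed year to ``years[1]`` (default: the cohort-wide
    maximum year), with columns ``person_id, year, position, state,
    triggered_rule``.  Once a person's state is ``censored`` in some year,
    every later year is ``censored`` regardless of any later records; years
    with no record after a censoring event are emitted with an empty
    position and rule ``"absorbing"``.
    """
    if records.duplicated(subset=["person_id", "year"]).any():
        dup = records[records.duplicated(subset=["person_id", "year"], keep=False)]
        raise ValueError(
            f"duplicate (person_id, year) rows: {dup[['person_id', 'year']].head().values.tolist()}"
        )
    records = records.sort_values(["person_id", "year"], kind="stable")
    cls = classify_records(records, config)
    out = pd.DataFrame(
        {
            "person_id": records["person_id"].to_numpy(),
            "year": records["year"].to_numpy(),
            "position": cls["position"].to_numpy(),
            "state": cls["state"].to_numpy(),
            "triggered_rule": cls["triggered_rule"].to_numpy(),
        }
    )
    # contiguity check within person
    gap = (out["person_id"] == out["person_id"].shift()) & (
        out["year"] != out["year"].shift() + 1
    )
    if gap.any():
        bad = out.loc[gap, ["person_id", "year"]].head().values.tolist()
        raise ValueError(f"non-contiguous years within person (first offenders {bad})")

    end_year = years[1] if years is not None else int(out["year"].max())

    censored = str(State.CENSORED)
    is_cens = (out["state"] == censored).to_numpy()
    pid = out["person_id"].to_numpy()
    # absorbing fill over existing rows: censored once => censored onward
    carried = (
        pd.Series(is_cens).groupby(pd.Series(pid), sort=False).cummax().to_numpy()
    )
    out.loc[carried & (out["state"] != censored), "triggered_rule"] = "absorbing"
    out.loc[carried, "state"] = censored

    # extend persons whose records stop before end_year (death/emigration)
    last = out.groupby("person_id", sort=False).agg(
        last_year=("year", "max"), last_state=("state", "last")
    )
    to_extend = last[(last["last_year"] < end_year) & (last["last_state"] == censored)]
    if len(to_extend):
        fill = []
        for person, row in to_extend.iterrows():
            yrs = np.arange(row["last_year"] + 1, end_year + 1)
            fill.append(
                pd.DataFrame(
                    {
                        "person_id": person,
                        "year": yrs,
                        "position": "",
                        "state": censored,
                        "triggered_rule": "absorbing",
                    }
                )
            )
        out = pd.concat([out, *fill], ignore_index=True)
        out = out.sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)
    # persons whose records simply stop while uncensored would leave holes
    short = last[(last["last_year"] < end_year) & (last["last_state"] != censored)]
    if len(short):
        raise ValueError(
            f"records end before {end_year} without censoring for persons "
            f"{short.index[:5].tolist()}"
        )
    return out.reset_index(drop=True)
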