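"""Seeded synthetic register-style cohorts with known transition dynamics.

Real administrative registers of earnings, social-insurance benefit days and
inpatient care are not redistributable, so every downstream stage of the
pipeline is exercised on synthetic cohorts whose ground truth is known.  The
generator

1. samples baseline covariates (sex, age group 20–40, country of birth,
   education) from configurable marginals, treating the factors as
   independent;
2. simulates each person's four-state trajectory over the measurement years
   from a covariate-dependent multinomial-logit Markov kernel (the same
   probability machinery used for prediction), with education allowed to
   upgrade over time and inpatient-care history feeding back into the
   kernel;
3. realises a Censored draw as a death, emigration or old-age-pension event
   (type split from the configured rates) in a year of the preceding gap —
   after death or emigration no further records exist;
4. renders each person-year's intended state into raw register variables
   (benefit days, earnings, income shares) through one of the nine
   fine-grained positions, sampled with weights proportional to their
   population frequencies, such that the position classifier recovers the
   intended state.

Identical configuration + seed yields byte-identical output.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .multistate_model import (
    OUTCOME_ORDER,
    CoefficientSet,
    design_columns_from_levels,
    outcome_probabilities,
)
from .position_classifier import (
    ClassificationConfig,
    LabourMarketPosition,
    State,
    classify_cohort,
)

__all__ = [
    "CovariateMarginals",
    "InpatientModel",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_trajectories",
    "trajectories_to_panel",
    "sample_covariate_table",
    "round_trip_report",
    "write_cohort",
]

STATE_CODES = OUTCOME_ORDER  # 0 jobless, 1 self_sufficient, 2 disabled, 3 censored
_CENSORED = 3

EDUCATION_LEVELS = ("lower", "high_school", "higher")

RECORD_COLUMNS = (
    "person_id", "year", "earnings",
    "unemployment_days", "sickness_days", "disability_days", "parental_days",
    "social_assistance_income", "student_allowance_income",
    "oldage_pension_income", "disposable_income",
    "inpatient_days_countable", "inpatient_days_excluded",
    "sex", "birth_year", "country_of_birth", "education",
    "died_this_year", "emigrated_this_year",
)

_AGE_BOUNDS = {"20-25": (20, 25), "26-30": (26, 30), "31-35": (31, 35), "36-40": (36, 40)}

# fine-position sampling weights within each state, proportional to the
# population frequencies of the positions in the emulated 1995 register
DEFAULT_POSITION_WEIGHTS: dict[str, dict[str, float]] = {
    "jobless": {
        str(LabourMarketPosition.LONG_TERM_UNEMPLOYED): 392_035,
        str(LabourMarketPosition.SOCIAL_ASSISTANCE): 42_041,
        str(LabourMarketPosition.MINIMAL_INCOME): 204_546,
    },
    "self_sufficient": {
        str(LabourMarketPosition.EMPLOYED): 1_529_669,
        str(LabourMarketPosition.PARENTAL_LEAVE): 116_983,
        str(LabourMarketPosition.STUDENT): 147_751,
    },
    "disabled": {
        str(LabourMarketPosition.DISABILITY_PENSION): 44_429,
        str(LabourMarketPosition.LONG_TERM_SICK): 35_982,
    },
}


def _check_probs(name: str, probs: dict) -> None:
    vals = np.array(list(probs.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"{name}: proportions must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name}: proportions must sum to 1 (got {vals.sum()})")


@dataclass
class CovariateMarginals:
    """Marginal distributions of the baseline covariates (independent factors)."""

    sex: dict[str, float] = field(
        default_factory=lambda: {"male": 0.526, "female": 0.474}
    )
    age_group: dict[str, float] = field(
        default_factory=lambda: {"20-25": 0.30, "26-30": 0.25, "31-35": 0.23, "36-40": 0.22}
    )
    country: dict[str, float] = field(
        default_factory=lambda: {"sweden": 0.747, "other": 0.253}
    )
    education: dict[str, float] = field(
        default_factory=lambda: {"lower": 0.249, "high_school": 0.589, "higher": 0.162}
    )
    #: yearly probability of moving one education level up (makes the lagged
    #: education covariate genuinely time-varying; ~16 % → ~31 % with higher
    #: education over 15 years at the default)
    education_upgrade_prob: float = 0.017

    def validate(self) -> None:
        for name in ("sex", "age_group", "country", "education"):
            _check_probs(name, getattr(self, name))
        if not 0.0 <= self.education_upgrade_prob <= 1.0:
            raise ValueError("education_upgrade_prob must lie in [0, 1]")


@dataclass
class InpatientModel:
    """Zero-inflated geometric model for annual countable inpatient days.

    ``p_any`` is the probability of any care given the current state;
    positive day counts are geometric with success probability ``day_p``
    (mean 1/day_p days).  ``kernel_threshold`` is the day cut the *generator*
    uses to categorise the two-year care window fed into the transition
    kernel; it defaults to the theoretical median of the positive-count
    distribution (the empirical per-period median recomputed downstream by
    the panel builder lands on the same value in large samples).
    """

    p_any: dict[str, float] = field(
        default_factory=lambda: {
            "jobless": 0.136, "self_sufficient": 0.10, "disabled": 0.40, "censored": 0.15,
        }
    )
    day_p: float = 0.2
    excluded_p_any: float = 0.03
    kernel_threshold: int | None = None

    def threshold(self) -> int:
        if self.kernel_threshold is not None:
            return int(self.kernel_threshold)
        return max(1, math.ceil(math.log(0.5) / math.log(1.0 - self.day_p)))

    def validate(self) -> None:
        if not 0.0 < self.day_p <= 1.0:
            raise ValueError("day_p must lie in (0, 1]")
        for s, p in self.p_any.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_any[{s!r}] must lie in [0, 1]")
        if not 0.0 <= self.excluded_p_any <= 1.0:
            raise ValueError("excluded_p_any must lie in [0, 1]")


def _default_coefficients() -> CoefficientSet:
    from .transition_predict import REFERENCE_MODEL3_ORS

    terms = tuple(REFERENCE_MODEL3_ORS["self_sufficient"])
    beta = np.array(
        [
            [math.log(REFERENCE_MODEL3_ORS[o][t]) for t in terms]
            for o in ("self_sufficient", "disabled", "censored")
        ]
    )
    return CoefficientSet(terms=terms, beta=beta)


@dataclass
class GeneratorConfig:
    """Everything the cohort generator needs; see the module docstring."""

    n_persons: int
    baseline_year: int = 1995
    follow_up_years: tuple[int, ...] = (1997, 2001, 2005, 2008, 2010)
    seed: int = 0
    covariate_marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    true_coefficients: CoefficientSet | None = None
    censoring_rates: dict[str, float] = field(
        default_factory=lambda: {"death": 0.002, "emigration": 0.005}
    )
    oldage_censor_share: float = 0.01
    earnings_threshold: float = 1.0
    inpatient_model: InpatientModel = field(default_factory=InpatientModel)
    initial_state_probs: dict[str, float] = field(
        default_factory=lambda: {"jobless": 0.26, "self_sufficient": 0.71, "disabled": 0.03}
    )
    position_weights: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.true_coefficients is None:
            self.true_coefficients = _default_coefficients()

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        if self.earnings_threshold <= 0:
            raise ValueError(
                "earnings_threshold must be > 0 for rendering to be "
                "classification-consistent"
            )
        years = self.follow_up_years
        if len(years) == 0 or any(np.diff(years) <= 0):
            raise ValueError("follow_up_years must be non-empty and strictly increasing")
        if self.baseline_year >= years[0]:
            raise ValueError("baseline_year must precede all follow_up_years")
        self.covariate_marginals.validate()
        self.inpatient_model.validate()
        _check_probs("initial_state_probs", self.initial_state_probs)
        for k, v in self.censoring_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"censoring rate {k!r} must lie in [0, 1]")
        if not 0.0 <= self.oldage_censor_share <= 1.0:
            raise ValueError("oldage_censor_share must lie in [0, 1]")

    def weights(self) -> dict[str, dict[str, float]]:
        return self.position_weights or DEFAULT_POSITION_WEIGHTS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_coefficients"] = self.true_coefficients.to_dict()
        d["follow_up_years"] = list(self.follow_up_years)
        return d


@dataclass
class SyntheticCohort:
    """Generated register records plus the ground truth behind them."""

    records: pd.DataFrame
    truth: pd.DataFrame  # person_id, year, state, position (intended)
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# trajectory simulation (shared kernel machinery)
# ---------------------------------------------------------------------------

def _needed_factors(terms) -> set[str]:
    return {t.partition(":")[0] for t in terms if t != "intercept"}


def _kernel_step(
    coeffs: CoefficientSet,
    prev_codes: np.ndarray,
    period: int,
    covariates: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw next-state codes for every person given the previous state."""
    n = len(prev_codes)
    levels: dict[str, object] = {"prev": np.take(np.array(STATE_CODES), prev_codes)}
    for factor in _needed_factors(coeffs.terms) - {"prev", "period"}:
        if factor not in covariates:
            raise ValueError(f"kernel needs covariate factor {factor!r}")
        levels[factor] = covariates[factor]
    levels["period"] = np.full(n, period)
    X = design_columns_from_levels(coeffs.terms, levels, n=n)
    P = outcome_probabilities(coeffs.beta, X)  # columns ordered J, S, D, C
    draws = rng.random(n)
    new = (draws[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
    new[prev_codes == _CENSORED] = _CENSORED  # absorbing
    return new.astype(np.int64)


def simulate_trajectories(
    coeffs: CoefficientSet,
    covariates: pd.DataFrame,
    periods: int,
    seed: int,
) -> np.ndarray:
    """Forward-simulate state sequences from the Markov kernel.

    Every person starts Jobless (the cohort-entry condition); Censored is
    absorbing.  ``covariates`` holds one row per person with whichever of
    the columns ``sex, age_group, country, education, inpatient_cat`` the
    kernel terms require (levels held fixed over periods).  Returns an
    ``(n, periods + 1)`` integer array of state codes (see
    :data:`STATE_CODES`).
    """
    if not np.all(np.isfinite(coeffs.beta)):
        raise ValueError("coefficients must be finite")
    rng = np.random.default_rng(seed)
    n = len(covariates)
    colmap = {"sex": "sex", "age": "age_group", "country": "country",
              "education": "education", "inpatient": "inpatient_cat"}
    covs = {
        f: covariates[col].to_numpy()
        for f, col in colmap.items()
        if col in covariates.columns
    }
    states = np.zeros((n, periods + 1), dtype=np.int64)  # start jobless
    for p in range(1, periods + 1):
        states[:, p] = _kernel_step(coeffs, states[:, p - 1], p, covs, rng)
    return states


def trajectories_to_panel(states: np.ndarray, covariates: pd.DataFrame) -> pd.DataFrame:
    """Person-period rows (previous state not censored) from raw sequences."""
    n, width = states.shape
    chunks = []
    codes = np.array(STATE_CODES)
    for p in range(1, width):
        keep = states[:, p - 1] != _CENSORED
        chunk = covariates.loc[keep].copy()
        chunk = chunk.rename(columns={"education": "education_prev"})
        chunk["person_id"] = np.nonzero(keep)[0]
        chunk["period"] = p
        chunk["state"] = codes[states[keep, p]]
        chunk["state_prev"] = codes[states[keep, p - 1]]
        chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)


def sample_covariate_table(
    n: int,
    seed: int | np.random.Generator,
    marginals: CovariateMarginals | None = None,
    inpatient_probs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Independent covariate draws for kernel simulations (one row/person)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = marginals or CovariateMarginals()
    inp = inpatient_probs or {"none": 0.864, "le_median": 0.074, "gt_median": 0.062}
    _check_probs("inpatient_probs", inp)

    def draw(d: dict) -> np.ndarray:
        keys = list(d)
        return rng.choice(np.array(keys, dtype=object), size=n, p=list(d.values()))

    return pd.DataFrame(
        {
            "sex": draw(m.sex),
            "age_group": draw(m.age_group),
            "country": draw(m.country),
            "education": draw(m.education),
            "inpatient_cat": draw(inp),
        }
    )


# ---------------------------------------------------------------------------
# full cohort generation
# ---------------------------------------------------------------------------

def _draw_inpatient(
    rng: np.random.Generator, state_codes: np.ndarray, model: InpatientModel
) -> np.ndarray:
    p_any = np.array([model.p_any[s] for s in STATE_CODES])[state_codes]
    any_care = rng.random(len(state_codes)) < p_any
    days = rng.geometric(model.day_p, size=len(state_codes))
    return np.where(any_care, np.minimum(days, 366), 0).astype(np.int64)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one synthetic register cohort; see the module docstring.

    The returned records hold one row per alive, non-emigrated person-year
    from the baseline year through the last follow-up year; ``truth`` holds
    the intended state and position for every one of those person-years.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    m = config.covariate_marginals
    coeffs = config.true_coefficients
    years = np.arange(config.baseline_year, config.follow_up_years[-1] + 1)
    ny = len(years)
    meas_years = [config.baseline_year, *config.follow_up_years]
    meas_index = {y: p for p, y in enumerate(meas_years)}

    if n == 0:
        empty = pd.DataFrame(columns=list(RECORD_COLUMNS))
        truth = pd.DataFrame(columns=["person_id", "year", "state", "position"])
        return SyntheticCohort(records=empty, truth=truth, config=config)

    def draw_factor(d: dict) -> np.ndarray:
        return rng.choice(np.array(list(d), dtype=object), size=n, p=list(d.values()))

    sex = draw_factor(m.sex)
    age_group = draw_factor(m.age_group)
    country = draw_factor(m.country)
    lo = np.array([_AGE_BOUNDS[g][0] for g in age_group])
    hi = np.array([_AGE_BOUNDS[g][1] for g in age_group])
    age = rng.integers(lo, hi + 1)
    birth_year = config.baseline_year - age

    edu0 = draw_factor(m.education)
    edu_code = np.array([EDUCATION_LEVELS.index(e) for e in edu0], dtype=np.int64)
    edu_by_year = np.empty((n, ny), dtype=np.int64)
    edu_by_year[:, 0] = edu_code
    for yi in range(1, ny):
        upgrade = (edu_by_year[:, yi - 1] < 2) & (
            rng.random(n) < m.education_upgrade_prob
        )
        edu_by_year[:, yi] = edu_by_year[:, yi - 1] + upgrade

    init = rng.choice(
        np.array([0, 1, 2]),
        size=n,
        p=[config.initial_state_probs.get(s, 0.0) for s in STATE_CODES[:3]],
    )

    state_by_year = np.empty((n, ny), dtype=np.int64)
    inp_by_year = np.zeros((n, ny), dtype=np.int64)
    censor_kind = np.full(n, "", dtype=object)
    censor_year = np.full(n, -1, dtype=np.int64)

    d_rate = config.censoring_rates.get("death", 0.0)
    e_rate = config.censoring_rates.get("emigration", 0.0)
    oa = config.oldage_censor_share
    if d_rate + e_rate > 0:
        kinds = np.array(["death", "emigration", "oldage"], dtype=object)
        kind_p = [
            (1 - oa) * d_rate / (d_rate + e_rate),
            (1 - oa) * e_rate / (d_rate + e_rate),
            oa,
        ]
    else:
        kinds = np.array(["oldage"], dtype=object)
        kind_p = [1.0]

    threshold = config.inpatient_model.threshold()
    cur = init.copy()
    prev_meas_yi = 0
    state_by_year[:, 0] = cur
    inp_by_year[:, 0] = _draw_inpatient(rng, cur, config.inpatient_model)
    for yi in range(1, ny):
        y = int(years[yi])
        if y in meas_index:
            p = meas_index[y]
            window = inp_by_year[:, yi - 1] + (inp_by_year[:, yi - 2] if yi >= 2 else 0)
            inp_cat = np.where(
                window == 0,
                "none",
                np.where(window <= threshold, "le_median", "gt_median"),
            ).astype(object)
            covs = {
                "sex": sex,
                "age": age_group,
                "country": country,
                "education": np.take(np.array(EDUCATION_LEVELS), edu_by_year[:, prev_meas_yi]),
                "inpatient": inp_cat,
            }
            new = _kernel_step(coeffs, cur, p, covs, rng)
            newly = (new == _CENSORED) & (cur != _CENSORED)
            if newly.any():
                k = int(newly.sum())
                censor_kind[newly] = rng.choice(kinds, size=k, p=kind_p)
                censor_year[newly] = rng.integers(
                    years[prev_meas_yi] + 1, y + 1, size=k
                )
            cur = new
            prev_meas_yi = yi
        state_by_year[:, yi] = cur
        inp_by_year[:, yi] = _draw_inpatient(rng, cur, config.inpatient_model)

    # censoring is effective from the realised event year onwards
    has_event = censor_year >= 0
    if has_event.any():
        year_grid = years[None, :]
        mask = has_event[:, None] & (year_grid >= censor_year[:, None])
        state_by_year[mask] = _CENSORED

    # record inclusion: death/emigration stop the record stream
    include = np.ones((n, ny), dtype=bool)
    hard_exit = has_event & np.isin(censor_kind, ["death", "emigration"])
    if hard_exit.any():
        include[hard_exit[:, None] & (years[None, :] > censor_year[:, None])] = False

    pidx, yidx = np.nonzero(include)
    nrows = len(pidx)
    row_year = years[yidx]
    row_state = state_by_year[pidx, yidx]

    # intended fine positions
    position = np.empty(nrows, dtype=object)
    weights = config.weights()
    for code, state in enumerate(STATE_CODES[:3]):
        msk = row_state == code
        w = weights[state]
        names = np.array(list(w), dtype=object)
        pvals = np.array(list(w.values()), dtype=float)
        pvals /= pvals.sum()
        position[msk] = rng.choice(names, size=int(msk.sum()), p=pvals)
    cens_rows = row_state == _CENSORED
    row_kind = censor_kind[pidx]
    row_event = censor_year[pidx]
    position[cens_rows & (row_kind == "oldage")] = str(LabourMarketPosition.OLD_AGE_PENSION)
    position[cens_rows & (row_kind == "death")] = str(LabourMarketPosition.DIED)
    position[cens_rows & (row_kind == "emigration")] = str(LabourMarketPosition.EMIGRATED)

    # --- render register variables ------------------------------------------
    thr = config.earnings_threshold
    u = rng.random  # shorthand
    earnings = np.zeros(nrows)
    bdays = rng.integers(0, 21, size=(nrows, 4))  # unemp, sick, disab, parental
    disposable = thr * (0.5 + 1.5 * u(nrows))
    sa_inc = disposable * 0.2 * u(nrows)
    st_inc = disposable * 0.2 * u(nrows)
    oa_inc = disposable * 0.2 * u(nrows)
    died_flag = np.zeros(nrows, dtype=bool)
    emig_flag = np.zeros(nrows, dtype=bool)

    def mask(pos: LabourMarketPosition) -> np.ndarray:
        return position == str(pos)

    mm = mask(LabourMarketPosition.EMPLOYED)
    earnings[mm] = thr * (1.2 + 4.8 * u(mm.sum()))
    disposable[mm] = earnings[mm] * (1.0 + 0.2 * u(mm.sum()))
    for arr in (sa_inc, st_inc, oa_inc):
        arr[mm] = disposable[mm] * 0.2 * u(mm.sum())

    long_days = lambda k: rng.integers(200, 331, size=k)
    for pos, col in (
        (LabourMarketPosition.LONG_TERM_UNEMPLOYED, 0),
        (LabourMarketPosition.LONG_TERM_SICK, 1),
        (LabourMarketPosition.DISABILITY_PENSION, 2),
        (LabourMarketPosition.PARENTAL_LEAVE, 3),
    ):
        mm = mask(pos)
        bdays[mm, col] = long_days(int(mm.sum()))
        earnings[mm] = thr * 0.5 * u(mm.sum())

    for pos, arr in (
        (LabourMarketPosition.SOCIAL_ASSISTANCE, sa_inc),
        (LabourMarketPosition.STUDENT, st_inc),
        (LabourMarketPosition.OLD_AGE_PENSION, oa_inc),
    ):
        mm = mask(pos)
        arr[mm] = disposable[mm] * (0.55 + 0.35 * u(mm.sum()))
        earnings[mm] = thr * 0.4 * u(mm.sum())

    mm = mask(LabourMarketPosition.MINIMAL_INCOME)
    earnings[mm] = thr * 0.8 * u(mm.sum())

    died_flag[mask(LabourMarketPosition.DIED) & (row_year == row_event)] = True
    emig_flag[mask(LabourMarketPosition.EMIGRATED) & (row_year == row_event)] = True
    # death/emigration rows before the event year keep the held state; their
    # position labels were only set at the event year, so fill the earlier
    # censored-but-not-yet-exited rows (they do not exist: include[] drops
    # only years *after* the event, and state flips at the event year).
    pre_event = cens_rows & np.isin(row_kind, ["death", "emigration"]) & (
        row_year < row_event
    )
    assert not pre_event.any()

    excl_any = u(nrows) < config.inpatient_model.excluded_p_any
    excl_days = np.where(excl_any, rng.geometric(0.3, size=nrows), 0)

    person_ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    records = pd.DataFrame(
        {
            "person_id": person_ids[pidx],
            "year": row_year,
            "earnings": earnings,
            "unemployment_days": bdays[:, 0],
            "sickness_days": bdays[:, 1],
            "disability_days": bdays[:, 2],
            "parental_days": bdays[:, 3],
            "social_assistance_income": sa_inc,
            "student_allowance_income": st_inc,
            "oldage_pension_income": oa_inc,
            "disposable_income": disposable,
            "inpatient_days_countable": inp_by_year[pidx, yidx],
            "inpatient_days_excluded": excl_days,
            "sex": sex[pidx],
            "birth_year": birth_year[pidx],
            "country_of_birth": country[pidx],
            "education": np.take(np.array(EDUCATION_LEVELS), edu_by_year[pidx, yidx]),
            "died_this_year": died_flag,
            "emigrated_this_year": emig_flag,
        }
    )
    truth = pd.DataFrame(
        {
            "person_id": person_ids[pidx],
            "year": row_year,
            "state": np.take(np.array(STATE_CODES), row_state),
            "position": position,
        }
    )
    # truth for post-exit years (death/emigration): censored, no record
    if hard_exit.any():
        extra_p, extra_y = np.nonzero(
            hard_exit[:, None] & (years[None, :] > censor_year[:, None])
        )
        truth = pd.concat(
            [
                truth,
                pd.DataFrame(
                    {
                        "person_id": person_ids[extra_p],
                        "year": years[extra_y],
                        "state": str(State.CENSORED),
                        "position": "",
                    }
                ),
            ],
            ignore_index=True,
        )
        truth = truth.sort_values(["person_id", "year"], kind="stable").reset_index(
            drop=True
        )
    return SyntheticCohort(records=records, truth=truth, config=config)


def round_trip_report(
    cohort: SyntheticCohort, class_config: ClassificationConfig | None = None
) -> tuple[float, pd.DataFrame]:
    """Classify generated records and compare with the intended states.

    Returns the agreement rate over all person-years and a frame of the
    mismatching rows (person, year, intended vs recovered state, the rule
    that fired) — the logged remainder.
    """
    cfg = class_config or ClassificationConfig(
        earnings_threshold=cohort.config.earnings_threshold
    )
    got = classify_cohort(cohort.records, cfg)
    merged = cohort.truth.merge(
        got, on=["person_id", "year"], how="left", suffixes=("_intended", "_got")
    )
    bad = merged[merged["state_intended"] != merged["state_got"]].copy()
    if len(bad):
        bad["reason"] = (
            "intended " + bad["state_intended"].astype(str)
            + " recovered " + bad["state_got"].astype(str)
            + " via rule " + bad["triggered_rule"].astype(str)
        )
    rate = 1.0 - len(bad) / max(len(merged), 1)
    return rate, bad


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the tidy registry CSV plus a JSON sidecar echoing the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_path = out / "registry.csv"
    truth_path = out / "registry_truth.csv"
    sidecar_path = out / "registry_config.json"
    cohort.records.to_csv(records_path, index=False)
    cohort.truth.to_csv(truth_path, index=False)
    sidecar_path.write_text(json.dumps(cohort.config.to_dict(), indent=2, sort_keys=True))
    return {"records": records_path, "truth": truth_path, "config": sidecar_path}
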