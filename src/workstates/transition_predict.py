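"""Transition probabilities for covariate profiles and stratified tables.

Coefficients — either fitted by :mod:`workstates.multistate_model` or
injected from the published odds ratios of the Swedish register study this
pipeline is modelled on — are turned into four-way transition probabilities
through the multinomial inverse link: with linear predictors
η = (η_S, η_D, η_C) for the three non-reference outcomes,

    p = (e^{η_S}, 1, e^{η_D}, e^{η_C}) / (1 + e^{η_S} + e^{η_D} + e^{η_C}),

presented in the order (Self-sufficient, Jobless, Disabled, Censored).  The
probabilities sum to one by construction.

Stratified probability tables mirror the published layout: a fixed
socio-demographic profile (male, born in Sweden, age 26–30, high-school
education), with one column per period × inpatient-care stratum and, per
origin state, four destination rows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .multistate_model import (
    EQUATION_OUTCOMES,
    FACTOR_LEVELS,
    CoefficientSet,
    design_columns_from_levels,
)

__all__ = [
    "CovariateProfile",
    "TransitionTable",
    "REFERENCE_MODEL3_ORS",
    "DEST_ORDER",
    "PERIOD_LABELS",
    "linear_predictors",
    "softmax_probabilities",
    "coefficients_from_printed_ors",
    "probability_table",
    "round_half_up",
]

logger = logging.getLogger(__name__)

# presentation order of destination states in probability tables
DEST_ORDER = ("self_sufficient", "jobless", "disabled", "censored")
ORIGIN_ORDER = ("self_sufficient", "jobless", "disabled")

# interval labels of the default unequally spaced outcome periods
PERIOD_LABELS = {
    1: "1995-1997",
    2: "1997-2001",
    3: "2001-2005",
    4: "2005-2008",
    5: "2008-2010",
}


@dataclass(frozen=True)
class CovariateProfile:
    """One covariate combination for which probabilities are evaluated."""

    previous_state: str = "jobless"
    sex: str = "male"
    age_group: str = "26-30"
    country: str = "sweden"
    education: str = "high_school"
    inpatient_cat: str = "none"
    period: int = 2

    def __post_init__(self) -> None:
        if self.previous_state == "censored":
            raise ValueError("previous_state cannot be the absorbing censored state")
        checks = {
            "prev": self.previous_state,
            "sex": self.sex,
            "age": self.age_group,
            "country": self.country,
            "education": self.education,
            "inpatient": self.inpatient_cat,
        }
        for factor, value in checks.items():
            if value not in FACTOR_LEVELS[factor]:
                raise ValueError(f"invalid level {value!r} for factor {factor!r}")

    def levels(self) -> dict[str, object]:
        return {
            "prev": self.previous_state,
            "sex": self.sex,
            "age": self.age_group,
            "country": self.country,
            "education": self.education,
            "inpatient": self.inpatient_cat,
            "period": self.period,
        }


def linear_predictors(coeffs: CoefficientSet, profile: CovariateProfile) -> np.ndarray:
    """η = (η_S, η_D, η_C): sum of the profile's active coefficients."""
    x = design_columns_from_levels(coeffs.terms, profile.levels(), n=1)[0]
    return coeffs.beta @ x


def softmax_probabilities(eta: Sequence[float]) -> np.ndarray:
    """Four-way probabilities ordered (S, J, D, C), numerically stabilised."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 3-vector (S, D, C)")
    full = np.array([eta[0], 0.0, eta[1], eta[2]])  # S, J, D, C
    full -= full.max()
    p = np.exp(full)
    return p / p.sum()


# ---------------------------------------------------------------------------
# published odds ratios (full covariate model, Swedish jobless-in-1995 cohort)
# ---------------------------------------------------------------------------
# Point odds ratios, as published to two decimals, for the model with
# previous state + sex + age + education + country + inpatient care + period.
# Outcome reference: Jobless.  These are *inputs* used to reproduce the
# published stratified probability table; the 2-decimal rounding (notably the
# 0.02 Disabled intercept) propagates roughly ±1 percentage point into the
# probabilities derived from them.
REFERENCE_MODEL3_ORS: dict[str, dict[str, float]] = {
    "self_sufficient": {
        "intercept": 1.14,
        "prev:self_sufficient": 9.88,
        "prev:disabled": 1.53,
        "sex:female": 1.19,
        "age:26-30": 0.75,
        "age:31-35": 0.64,
        "age:36-40": 0.58,
        "education:lower": 0.57,
        "education:higher": 1.48,
        "country:other": 0.66,
        "inpatient:le_median": 0.86,
        "inpatient:gt_median": 0.65,
        "period:2": 1.44,
        "period:3": 0.82,
        "period:4": 1.29,
        "period:5": 0.86,
    },
    "disabled": {
        "intercept": 0.02,
        "prev:self_sufficient": 2.64,
        "prev:disabled": 49.37,
        "sex:female": 1.56,
        "age:26-30": 1.25,
        "age:31-35": 1.45,
        "age:36-40": 1.70,
        "education:lower": 1.04,
        "education:higher": 0.83,
        "country:other": 0.81,
        "inpatient:le_median": 1.64,
        "inpatient:gt_median": 3.13,
        "period:2": 5.73,
        "period:3": 5.93,
        "period:4": 5.18,
        "period:5": 2.62,
    },
    "censored": {
        "intercept": 0.04,
        "prev:self_sufficient": 1.22,
        "prev:disabled": 2.51,
        "sex:female": 0.98,
        "age:26-30": 0.87,
        "age:31-35": 0.77,
        "age:36-40": 0.72,
        "education:lower": 1.10,
        "education:higher": 2.06,
        "country:other": 1.95,
        "inpatient:le_median": 0.54,
        "inpatient:gt_median": 1.34,
        "period:2": 2.80,
        "period:3": 2.31,
        "period:4": 2.23,
        "period:5": 0.95,
    },
}


def coefficients_from_printed_ors(
    or_table: Mapping[str, Mapping[str, float]] | None = None,
) -> CoefficientSet:
    """Build a coefficient set from a table of point odds ratios.

    ``or_table`` maps outcome → {term: OR}; defaults to the published
    full-model estimates (:data:`REFERENCE_MODEL3_ORS`).  Coefficients are
    ln(OR); every outcome must supply an OR (intercepts included) for every
    term of the table.
    """
    table = REFERENCE_MODEL3_ORS if or_table is None else or_table
    missing = set(EQUATION_OUTCOMES) - set(table)
    if missing:
        raise ValueError(f"odds-ratio table lacks outcomes {sorted(missing)}")
    terms = tuple(table[EQUATION_OUTCOMES[0]])
    beta = np.empty((3, len(terms)))
    for i, outcome in enumerate(EQUATION_OUTCOMES):
        row = table[outcome]
        lacking = set(terms) - set(row)
        if lacking:
            raise ValueError(f"outcome {outcome!r} lacks ORs for {sorted(lacking)}")
        ors = np.array([float(row[t]) for t in terms])
        if np.any(ors <= 0):
            raise ValueError("odds ratios must be strictly positive")
        beta[i] = np.log(ors)
    logger.warning(
        "coefficients derived from odds ratios printed to 2 decimals; the "
        "rounding (e.g. a 0.02 intercept spanning 0.015-0.025) propagates "
        "roughly +/-1 percentage point into derived probabilities"
    )
    return CoefficientSet(terms=terms, beta=beta)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def round_half_up(values, decimals: int = 1):
    """Decimal-style half-up rounding (matches printed tables)."""
    factor = 10.0**decimals
    arr = np.floor(np.asarray(values, dtype=float) * factor + 0.5) / factor
    return arr


@dataclass
class TransitionTable:
    """A labelled grid of transition percentages.

    ``data`` holds unrounded column percentages.  For model-based tables the
    rows are a (origin, destination) MultiIndex ordered (S, J, D, C) within
    origin and the columns a (period, inpatient) MultiIndex; for empirical
    tables rows are destinations and columns origins.  Every origin column
    (or origin block within a stratum) sums to 100.
    """

    data: pd.DataFrame
    kind: str = "model"

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        out = self.data.copy()
        out.loc[:, :] = round_half_up(out.to_numpy(), decimals)
        return out

    def to_csv(self, path, decimals: int | None = 1) -> None:
        frame = self.data if decimals is None else self.rounded(decimals)
        frame.to_csv(path)


def probability_table(
    coeffs: CoefficientSet,
    base_profile: CovariateProfile | None = None,
    periods: Sequence[int] = (2, 3, 4, 5),
    inpatient_levels: Sequence[str] = ("none", "le_median", "gt_median"),
    origins: Sequence[str] = ORIGIN_ORDER,
    period_labels: Mapping[int, str] | None = None,
) -> TransitionTable:
    """Stratified model-based transition-probability table (column per cent).

    The base profile fixes the socio-demographic covariates; the grid varies
    the origin state, the outcome period, and the inpatient-care category.
    Values are percentages; each (origin, stratum) 4-vector sums to 100
    before rounding.
    """
    base = base_profile or CovariateProfile()
    labels = PERIOD_LABELS if period_labels is None else period_labels
    cols = pd.MultiIndex.from_product(
        [[labels.get(p, str(p)) for p in periods], list(inpatient_levels)],
        names=["period", "inpatient"],
    )
    rows = pd.MultiIndex.from_tuples(
        [(o, d) for o in origins for d in DEST_ORDER], names=["origin", "destination"]
    )
    data = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for origin in origins:
        for p, plabel in zip(periods, [labels.get(p, str(p)) for p in periods]):
            for inp in inpatient_levels:
                prof = replace(
                    base, previous_state=origin, period=p, inpatient_cat=inp
                )
                probs = softmax_probabilities(linear_predictors(coeffs, prof))
                data.loc[(origin, list(DEST_ORDER)), (plabel, inp)] = probs * 100.0
    return TransitionTable(data=data, kind="model")
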