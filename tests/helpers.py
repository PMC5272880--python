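"""Shared test utilities: record factory, independent oracles, kernel tools."""
from __future__ import annotations

import math

import numpy as np

from workstates.multistate_model import CoefficientSet

DEFAULT_RECORD = {
    "person_id": "P0",
    "year": 1995,
    "earnings": 0.0,
    "unemployment_days": 0,
    "sickness_days": 0,
    "disability_days": 0,
    "parental_days": 0,
    "social_assistance_income": 0.0,
    "student_allowance_income": 0.0,
    "oldage_pension_income": 0.0,
    "disposable_income": 1.0,
    "inpatient_days_countable": 0,
    "inpatient_days_excluded": 0,
    "sex": "male",
    "birth_year": 1970,
    "country_of_birth": "sweden",
    "education": "high_school",
    "died_this_year": False,
    "emigrated_this_year": False,
}


def make_record(**overrides) -> dict:
    rec = dict(DEFAULT_RECORD)
    rec.update(overrides)
    return rec


def oracle_classify(record, cfg):
    """Brute-force position oracle: evaluate every rule family independently,
    then apply the documented precedence.  Deliberately written in a different
    style from the implementation (candidate list, no early returns)."""
    candidates = []
    if record["died_this_year"]:
        candidates.append((0, "died"))
    if record["emigrated_this_year"]:
        candidates.append((1, "emigrated"))
    day_fields = ["disability_days", "sickness_days", "unemployment_days", "parental_days"]
    day_positions = ["disability_pension", "long_term_sick", "long_term_unemployed", "parental_leave"]
    if sum(record[f] for f in day_fields) >= cfg.long_term_days:
        best, best_days = None, -1
        for f, pos in zip(day_fields, day_positions):
            if record[f] > best_days:
                best, best_days = pos, record[f]
        candidates.append((2, best))
    share_fields = ["social_assistance_income", "student_allowance_income", "oldage_pension_income"]
    share_positions = ["social_assistance", "student", "oldage_pension"]
    best, best_inc = None, -1.0
    for f, pos in zip(share_fields, share_positions):
        if record[f] > best_inc:
            best, best_inc = pos, record[f]
    if best_inc > cfg.income_share_cut * record["disposable_income"]:
        candidates.append((3, best))
    if record["earnings"] > cfg.earnings_threshold:
        candidates.append((4, "employed"))
    candidates.append((5, "minimal_income"))
    return min(candidates)[1]


def random_record(rng: np.random.Generator) -> dict:
    """A random but internally consistent register record."""
    disposable = float(rng.uniform(0.1, 5.0))
    return make_record(
        earnings=float(rng.uniform(0, 3.0)),
        unemployment_days=int(rng.integers(0, 250)),
        sickness_days=int(rng.integers(0, 250)),
        disability_days=int(rng.integers(0, 250)),
        parental_days=int(rng.integers(0, 250)),
        social_assistance_income=float(rng.uniform(0, disposable)),
        student_allowance_income=float(rng.uniform(0, disposable)),
        oldage_pension_income=float(rng.uniform(0, disposable)),
        disposable_income=disposable,
        died_this_year=bool(rng.random() < 0.02),
        emigrated_this_year=bool(rng.random() < 0.02),
    )


def model1_coefficients(kernel: dict[str, dict[str, float]]) -> CoefficientSet:
    """Previous-state-only coefficients reproducing a specified 4-way kernel.

    ``kernel`` maps origin -> {destination: probability} over the states
    jobless / self_sufficient / disabled (+ censored destinations allowed).
    Zero probabilities are floored at 1e-13 (log-odds ~ -30).
    """

    def eta(origin, dest):
        p = kernel[origin]
        return math.log(max(p.get(dest, 0.0), 1e-13) / max(p.get("jobless", 0.0), 1e-13))

    terms = ("intercept", "prev:self_sufficient", "prev:disabled")
    beta = np.empty((3, 3))
    for i, dest in enumerate(("self_sufficient", "disabled", "censored")):
        alpha = eta("jobless", dest)
        beta[i] = [
            alpha,
            eta("self_sufficient", dest) - alpha,
            eta("disabled", dest) - alpha,
        ]
    return CoefficientSet(terms=terms, beta=beta)


def empirical_kernel(prev_codes: np.ndarray, next_codes: np.ndarray) -> np.ndarray:
    """Origin (J,S,D) x destination (J,S,D,C) empirical fractions."""
    out = np.full((3, 4), np.nan)
    for o in range(3):
        mask = prev_codes == o
        if mask.sum():
            out[o] = np.bincount(next_codes[mask], minlength=4) / mask.sum()
    return out
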