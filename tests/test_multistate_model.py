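"""Design matrices, likelihood, Newton fit, inference statistics."""
import math

import numpy as np
import pandas as pd
import pytest

import workstates as ws
from workstates.multistate_model import (
    CoefficientSet,
    ModelSpec,
    design_matrix,
    encode_outcomes,
    outcome_probabilities,
)

from helpers import model1_coefficients


def _panel_from_counts(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for (prev, state), n in counts.items():
        rows += [
            {
                "person_id": len(rows) + i,
                "period": 1,
                "state": state,
                "state_prev": prev,
                "sex": "male",
                "age_group": "20-25",
                "country": "sweden",
                "education_prev": "high_school",
                "inpatient_cat": "none",
            }
            for i in range(n)
        ]
    return pd.DataFrame(rows)


def _random_panel(rng: np.random.Generator, n: int = 400) -> pd.DataFrame:
    coeffs = ws.coefficients_from_printed_ors()
    cov = ws.sample_covariate_table(n, seed=rng)
    states = ws.simulate_trajectories(coeffs, cov, periods=3, seed=int(rng.integers(2**31)))
    return ws.trajectories_to_panel(states, cov)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_model1_design_has_three_columns():
    panel = _panel_from_counts(
        {("jobless", "jobless"): 2, ("self_sufficient", "jobless"): 2, ("disabled", "jobless"): 2}
    )
    X, terms = design_matrix(panel, ModelSpec(1))
    assert terms == ("intercept", "prev:self_sufficient", "prev:disabled")
    assert X.shape == (6, 3)


def test_reference_profile_row_is_indicator_free():
    panel = _panel_from_counts({("jobless", "jobless"): 1})
    panel["period"] = 1
    X, _ = design_matrix(panel, ModelSpec(3))
    assert X[0, 0] == 1.0 and (X[0, 1:] == 0.0).all()


def test_design_matrix_matches_dictionary_oracle():
    rng = np.random.default_rng(23)
    panel = _random_panel(rng)
    spec = ModelSpec(3, period_levels=(1, 2, 3))
    X, terms = design_matrix(panel, spec)
    colmap = {
        "prev": "state_prev", "sex": "sex", "age": "age_group",
        "education": "education_prev", "country": "country",
        "inpatient": "inpatient_cat", "period": "period",
    }
    for i, row in panel.reset_index(drop=True).iterrows():
        for j, term in enumerate(terms):
            if term == "intercept":
                expected = 1.0
            else:
                factor, level = term.split(":")
                expected = float(str(row[colmap[factor]]) == level)
            assert X[i, j] == expected


def test_undeclared_level_rejected():
    panel = _panel_from_counts({("jobless", "jobless"): 1})
    panel["sex"] = "unknown"
    with pytest.raises(ValueError, match="undeclared"):
        design_matrix(panel, ModelSpec(2))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_zero_coefficients_give_uniform_loglik():
    panel = _panel_from_counts({("jobless", "jobless"): 7, ("self_sufficient", "disabled"): 5})
    X, terms = design_matrix(panel, ModelSpec(1))
    y = encode_outcomes(panel["state"])
    coeffs = CoefficientSet(terms=terms, beta=np.zeros((3, 3)))
    assert ws.negative_loglik(coeffs, X, y) == pytest.approx(len(panel) * math.log(4))


def test_certain_outcome_gives_vanishing_loglik():
    X = np.array([[1.0]])
    y = np.array([1])  # self-sufficient
    beta = np.array([[50.0], [0.0], [0.0]])
    assert ws.negative_loglik(beta, X, y) < 1e-12


def test_loglik_matches_direct_enumeration():
    rng = np.random.default_rng(29)
    panel = _random_panel(rng, n=100)
    X, terms = design_matrix(panel, ModelSpec(2))
    y = encode_outcomes(panel["state"])
    beta = rng.normal(scale=0.5, size=(3, len(terms)))
    expected = 0.0
    for i in range(len(y)):
        etas = [0.0] + [float(X[i] @ beta[a]) for a in range(3)]
        denom = sum(math.exp(e) for e in etas)
        expected -= math.log(math.exp(etas[y[i]]) / denom)
    assert ws.negative_loglik(beta, X, y) == pytest.approx(expected, rel=1e-10)


def test_probabilities_positive_and_sum_to_one():
    rng = np.random.default_rng(31)
    X = rng.normal(size=(50, 4))
    beta = rng.normal(scale=3.0, size=(3, 4))
    P = outcome_probabilities(beta, X)
    assert (P > 0).all()
    assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-12


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_saturated_intercepts_reproduce_count_ratios():
    """Previous-state-only fit on counts J -> (S, J, D, C) = (82, 100, 10, 8)
    forces intercept odds ratios (0.82, 0.10, 0.08)."""
    panel = _panel_from_counts(
        {
            ("jobless", "self_sufficient"): 82,
            ("jobless", "jobless"): 100,
            ("jobless", "disabled"): 10,
            ("jobless", "censored"): 8,
            # add the other origins so the design is full rank
            ("self_sufficient", "self_sufficient"): 40,
            ("self_sufficient", "jobless"): 10,
            ("self_sufficient", "disabled"): 5,
            ("self_sufficient", "censored"): 5,
            ("disabled", "disabled"): 20,
            ("disabled", "jobless"): 5,
            ("disabled", "self_sufficient"): 4,
            ("disabled", "censored"): 2,
        }
    )
    f = ws.fit(ModelSpec(1), panel)
    assert f.converged
    a = f.coefficients
    assert math.exp(a.get("self_sufficient", "intercept")) == pytest.approx(0.82, abs=1e-6)
    assert math.exp(a.get("disabled", "intercept")) == pytest.approx(0.10, abs=1e-6)
    assert math.exp(a.get("censored", "intercept")) == pytest.approx(0.08, abs=1e-6)
    # origin coefficients follow the closed-form odds-ratio identity
    expected = (40 / 10) / (82 / 100)
    assert math.exp(
        a.get("self_sufficient", "prev:self_sufficient")
    ) == pytest.approx(expected, rel=1e-6)


def test_model1_reproduces_pooled_empirical_fractions(kernel_panel):
    """The previous-state-only model is saturated: its fitted probabilities
    equal the pooled origin -> destination fractions exactly."""
    f = ws.fit(ModelSpec(1), kernel_panel)
    assert f.converged
    for origin in ("jobless", "self_sufficient", "disabled"):
        sub = kernel_panel[kernel_panel["state_prev"] == origin]
        emp = sub["state"].value_counts(normalize=True)
        prof = ws.CovariateProfile(previous_state=origin)
        probs = ws.softmax_probabilities(ws.linear_predictors(f.coefficients, prof))
        for p, dest in zip(probs, ("self_sufficient", "jobless", "disabled", "censored")):
            assert p == pytest.approx(emp.get(dest, 0.0), abs=1e-7)


def test_parameter_recovery_small():
    truth = model1_coefficients(
        {
            "jobless": {"jobless": 0.5, "self_sufficient": 0.4, "disabled": 0.06, "censored": 0.04},
            "self_sufficient": {"jobless": 0.1, "self_sufficient": 0.8, "disabled": 0.06, "censored": 0.04},
            "disabled": {"jobless": 0.1, "self_sufficient": 0.15, "disabled": 0.7, "censored": 0.05},
        }
    )
    cov = ws.sample_covariate_table(8000, seed=37)
    states = ws.simulate_trajectories(truth, cov, periods=4, seed=38)
    panel = ws.trajectories_to_panel(states, cov)
    f = ws.fit(ModelSpec(1, period_levels=(1, 2, 3, 4)), panel)
    z = np.abs(f.coefficients.beta - truth.beta) / f.standard_errors()
    assert (z < 4).all()


def test_estimates_invariant_to_row_order_and_ids(kernel_panel):
    f1 = ws.fit(ModelSpec(2), kernel_panel)
    shuffled = kernel_panel.sample(frac=1.0, random_state=3).reset_index(drop=True)
    shuffled["person_id"] = np.arange(len(shuffled))[::-1]
    f2 = ws.fit(ModelSpec(2), shuffled)
    assert np.allclose(f1.coefficients.beta, f2.coefficients.beta, atol=1e-8)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)


def test_rank_deficiency_names_offending_columns(kernel_panel):
    panel = kernel_panel.copy()
    panel["country"] = "sweden"  # country:other column becomes all-zero
    with pytest.raises(ValueError, match="country:other"):
        ws.fit(ModelSpec(2), panel)


def test_agreement_with_reference_mnlogit(kernel_panel):
    """Hand-written Newton fit matches an established multinomial-logit
    implementation to 1e-6 on 20 random small panels (coefficients, SEs
    and log-likelihood)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(41)
    checked = 0
    attempts = 0
    while checked < 20 and attempts < 40:
        attempts += 1
        panel = _random_panel(rng, n=1200)
        cells = pd.crosstab(panel["state_prev"], panel["state"])
        if cells.shape != (3, 4) or (cells < 2).any().any():
            continue  # quasi-separation: the MLE is not interior
        spec = ModelSpec(2)
        X, terms = design_matrix(panel, spec)
        y = encode_outcomes(panel["state"])
        ours = ws.fit(spec, panel, tol=1e-10)
        if not ours.converged:
            continue
        ref = sm.MNLogit(y, X).fit(method="newton", maxiter=300, disp=0, tol=1e-12)
        assert np.max(np.abs(ours.coefficients.beta.T - ref.params)) < 1e-6
        assert np.max(np.abs(ours.standard_errors().T - ref.bse)) < 1e-6
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)
        checked += 1
    assert checked == 20


# ---------------------------------------------------------------------------
# inference statistics
# ---------------------------------------------------------------------------

def test_odds_ratio_intervals_match_quantile_oracle(kernel_panel):
    from scipy import stats

    f = ws.fit(ModelSpec(2), kernel_panel)
    table = ws.odds_ratios(f, level=0.95)
    z = stats.norm.ppf(0.975)
    beta = f.coefficients.beta
    se = f.standard_errors()
    for i, outcome in enumerate(f.coefficients.outcomes):
        for j, term in enumerate(f.coefficients.terms):
            assert table.loc[term, (outcome, "or")] == pytest.approx(math.exp(beta[i, j]))
            assert table.loc[term, (outcome, "lo")] == pytest.approx(
                math.exp(beta[i, j] - z * se[i, j])
            )
            assert table.loc[term, (outcome, "hi")] == pytest.approx(
                math.exp(beta[i, j] + z * se[i, j])
            )


def test_zero_coefficient_with_zero_se_gives_unit_or():
    spec = ModelSpec(1)
    f = ws.FittedModel(
        spec=spec,
        coefficients=CoefficientSet(terms=spec.terms, beta=np.zeros((3, 3))),
        covariance=np.zeros((9, 9)),
        loglik=-1.0,
        n_rows=1,
        n_iter=0,
        converged=True,
    )
    tab = ws.odds_ratios(f)
    assert (tab.to_numpy() == 1.0).all()
    # coef = ln 2, se = 0 -> OR exactly 2 with degenerate interval
    f.coefficients.beta[0, 0] = math.log(2.0)
    tab = ws.odds_ratios(f)
    assert tab.loc["intercept", ("self_sufficient", "or")] == pytest.approx(2.0)
    assert tab.loc["intercept", ("self_sufficient", "lo")] == pytest.approx(2.0)


def test_lr_test_identical_models(kernel_panel):
    f = ws.fit(ModelSpec(1), kernel_panel)
    res = ws.likelihood_ratio_test(f, f)
    assert res.statistic == 0.0 and res.df == 0 and res.pvalue == 1.0


def test_nested_loglik_ordering_and_lr_nonnegative(kernel_panel):
    f1 = ws.fit(ModelSpec(1), kernel_panel)
    f2 = ws.fit(ModelSpec(2), kernel_panel)
    f3 = ws.fit(ModelSpec(3), kernel_panel)
    assert f1.loglik <= f2.loglik <= f3.loglik
    for small, large in [(f1, f2), (f2, f3), (f1, f3)]:
        res = ws.likelihood_ratio_test(small, large)
        assert res.statistic >= 0.0
        assert res.df == large.n_params - small.n_params


def test_lr_test_rejects_non_nested(kernel_panel):
    f2 = ws.fit(ModelSpec(2), kernel_panel)
    f1 = ws.fit(ModelSpec(1), kernel_panel)
    with pytest.raises(ValueError, match="nested"):
        ws.likelihood_ratio_test(f2, f1)


def test_pseudo_r2_matches_definitional_oracle(kernel_panel):
    f = ws.fit(ModelSpec(2), kernel_panel)
    counts = kernel_panel["state"].value_counts()
    n = counts.sum()
    ll0 = sum(c * math.log(c / n) for c in counts)
    assert ws.pseudo_r2(f) == pytest.approx(1.0 - f.loglik / ll0, rel=1e-10)
    assert 0.0 <= ws.pseudo_r2(f) < 1.0


def test_pseudo_r2_approaches_one_under_separation():
    panel = _panel_from_counts(
        {
            ("jobless", "self_sufficient"): 50,
            ("self_sufficient", "jobless"): 50,
            ("disabled", "disabled"): 50,
        }
    )
    f = ws.fit(ModelSpec(1), panel, max_iter=30)
    assert ws.pseudo_r2(f) > 0.9
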