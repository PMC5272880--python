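"""First-order Markov transition models fitted by multinomial-logit ML.

The unit of analysis is a person-period transition row: state at period *p*
regressed on the state at period *p − 1* and covariates, with the outcome
"Jobless" as the reference category.  The three non-reference equations
(Self-sufficient, Disabled, Censored vs Jobless) are estimated jointly so
that the four predicted probabilities sum to one.  Repeated rows within a
person are treated as independent under the Markov conditional-independence
assumption, and rows with a censored previous state are excluded upstream
(censoring is absorbing).

Three nested specifications are supported:

* Model 1 — previous state only (a homogeneous first-order Markov chain);
* Model 2 — + sex, age group (fixed at baseline), education at the previous
  period, country of birth;
* Model 3 — + inpatient-care category (days in the two years before the
  outcome year: none / ≤ median / > median among those with any care) and
  period dummies for the unequally spaced measurement intervals.

Estimation is a hand-written Newton–Raphson on the analytic gradient and
Hessian of the multinomial likelihood; no regression library is involved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OUTCOME_ORDER",
    "EQUATION_OUTCOMES",
    "FACTOR_LEVELS",
    "ModelSpec",
    "CoefficientSet",
    "FittedModel",
    "design_matrix",
    "design_columns_from_levels",
    "encode_outcomes",
    "outcome_probabilities",
    "negative_loglik",
    "fit",
    "odds_ratios",
    "likelihood_ratio_test",
    "pseudo_r2",
]

# outcome coding: 0 = reference (jobless), then the three modelled equations
OUTCOME_ORDER = ("jobless", "self_sufficient", "disabled", "censored")
EQUATION_OUTCOMES = ("self_sufficient", "disabled", "censored")

# factor levels, reference level first
FACTOR_LEVELS: dict[str, tuple] = {
    "prev": ("jobless", "self_sufficient", "disabled"),
    "sex": ("male", "female"),
    "age": ("20-25", "26-30", "31-35", "36-40"),
    "education": ("high_school", "lower", "higher"),
    "country": ("sweden", "other"),
    "inpatient": ("none", "le_median", "gt_median"),
    "period": (1, 2, 3, 4, 5),
}

# which column of a person-period panel carries each factor
PANEL_COLUMN = {
    "prev": "state_prev",
    "sex": "sex",
    "age": "age_group",
    "education": "education_prev",
    "country": "country",
    "inpatient": "inpatient_cat",
    "period": "period",
}

_MODEL_FACTORS = {
    1: ("prev",),
    2: ("prev", "sex", "age", "education", "country"),
    3: ("prev", "sex", "age", "education", "country", "inpatient", "period"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the three nested model specifications.

    ``period_levels`` lists the outcome-period indices present in the panel
    (reference is the first); it only matters for Model 3.
    """

    model_id: int
    period_levels: tuple = tuple(FACTOR_LEVELS["period"])

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_FACTORS:
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def factors(self) -> tuple[str, ...]:
        return _MODEL_FACTORS[self.model_id]

    def levels(self, factor: str) -> tuple:
        if factor == "period":
            return tuple(self.period_levels)
        return FACTOR_LEVELS[factor]

    @property
    def terms(self) -> tuple[str, ...]:
        out = ["intercept"]
        for f in self.factors:
            out.extend(f"{f}:{lvl}" for lvl in self.levels(f)[1:])
        return tuple(out)


@dataclass
class CoefficientSet:
    """Log-odds coefficients of the three jointly estimated equations.

    ``beta`` has one row per non-reference outcome (order
    ``EQUATION_OUTCOMES``) and one column per design term (``terms``,
    intercept first).
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    outcomes: tuple[str, ...] = EQUATION_OUTCOMES

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.outcomes), len(self.terms)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"({len(self.outcomes)}, {len(self.terms)})"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("coefficients must be finite")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("term labels must be unique")

    def get(self, outcome: str, term: str) -> float:
        return float(self.beta[self.outcomes.index(outcome), self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta.T, index=list(self.terms), columns=list(self.outcomes))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CoefficientSet":
        return cls(
            terms=tuple(frame.index),
            beta=frame[list(EQUATION_OUTCOMES)].to_numpy().T,
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "outcomes": list(self.outcomes),
            "beta": self.beta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        return cls(terms=tuple(d["terms"]), beta=np.asarray(d["beta"]),
                   outcomes=tuple(d.get("outcomes", EQUATION_OUTCOMES)))


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: CoefficientSet
    covariance: np.ndarray  # (3k, 3k), equation-major parameter order
    loglik: float
    n_rows: int
    n_iter: int
    converged: bool
    outcome_counts: np.ndarray = field(default_factory=lambda: np.zeros(4, int))

    @property
    def n_params(self) -> int:
        return self.coefficients.beta.size

    def standard_errors(self) -> np.ndarray:
        """SEs shaped like ``coefficients.beta`` (3 × k)."""
        k = len(self.coefficients.terms)
        se = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return se.reshape(3, k)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _parse_term(term: str) -> tuple[str, str]:
    factor, _, level = term.partition(":")
    return factor, level


def design_columns_from_levels(
    terms: Sequence[str], levels: Mapping[str, object], n: int | None = None
) -> np.ndarray:
    """Build a design matrix from per-factor level values.

    ``levels`` maps factor name → scalar level or array of levels (length
    *n*).  Used both for panel rows and for single covariate profiles; any
    factor not named in ``terms`` is ignored.
    """
    if n is None:
        n = max(
            (np.size(v) for v in levels.values() if np.ndim(v) > 0),
            default=1,
        )
    X = np.empty((n, len(terms)), dtype=float)
    for j, term in enumerate(terms):
        if term == "intercept":
            X[:, j] = 1.0
            continue
        factor, level = _parse_term(term)
        if factor not in levels:
            raise ValueError(f"no value supplied for factor {factor!r}")
        vals = np.asarray(levels[factor])
        X[:, j] = (vals.astype(str) == level).astype(float)
    return X


def design_matrix(
    panel: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Dummy-coded design matrix for a person-period panel.

    Reference levels carry no column; the intercept column comes first and
    the column order is deterministic (factor order of the spec, declared
    level order within factor).  Unknown factor levels raise.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    levels: dict[str, np.ndarray] = {}
    for f in spec.factors:
        col = panel[PANEL_COLUMN[f]]
        observed = set(col.astype(str).unique())
        declared = {str(l) for l in spec.levels(f)}
        if not observed <= declared:
            raise ValueError(
                f"factor {f!r} has undeclared levels {sorted(observed - declared)}"
            )
        levels[f] = col.to_numpy()
    X = design_columns_from_levels(spec.terms, levels, n=len(panel))
    return X, spec.terms


def encode_outcomes(states: Iterable[str]) -> np.ndarray:
    codes = {s: i for i, s in enumerate(OUTCOME_ORDER)}
    return np.array([codes[str(s)] for s in states], dtype=np.int64)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def outcome_probabilities(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise four-way probabilities (columns ordered as OUTCOME_ORDER).

    The reference outcome has linear predictor 0; probabilities are
    computed with max-subtraction for numerical stability and sum to one to
    machine precision.
    """
    eta = X @ np.asarray(beta, dtype=float).T  # (n, 3)
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=1, keepdims=True)
    return full


def negative_loglik(
    coeffs: CoefficientSet | np.ndarray, X: np.ndarray, y: np.ndarray
) -> float:
    """−Σ log p_i(y_i) for outcome codes ``y`` (0 = reference)."""
    beta = coeffs.beta if isinstance(coeffs, CoefficientSet) else np.asarray(coeffs)
    eta = X @ beta.T
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    m = full.max(axis=1)
    lse = m + np.log(np.exp(full - m[:, None]).sum(axis=1))
    chosen = full[np.arange(len(y)), y]
    return float(np.sum(lse - chosen))


def _gradient_hessian(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient and Hessian of the *negative* log-likelihood."""
    n, k = X.shape
    P = outcome_probabilities(beta, X)  # (n, 4)
    Y = np.zeros((n, 3))
    pos = y > 0
    Y[np.arange(n)[pos], y[pos] - 1] = 1.0
    G = ((P[:, 1:] - Y).T @ X).ravel()  # (3k,), equation-major
    H = np.empty((3 * k, 3 * k))
    for a in range(3):
        pa = P[:, a + 1]
        for b in range(a, 3):
            w = pa * ((1.0 if a == b else 0.0) - P[:, b + 1])
            block = X.T @ (X * w[:, None])  # NLL Hessian block (PSD overall)
            H[a * k : (a + 1) * k, b * k : (b + 1) * k] = block
            if b != a:
                H[b * k : (b + 1) * k, a * k : (a + 1) * k] = block.T
    return G, H, P


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    # column-pivoted QR names the offending (linearly dependent) columns
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [terms[piv[i]] for i in range(len(terms)) if diag[i] <= tol]
    if bad:
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")


def fit(
    spec: ModelSpec,
    panel: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> FittedModel:
    """Maximum-likelihood fit by Newton–Raphson with step halving.

    Convergence is declared when the gradient max-norm drops below ``tol``.
    ``ridge`` adds a small diagonal to the Hessian (a logged last resort for
    near-separation); the reported covariance is the inverse observed
    information at the optimum.
    """
    X, terms = design_matrix(panel, spec)
    y = encode_outcomes(panel["state"])
    _check_rank(X, terms)
    n, k = X.shape
    beta = np.zeros((3, k))
    nll = negative_loglik(beta, X, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        G, H, _ = _gradient_hessian(beta, X, y)
        if np.max(np.abs(G)) < tol:
            converged = True
            it -= 1
            break
        Hs = H if ridge == 0.0 else H + ridge * np.eye(3 * k)
        try:
            step = np.linalg.solve(Hs, G)
        except np.linalg.LinAlgError:
            import logging

            logging.getLogger(__name__).warning(
                "singular Hessian; retrying with ridge 1e-8"
            )
            step = np.linalg.solve(H + 1e-8 * np.eye(3 * k), G)
        scale = 1.0
        for _ in range(40):  # step halving on likelihood decrease
            cand = beta - scale * step.reshape(3, k)
            cand_nll = negative_loglik(cand, X, y)
            if cand_nll <= nll + 1e-10:
                break
            scale *= 0.5
        beta, nll = cand, cand_nll
    else:
        G, H, _ = _gradient_hessian(beta, X, y)
        converged = bool(np.max(np.abs(G)) < tol)

    G, H, _ = _gradient_hessian(beta, X, y)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return FittedModel(
        spec=spec,
        coefficients=CoefficientSet(terms=terms, beta=beta),
        covariance=cov,
        loglik=-nll,
        n_rows=n,
        n_iter=it,
        converged=converged,
        outcome_counts=np.bincount(y, minlength=4),
    )


# ---------------------------------------------------------------------------
# inference and fit statistics
# ---------------------------------------------------------------------------

def odds_ratios(fitted: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """exp(coefficient) with Wald confidence intervals.

    Returns a frame indexed by design term with a (outcome, quantity)
    column MultiIndex, three outcome blocks against the Jobless reference.
    """
    if not fitted.converged:
        raise ValueError("fit did not converge; odds ratios would be unreliable")
    z = stats.norm.ppf(0.5 + level / 2.0)
    beta = fitted.coefficients.beta
    se = fitted.standard_errors()
    blocks = {}
    for i, outcome in enumerate(fitted.coefficients.outcomes):
        blocks[(outcome, "or")] = np.exp(beta[i])
        blocks[(outcome, "lo")] = np.exp(beta[i] - z * se[i])
        blocks[(outcome, "hi")] = np.exp(beta[i] + z * se[i])
    out = pd.DataFrame(blocks, index=list(fitted.coefficients.terms))
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(small: FittedModel, large: FittedModel) -> LRTestResult:
    """Likelihood-ratio test of two nested fits on the same rows."""
    if not set(small.coefficients.terms) <= set(large.coefficients.terms):
        raise ValueError("models are not nested (term sets)")
    if small.n_rows != large.n_rows:
        raise ValueError("models were fitted on different row counts")
    df = large.n_params - small.n_params
    stat = max(2.0 * (large.loglik - small.loglik), 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTestResult(statistic=stat, df=df, pvalue=p)


def pseudo_r2(fitted: FittedModel) -> float:
    """McFadden pseudo-R²: 1 − LL(model) / LL(intercept-only).

    The intercept-only log-likelihood has the closed form Σ n_k log(n_k/n)
    over the outcome frequencies of the same rows.
    """
    counts = np.asarray(fitted.outcome_counts, dtype=float)
    n = counts.sum()
    nz = counts > 0
    ll0 = float(np.sum(counts[nz] * np.log(counts[nz] / n)))
    if ll0 == 0.0:
        return 0.0
    return 1.0 - fitted.loglik / ll0
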