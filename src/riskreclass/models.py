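"""Binary-outcome logistic risk models and calibration testing.

The *established* sickness-absence prognostic models regress a binary high-SA
outcome on age, self-rated health and prior SA; the *extended* models add the
fatigue score.  Predictors enter on scaled units (age and fatigue per 10, SRH
per category, prior SA days per 10 days, prior SA episodes per episode) so
coefficients exponentiate to the odds ratios conventionally reported.

Fitting is maximum likelihood (statsmodels); calibration is assessed with the
Hosmer-Lemeshow grouped chi-square test on risk deciles, df = groups - 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, norm

from .cohort import (
    Cohort,
    HIGH_SA_DAYS_THRESHOLD,
    HIGH_SA_EPISODES_THRESHOLD,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FittedRiskModel",
    "CalibrationResult",
    "established_spec",
    "extended_spec",
    "outcome_labels",
    "fit_logistic",
    "predict_risk",
    "odds_ratios",
    "hosmer_lemeshow",
]

#: outcome name -> (source column, threshold on that column)
OUTCOME_DEFINITIONS = {
    "high_sa_days": ("fu_sa_days", HIGH_SA_DAYS_THRESHOLD),
    "high_sa_episodes": ("fu_sa_episodes", HIGH_SA_EPISODES_THRESHOLD),
}

#: the prior-SA predictor and its scaling divisor, per outcome
_PRIOR_TERM = {
    "high_sa_days": ("prior_sa_days", 10.0),
    "high_sa_episodes": ("prior_sa_episodes", 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome to model and which scaled predictors to use.

    ``predictors`` is an ordered tuple of ``(field, divisor)``; an empty tuple
    fits an intercept-only model.
    """

    outcome: str
    predictors: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_DEFINITIONS:
            raise ValidationError(
                f"unknown outcome {self.outcome!r}; expected one of "
                f"{sorted(OUTCOME_DEFINITIONS)}"
            )
        for fld, divisor in self.predictors:
            if divisor <= 0:
                raise ValidationError(f"divisor for {fld!r} must be > 0")

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(f for f, _ in self.predictors)

    def term_names(self) -> tuple[str, ...]:
        out = []
        for fld, divisor in self.predictors:
            out.append(fld if divisor == 1 else f"{fld}/{divisor:g}")
        return tuple(out)


def established_spec(outcome: str) -> ModelSpec:
    """Established model: age + SRH + prior SA (days or episodes per outcome)."""
    prior = _PRIOR_TERM[outcome]
    return ModelSpec(outcome, (("age", 10.0), ("srh", 1.0), prior))


def extended_spec(outcome: str) -> ModelSpec:
    """Extended model: the established predictors plus fatigue (per 10 points)."""
    base = established_spec(outcome)
    return ModelSpec(outcome, base.predictors + (("fatigue", 10.0),))


@dataclass(frozen=True)
class FittedRiskModel:
    spec: ModelSpec
    intercept: float
    coefficients: np.ndarray  # log-odds per scaled unit, aligned with spec
    cov_params: np.ndarray  # (p+1)x(p+1), intercept first
    n_used: int
    converged: bool
    log_likelihood: float
    diagnostic: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.spec.predictors):
            raise ValidationError("coefficient count != predictor count")

    @property
    def params(self) -> np.ndarray:
        return np.concatenate(([self.intercept], self.coefficients))


@dataclass(frozen=True)
class CalibrationResult:
    """Hosmer-Lemeshow grouped goodness-of-fit result."""

    chi2: float
    df: int
    p_value: float
    table: pd.DataFrame = field(compare=False)  # n, mean_risk, observed, expected


def outcome_labels(cohort: Cohort, outcome: str) -> pd.Series:
    """Boolean outcome labels (nullable) derived from follow-up SA counts."""
    col, threshold = OUTCOME_DEFINITIONS[outcome]
    vals = cohort.frame[col]
    return (vals >= threshold).astype("boolean").where(vals.notna())


def _design(cohort: Cohort, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    y = outcome_labels(cohort, spec.outcome)
    cols = {}
    for fld, divisor in spec.predictors:
        cols[fld if divisor == 1 else f"{fld}/{divisor:g}"] = (
            cohort.frame[fld].astype(float) / divisor
        )
    X = pd.DataFrame(cols, index=cohort.frame.index)
    mask = y.notna() & (X.notna().all(axis=1) if len(X.columns) else True)
    return X[mask].astype(float), y[mask].astype(bool)


def fit_logistic(cohort: Cohort, spec: ModelSpec) -> FittedRiskModel:
    """Maximum-likelihood logistic fit of ``spec`` on the complete cases.

    Uses Newton iterations with a log-likelihood tolerance of 1e-8 and at most
    100 iterations; the fit is deterministic.  Perfect separation is reported
    as a non-converged model with a diagnostic rather than silent estimates; a
    constant predictor raises :class:`ValidationError` naming it.
    """
    X, y = _design(cohort, spec)
    n = len(y)
    if n == 0 or y.nunique() < 2:
        raise ValidationError(
            f"outcome {spec.outcome!r} needs both classes present "
            f"(n={n} after complete-case filtering)"
        )
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValidationError(f"degenerate (constant) predictor: {col!r}")
    design = sm.add_constant(X, has_constant="add")
    converged = True
    diagnostic = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y.astype(float), design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0,
                warn_convergence=False,
            )
        except Exception as exc:  # separation surfaces as a singular Hessian
            diagnostic = (
                "maximum-likelihood fit failed (perfect separation or "
                f"degenerate design): {exc}"
            )
            logger.warning("fit_logistic(%s): %s", spec.outcome, diagnostic)
            p = len(spec.predictors)
            return FittedRiskModel(
                spec=spec,
                intercept=float("nan"),
                coefficients=np.full(p, np.nan),
                cov_params=np.full((p + 1, p + 1), np.nan),
                n_used=n,
                converged=False,
                log_likelihood=float("nan"),
                diagnostic=diagnostic,
            )
    for w in caught:
        if "separation" in str(w.message).lower():
            converged = False
            diagnostic = f"perfect separation detected: {w.message}"
    if not res.mle_retvals.get("converged", False):
        converged = False
        diagnostic = diagnostic or "Newton iterations did not converge"
    if not converged:
        logger.warning("fit_logistic(%s): %s", spec.outcome, diagnostic)
    params = np.asarray(res.params, dtype=float)
    return FittedRiskModel(
        spec=spec,
        intercept=float(params[0]),
        coefficients=params[1:],
        cov_params=np.asarray(res.cov_params(), dtype=float),
        n_used=n,
        converged=converged,
        log_likelihood=float(res.llf),
        diagnostic=diagnostic,
    )


def predict_risk(model: FittedRiskModel, cohort: Cohort) -> pd.Series:
    """Predicted outcome probabilities aligned to the cohort's records.

    Records missing a required predictor get a missing risk.  Requires a
    converged model.
    """
    if not model.converged:
        raise ValidationError(
            f"cannot predict from a non-converged model: {model.diagnostic}"
        )
    lp = pd.Series(model.intercept, index=cohort.frame.index, dtype=float)
    for (fld, divisor), beta in zip(model.spec.predictors, model.coefficients):
        lp = lp + beta * cohort.frame[fld].astype(float) / divisor
    return pd.Series(expit(lp), index=cohort.frame.index, name="risk").where(lp.notna())


def odds_ratios(model: FittedRiskModel, level: float = 0.95) -> pd.DataFrame:
    """Wald odds-ratio table: OR = exp(beta), CI = exp(beta +/- z SE), p two-sided."""
    if not model.converged:
        raise ValidationError("odds_ratios requires a converged model")
    z = norm.ppf(0.5 + level / 2)
    se = np.sqrt(np.diag(model.cov_params))[1:]
    beta = model.coefficients
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                         np.inf * np.sign(beta))
    return pd.DataFrame({
        "predictor": model.spec.term_names(),
        "or": np.exp(beta),
        "ci_low": np.exp(beta - z * se),
        "ci_high": np.exp(beta + z * se),
        "p": 2 * norm.sf(np.abs(zstat)),
    })


def _hl_groups(order: np.ndarray, risks: np.ndarray, groups: int) -> list[np.ndarray]:
    """Risk-ordered near-equal groups; tied risks stay in the lower group."""
    n = len(order)
    sorted_risks = risks[order]
    boundaries = [round(n * g / groups) for g in range(1, groups)]
    adjusted = []
    prev = 0
    for b in boundaries:
        # push the boundary past any run of ties so the run stays intact below
        while 0 < b < n and sorted_risks[b] == sorted_risks[b - 1]:
            b += 1
        b = min(b, n)
        if b > prev:
            adjusted.append(b)
            prev = b
    edges = [0] + adjusted + [n]
    return [order[edges[i]:edges[i + 1]] for i in range(len(edges) - 1)
            if edges[i + 1] > edges[i]]


def hosmer_lemeshow(
    risks: np.ndarray, events: np.ndarray, groups: int = 10
) -> CalibrationResult:
    """Hosmer-Lemeshow grouped chi-square calibration test.

    Subjects are ranked by predicted risk and split into ``groups``
    near-equal-size groups (ties kept together in the lower group); the
    statistic is ``sum (O_g - E_g)^2 / (n_g pibar_g (1 - pibar_g))`` with
    ``E_g = sum of risks`` in the group, referred to chi-square with
    ``groups - 2`` degrees of freedom.  A group with mean risk 0 or 1
    contributes nothing (warned).
    """
    risks = np.asarray(risks, dtype=float)
    events = np.asarray(events, dtype=bool)
    if risks.shape != events.shape:
        raise ValidationError("risks and events must have equal length")
    n = len(risks)
    if groups < 2:
        raise ValidationError("groups must be >= 2")
    if n < groups:
        raise ValidationError(f"need at least {groups} observations, got {n}")
    order = np.argsort(risks, kind="stable")
    group_idx = _hl_groups(order, risks, groups)
    rows = []
    stat = 0.0
    for idx in group_idx:
        n_g = len(idx)
        pibar = float(risks[idx].mean())
        observed = int(events[idx].sum())
        expected = float(risks[idx].sum())
        rows.append({"n": n_g, "mean_risk": pibar,
                     "observed": observed, "expected": expected})
        denom = n_g * pibar * (1 - pibar)
        if denom <= 0:
            logger.warning(
                "hosmer_lemeshow: group with mean risk %g skipped", pibar
            )
            continue
        stat += (observed - expected) ** 2 / denom
    df = max(len(group_idx) - 2, 1)
    return CalibrationResult(
        chi2=float(stat),
        df=df,
        p_value=float(chi2_sf(stat, df)),
        table=pd.DataFrame(rows),
    )


def chi2_sf(stat: float, df: int) -> float:
    return float(chi2.sf(stat, df))
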