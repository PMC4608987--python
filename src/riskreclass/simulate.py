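"""Seeded synthetic occupational cohorts.

Generates per-worker cohorts whose marginal distributions match the study
population the package models: n = 579 office workers, age 44.4 +/- 9.3 y,
CIS fatigue 51.2 +/- 21.0 (truncated to its 20-140 score range), self-rated
health distributed 25/57/18/1 % over excellent/good/fair/poor, binned prior
sickness-absence marginals, and binary high-SA outcomes drawn from logistic
models whose coefficients equal the published univariate odds ratios
(fatigue 1.16/1.14 per 10 points, prior episodes 1.60 per episode, SRH
0.59/0.56 per category, age 0.99/0.92 per 10 years).  Outcome-model
intercepts are calibrated numerically so prevalences land near 10 % (high SA
days) and 11 % (high SA episodes).

Fatigue and SRH are drawn jointly through a Gaussian copula whose latent
correlation is solved (tetrachoric-style, via a Hermite expansion) to hit the
target Pearson correlation of -0.44 between the fatigue score and the 1-4 SRH
coding: higher fatigue accompanies worse self-rated health.

A raw episode register consistent with a cohort's follow-up outcomes can also
be generated, with a configurable fraction of merged episodes split by
sub-28-day gaps so the register aggregation rule is exercised.
"""

from __future__ import annotations

import datetime as dt
import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtr, ndtri
from scipy.stats import truncnorm

from .cohort import Cohort, Episode, EpisodeRegister, ValidationError

__all__ = [
    "OutcomeModel",
    "GeneratorParams",
    "default_params",
    "generate_cohort",
    "generate_register",
    "latent_correlation",
]

FATIGUE_MIN, FATIGUE_MAX = 20, 140

# Prior-SA bins of the study population table: (lo, hi inclusive) per category.
PRIOR_DAYS_BINS = ((0, 0), (1, 7), (8, 14), (15, 30), (31, 60), (61, 180))
PRIOR_EPISODES_BINS = ((0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 8))

_CALIBRATION_SEED = 190_428_571  # internal stream for intercept calibration
_CALIBRATION_N = 100_000


@dataclass(frozen=True)
class OutcomeModel:
    """Generating logistic model for one binary high-SA outcome.

    ``terms`` are ``(field, divisor, log_odds)`` triples: the linear predictor
    is ``intercept + sum(log_odds * field / divisor)``.  ``intercept`` may be
    ``None`` until calibrated against a target prevalence.
    """

    outcome: str  # "high_sa_days" | "high_sa_episodes"
    terms: tuple[tuple[str, float, float], ...]
    target_prevalence: float
    intercept: float | None = None


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator (defaults = study cohort)."""

    n: int = 579
    seed: int = 0
    age_mean: float = 44.4
    age_sd: float = 9.3
    prop_men: float = 361 / 579
    work_hours_mean: float = 34.5
    work_hours_sd: float = 8.0
    #: P(srh = 4..1), i.e. (excellent, good, fair, poor); study counts 143/330/103/3
    srh_probs: tuple[float, float, float, float] = (
        143 / 579, 330 / 579, 103 / 579, 3 / 579,
    )
    fatigue_mean: float = 51.2
    fatigue_sd: float = 21.0
    #: target Pearson correlation between fatigue and SRH on the 1-4 coding
    fatigue_srh_corr: float = -0.44
    #: P over the six PRIOR_DAYS_BINS; study counts 118/143/104/94/60/60
    prior_days_category_probs: tuple[float, ...] = (
        118 / 579, 143 / 579, 104 / 579, 94 / 579, 60 / 579, 60 / 579,
    )
    #: P over the six PRIOR_EPISODES_BINS; study counts 118/130/115/74/64/78
    prior_episodes_category_probs: tuple[float, ...] = (
        118 / 579, 130 / 579, 115 / 579, 74 / 579, 64 / 579, 78 / 579,
    )
    outcome_models: tuple[OutcomeModel, ...] = (
        OutcomeModel(
            "high_sa_days",
            terms=(
                ("age", 10.0, math.log(0.99)),
                ("srh", 1.0, math.log(0.59)),
                ("prior_sa_days", 10.0, math.log(1.02)),
                ("fatigue", 10.0, math.log(1.16)),
            ),
            target_prevalence=59 / 579,
        ),
        OutcomeModel(
            "high_sa_episodes",
            terms=(
                ("age", 10.0, math.log(0.92)),
                ("srh", 1.0, math.log(0.56)),
                ("prior_sa_episodes", 1.0, math.log(1.60)),
                ("fatigue", 10.0, math.log(1.14)),
            ),
            target_prevalence=65 / 579,
        ),
    )
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.age_sd <= 0 or self.fatigue_sd <= 0 or self.work_hours_sd <= 0:
            raise ValidationError("standard deviations must be > 0")
        for name in ("srh_probs", "prior_days_category_probs",
                     "prior_episodes_category_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
                raise ValidationError(f"{name} must be a probability vector")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Gaussian-copula machinery for the fatigue-SRH correlation


@functools.lru_cache(maxsize=32)
def _fatigue_parent_moments(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [20, 140]-truncation has the target mean/sd.

    The score range clips the lower tail, so a parent with the target moments
    would generate a sample mean above and an SD below target; solve the 2-D
    moment equations instead.
    """
    from scipy.optimize import root

    def gap(x):
        mu, sigma = x
        sigma = abs(sigma)
        a = (FATIGUE_MIN - mu) / sigma
        b = (FATIGUE_MAX - mu) / sigma
        m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = root(gap, x0=[mean, sd], tol=1e-12)
    if not sol.success:
        raise ValidationError(
            f"fatigue moments mean={mean}, sd={sd} are infeasible on "
            f"[{FATIGUE_MIN}, {FATIGUE_MAX}]"
        )
    mu, sigma = sol.x[0], abs(sol.x[1])
    return float(mu), float(sigma)


def _fatigue_truncnorm(params: GeneratorParams):
    mu, sigma = _fatigue_parent_moments(params.fatigue_mean, params.fatigue_sd)
    a = (FATIGUE_MIN - mu) / sigma
    b = (FATIGUE_MAX - mu) / sigma
    return truncnorm(a, b, loc=mu, scale=sigma)


def _srh_thresholds(params: GeneratorParams) -> np.ndarray:
    # latent z below threshold[k] -> srh <= k+1 (poor..good); probs are 4..1
    probs_low_to_high = np.asarray(params.srh_probs[::-1])  # poor, fair, good, excellent
    cum = np.cumsum(probs_low_to_high)[:-1]
    return ndtri(np.clip(cum, 1e-12, 1 - 1e-12))


def latent_correlation(params: GeneratorParams) -> float:
    """Latent normal correlation achieving the target fatigue-SRH Pearson r.

    Under the Gaussian copula, SRH is a step function of the second latent
    variable, ``srh = 1 + sum_j 1[z2 > t_j]``, so the fatigue-SRH covariance
    decomposes threshold-wise as ``sum_j Cov(F(z1), 1[z2 > t_j])`` with

        ``E[F(z1) 1(z2 > t_j)] = E[ F(z1) Phi((rho z1 - t_j)/sqrt(1-rho^2)) ]``

    which is a smooth 1-D Gaussian expectation evaluated by Gauss-Hermite
    quadrature; the resulting monotone equation in ``rho`` is solved by
    bisection.  Raises :class:`ValidationError` when the target correlation
    is unattainable for the given marginals.
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(150)
    wts = wts / math.sqrt(2 * math.pi)
    tn = _fatigue_truncnorm(params)
    f_vals = tn.ppf(np.clip(ndtr(nodes), 1e-14, 1 - 1e-14))
    mu_f = float(np.sum(wts * f_vals))
    sd_f = float(math.sqrt(np.sum(wts * (f_vals - mu_f) ** 2)))
    thresholds = _srh_thresholds(params)
    probs = np.asarray(params.srh_probs[::-1])
    vals = np.arange(1, 5)
    mu_g = float(probs @ vals)
    sd_g = float(math.sqrt(probs @ (vals - mu_g) ** 2))
    survivals = 1.0 - ndtr(thresholds)
    target = params.fatigue_srh_corr

    def pearson(rho: float) -> float:
        s = math.sqrt(max(1.0 - rho * rho, 1e-12))
        cov = 0.0
        for t_j, s_j in zip(thresholds, survivals):
            joint = float(np.sum(wts * f_vals * ndtr((rho * nodes - t_j) / s)))
            cov += joint - mu_f * s_j
        return cov / (sd_f * sd_g)

    lo, hi = -0.999999, 0.999999
    if (pearson(lo) - target) * (pearson(hi) - target) > 0:
        raise ValidationError(
            f"target fatigue-SRH correlation {target} is infeasible for the "
            "given marginals"
        )
    return float(brentq(lambda r: pearson(r) - target, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Covariate and outcome sampling


def _draw_covariates(params: GeneratorParams, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    age = rng.normal(params.age_mean, params.age_sd, n)
    gender = np.where(rng.random(n) < params.prop_men, "M", "F")
    work_hours = np.clip(rng.normal(params.work_hours_mean, params.work_hours_sd, n), 1, 80)

    rho = latent_correlation(params)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1 - rho * rho) * rng.standard_normal(n)
    tn = _fatigue_truncnorm(params)
    fatigue = np.rint(tn.ppf(np.clip(ndtr(z1), 1e-14, 1 - 1e-14)))
    fatigue = np.clip(fatigue, FATIGUE_MIN, FATIGUE_MAX).astype(int)
    srh = (1 + np.searchsorted(_srh_thresholds(params), z2)).astype(int)

    # comonotone coupling of the two prior-SA marginals: one latent uniform
    # feeds both binned quantile maps, so zero days coincide with zero episodes
    u = rng.random(n)
    days_cat = np.searchsorted(np.cumsum(params.prior_days_category_probs), u,
                               side="right")
    days_cat = np.clip(days_cat, 0, len(PRIOR_DAYS_BINS) - 1)
    ep_cat = np.searchsorted(np.cumsum(params.prior_episodes_category_probs), u,
                             side="right")
    ep_cat = np.clip(ep_cat, 0, len(PRIOR_EPISODES_BINS) - 1)
    lo_d = np.array([PRIOR_DAYS_BINS[c][0] for c in days_cat])
    hi_d = np.array([PRIOR_DAYS_BINS[c][1] for c in days_cat])
    prior_days = rng.integers(lo_d, hi_d + 1)
    lo_e = np.array([PRIOR_EPISODES_BINS[c][0] for c in ep_cat])
    hi_e = np.array([PRIOR_EPISODES_BINS[c][1] for c in ep_cat])
    prior_episodes = rng.integers(lo_e, hi_e + 1)

    return pd.DataFrame({
        "age": age,
        "gender": gender,
        "work_hours": work_hours,
        "srh": srh,
        "prior_sa_days": prior_days,
        "prior_sa_episodes": prior_episodes,
        "fatigue": fatigue,
    })


def _linear_predictor(model: OutcomeModel, cov: pd.DataFrame) -> np.ndarray:
    if model.intercept is None:
        raise ValidationError(
            f"outcome model {model.outcome!r} has no calibrated intercept"
        )
    lp = np.full(len(cov), model.intercept)
    for fld, divisor, beta in model.terms:
        lp += beta * cov[fld].to_numpy(dtype=float) / divisor
    return lp


@functools.lru_cache(maxsize=8)
def _calibrated_intercepts(params: GeneratorParams) -> tuple[float, ...]:
    rng = np.random.default_rng(_CALIBRATION_SEED)
    cov = _draw_covariates(params, _CALIBRATION_N, rng)
    intercepts = []
    for model in params.outcome_models:
        xb = np.zeros(len(cov))
        for fld, divisor, beta in model.terms:
            xb += beta * cov[fld].to_numpy(dtype=float) / divisor

        def gap(b0: float) -> float:
            return float(expit(b0 + xb).mean()) - model.target_prevalence

        intercepts.append(float(brentq(gap, -20.0, 5.0, xtol=1e-10)))
    return tuple(intercepts)


def default_params(**overrides) -> GeneratorParams:
    """Generator parameters calibrated to the study cohort.

    Marginals follow the published study-population table; outcome-model
    coefficients are the published univariate odds ratios used as joint
    generating log-odds; intercepts are solved by 1-D root finding so that
    simulated prevalences hit 59/579 and 65/579.
    """
    params = GeneratorParams(**overrides)
    intercepts = _calibrated_intercepts(replace(params, n=1, seed=0, missing_rate=0.0))
    models = tuple(
        replace(m, intercept=b0)
        for m, b0 in zip(params.outcome_models, intercepts)
    )
    return replace(params, outcome_models=models)


def _draw_followup_counts(y_days: np.ndarray, y_eps: np.ndarray,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Follow-up SA day/episode counts consistent with the binary labels.

    High-episode workers get 3-5 merged episodes; high-day workers accumulate
    30-120 days; otherwise counts stay below the outcome thresholds.  Counts
    respect days >= episodes and days > 0 iff episodes > 0, and every
    combination fits a 365-day window with 28-day separations between merged
    episodes.
    """
    n = len(y_days)
    eps = np.zeros(n, dtype=int)
    high_e = y_eps.astype(bool)
    eps[high_e] = rng.choice([3, 4, 5], size=int(high_e.sum()), p=[0.5, 0.3, 0.2])
    only_days = (~high_e) & y_days.astype(bool)
    eps[only_days] = rng.choice([1, 2], size=int(only_days.sum()), p=[0.6, 0.4])
    neither = (~high_e) & (~y_days.astype(bool))
    eps[neither] = rng.choice([0, 1, 2], size=int(neither.sum()),
                              p=[0.45, 0.35, 0.20])
    days = np.zeros(n, dtype=int)
    high_d = y_days.astype(bool)
    days[high_d] = rng.integers(30, 121, size=int(high_d.sum()))
    low_d = (~high_d) & (eps > 0)
    days[low_d] = rng.integers(eps[low_d], 30)
    return days, eps


def generate_cohort(params: GeneratorParams | None = None) -> Cohort:
    """Draw a synthetic cohort; deterministic given ``params.seed``.

    When ``params.missing_rate`` > 0, ``round(missing_rate * n)`` records get
    exactly one analysis field blanked, so complete-case filtering removes a
    predictable number of workers.
    """
    if params is None:
        params = default_params()
    if any(m.intercept is None for m in params.outcome_models):
        intercepts = _calibrated_intercepts(
            replace(params, n=1, seed=0, missing_rate=0.0)
        )
        params = replace(
            params,
            outcome_models=tuple(
                replace(m, intercept=m.intercept if m.intercept is not None else b0)
                for m, b0 in zip(params.outcome_models, intercepts)
            ),
        )
    rng = np.random.default_rng(params.seed)
    cov = _draw_covariates(params, params.n, rng)
    outcomes = {}
    for model in params.outcome_models:
        risk = expit(_linear_predictor(model, cov))
        outcomes[model.outcome] = rng.random(params.n) < risk
    days, eps = _draw_followup_counts(
        outcomes["high_sa_days"], outcomes["high_sa_episodes"], rng
    )
    frame = cov.copy()
    frame.insert(0, "worker_id", [f"W{i:06d}" for i in range(params.n)])
    frame["fu_sa_days"] = days
    frame["fu_sa_episodes"] = eps

    n_missing = round(params.missing_rate * params.n)
    if n_missing:
        rows = rng.choice(params.n, size=n_missing, replace=False)
        fields = ["age", "srh", "prior_sa_days", "prior_sa_episodes",
                  "fatigue", "fu_sa_days", "fu_sa_episodes"]
        which = rng.integers(0, len(fields), size=n_missing)
        frame = frame.astype({c: "Float64" for c in fields})
        for r, w in zip(rows, which):
            frame.loc[r, fields[w]] = pd.NA
    return Cohort(frame, provenance=f"synthetic cohort, seed={params.seed}, n={params.n}")


def generate_register(
    cohort: Cohort,
    window: tuple[dt.date, dt.date] = (dt.date(2007, 1, 1), dt.date(2007, 12, 31)),
    min_gap_days: int = 28,
    split_fraction: float = 0.3,
    seed: int = 0,
) -> EpisodeRegister:
    """Raw episode register whose aggregation reproduces the cohort outcomes.

    Per worker, ``fu_sa_days`` is partitioned over ``fu_sa_episodes`` merged
    episodes placed with >= ``min_gap_days`` days between them; a
    ``split_fraction`` share of multi-day merged episodes is recorded as two
    raw episodes separated by a sub-``min_gap_days`` gap, so merging is
    exercised.  ``aggregate_register`` on the result returns each worker's
    ``(fu_sa_days, fu_sa_episodes)`` exactly.

    Raises :class:`ValidationError` for infeasible day/episode combinations
    (positive days with zero episodes, fewer days than episodes, or a load
    that cannot fit the window).
    """
    rng = np.random.default_rng(seed)
    start, end = window
    window_days = (end - start).days + 1
    episodes: list[Episode] = []
    for rec in cohort.records():
        d, e = rec.fu_sa_days, rec.fu_sa_episodes
        if d is None or e is None:
            continue
        if e == 0:
            if d != 0:
                raise ValidationError(
                    f"worker {rec.worker_id!r}: {d} SA days with 0 episodes"
                )
            continue
        if d < e:
            raise ValidationError(
                f"worker {rec.worker_id!r}: {d} SA days < {e} episodes"
            )
        # partition d days over e merged episodes, each >= 1 day
        if e == 1:
            parts = [d]
        else:
            cuts = np.sort(rng.choice(np.arange(1, d), size=e - 1, replace=False))
            parts = np.diff(np.concatenate(([0], cuts, [d]))).tolist()
        # optionally split a merged episode into two raw ones with a short gap
        pieces: list[list[tuple[int, int]]] = []  # per merged ep: (len, gap-after)
        for p in parts:
            if p >= 2 and min_gap_days > 1 and rng.random() < split_fraction:
                a = int(rng.integers(1, p))
                g = int(rng.integers(1, min_gap_days))
                pieces.append([(a, g), (p - a, 0)])
            else:
                pieces.append([(p, 0)])
        spans = [sum(l + g for l, g in piece) for piece in pieces]
        need = sum(spans) + min_gap_days * (e - 1)
        if need > window_days:
            raise ValidationError(
                f"worker {rec.worker_id!r}: episode load of {need} days "
                f"exceeds the {window_days}-day window"
            )
        slack = window_days - need
        # distribute slack over e+1 gaps (before, between, after)
        extra = rng.multinomial(slack, np.full(e + 1, 1 / (e + 1)))
        day = 0
        for i, piece in enumerate(pieces):
            day += int(extra[i])
            if i > 0:
                day += min_gap_days
            for length, gap_after in piece:
                ep_start = start + dt.timedelta(days=day)
                ep_end = ep_start + dt.timedelta(days=length - 1)
                episodes.append(Episode(ep_start, ep_end, rec.worker_id))
                day += length + gap_after
    return EpisodeRegister(tuple(episodes), window)
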