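"""Risk reclassification and discrimination-improvement statistics.

Given each subject's predicted risk under an established model (*old*) and
under the model extended with a new predictor (*new*), together with the
observed binary outcome, this module computes:

* reclassification tables — old-category x new-category counts, cross-
  tabulated separately for events and nonevents, at a risk threshold;
* the event and nonevent Net Reclassification Indices,
  NRIe = P(up|event) - P(down|event) and
  NRIne = P(down|nonevent) - P(up|nonevent),
  each ranging -100..100 %, with asymptotic (Wald) inference and their sum;
* the category-free NRI, which counts any directional change of risk as a
  move (flagged with a caveat: it is prone to false-positive conclusions);
* the discrimination slope (mean risk of cases minus mean risk of non-cases)
  and the integrated discrimination improvement, IDI = slope(new) -
  slope(old), with inference from the per-subject risk differences;
* stratified bootstrap percentile intervals as an alternative to the
  asymptotic formulas.

Estimates are stored as proportions; ``MetricResult.estimate_pct`` reports
the percentage scale used in publications.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import ValidationError

__all__ = [
    "RiskPair",
    "RiskPairs",
    "ReclassTable",
    "MetricResult",
    "CategoryFreeNRI",
    "stratify",
    "build_reclass_table",
    "nri_events",
    "nri_nonevents",
    "nri_overall",
    "category_free_nri",
    "discrimination_slope",
    "idi",
    "bootstrap_ci",
    "count_reclassified",
]

CATEGORY_FREE_CAVEAT = (
    "category-free NRI counts any directional risk change as a move and is "
    "prone to false-positive conclusions; interpret with caution"
)


@dataclass(frozen=True)
class RiskPair:
    """One subject's old-model risk, new-model risk and outcome."""

    old_risk: float
    new_risk: float
    event: bool

    def __post_init__(self) -> None:
        for r in (self.old_risk, self.new_risk):
            if not 0.0 < r < 1.0:
                raise ValidationError(f"risk {r} must lie strictly in (0, 1)")


class RiskPairs:
    """Vectorised collection of :class:`RiskPair`."""

    def __init__(self, old: Sequence[float], new: Sequence[float],
                 event: Sequence[bool]) -> None:
        self.old = np.asarray(old, dtype=float)
        self.new = np.asarray(new, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        if not (len(self.old) == len(self.new) == len(self.event)):
            raise ValidationError("old, new and event must have equal length")
        if len(self.old) == 0:
            raise ValidationError("RiskPairs must be non-empty")
        for arr in (self.old, self.new):
            if (arr <= 0).any() or (arr >= 1).any():
                raise ValidationError("risks must lie strictly in (0, 1)")

    @classmethod
    def from_pairs(cls, pairs: Iterable[RiskPair]) -> "RiskPairs":
        pairs = list(pairs)
        return cls([p.old_risk for p in pairs], [p.new_risk for p in pairs],
                   [p.event for p in pairs])

    def __len__(self) -> int:
        return len(self.old)

    def subset(self, idx: np.ndarray) -> "RiskPairs":
        return RiskPairs(self.old[idx], self.new[idx], self.event[idx])

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def n_nonevents(self) -> int:
        return int((~self.event).sum())


def stratify(risk: float, threshold: float) -> str:
    """Risk category at a threshold: ``low`` iff risk <= threshold.

    The boundary is inclusive on the low side, matching reclassification-table
    headers of the form "<=10 % / >10 %".
    """
    if not 0.0 < risk < 1.0 or not 0.0 < threshold < 1.0:
        raise ValidationError("risk and threshold must lie strictly in (0, 1)")
    return "low" if risk <= threshold else "high"


@dataclass(frozen=True, eq=False)
class ReclassTable:
    """Paired old->new category counts at one threshold, split by outcome.

    ``events`` and ``nonevents`` are 2x2 integer arrays with rows = old
    category (low, high) and columns = new category (low, high), so cell
    ``[0, 1]`` counts subjects moving up and ``[1, 0]`` subjects moving down.
    """

    threshold: float
    events: np.ndarray
    nonevents: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReclassTable):
            return NotImplemented
        return (self.threshold == other.threshold
                and np.array_equal(self.events, other.events)
                and np.array_equal(self.nonevents, other.nonevents))

    def __hash__(self) -> int:
        return hash((self.threshold, self.events.tobytes(),
                     self.nonevents.tobytes()))

    def __post_init__(self) -> None:
        for name in ("events", "nonevents"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (2, 2) or (arr < 0).any():
                raise ValidationError(f"{name} must be a nonnegative 2x2 table")
            object.__setattr__(self, name, arr)
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must lie strictly in (0, 1)")

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_nonevents(self) -> int:
        return int(self.nonevents.sum())

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "events": self.events.tolist(),
            "nonevents": self.nonevents.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReclassTable":
        return cls(
            threshold=float(d["threshold"]),
            events=np.asarray(d["events"], dtype=int),
            nonevents=np.asarray(d["nonevents"], dtype=int),
        )


@dataclass(frozen=True)
class MetricResult:
    """A reclassification/discrimination statistic with its inference.

    ``estimate`` is a proportion in [-1, 1] (or [-2, 2] for the overall NRI).
    ``not_available`` marks strata in which no subject changed category — the
    point estimate 0 is retained internally but published tables print "n.a."
    and no inference is attached.
    """

    name: str
    estimate: float
    n: int
    se: float | None = None
    ci: tuple[float, float] | None = None
    p_value: float | None = None
    movers_up: int | None = None
    movers_down: int | None = None
    not_available: bool = False
    note: str = ""

    @property
    def estimate_pct(self) -> float:
        return 100.0 * self.estimate

    @property
    def ci_pct(self) -> tuple[float, float] | None:
        return None if self.ci is None else (100 * self.ci[0], 100 * self.ci[1])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "n": self.n,
            "se": self.se,
            "ci": list(self.ci) if self.ci is not None else None,
            "p_value": self.p_value,
            "movers_up": self.movers_up,
            "movers_down": self.movers_down,
            "not_available": self.not_available,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricResult":
        d = dict(d)
        if d.get("ci") is not None:
            d["ci"] = tuple(d["ci"])
        return cls(**d)


def build_reclass_table(pairs: RiskPairs, threshold: float) -> ReclassTable:
    """Cross-tabulate old vs new risk categories, separately for events."""
    old_high = pairs.old > threshold
    new_high = pairs.new > threshold
    tables = []
    for stratum in (pairs.event, ~pairs.event):
        t = np.zeros((2, 2), dtype=int)
        for i in (0, 1):
            for j in (0, 1):
                t[i, j] = int(
                    (stratum & (old_high == bool(i)) & (new_high == bool(j))).sum()
                )
        tables.append(t)
    return ReclassTable(threshold=threshold, events=tables[0], nonevents=tables[1])


def _z_ci_p(estimate: float, se: float, level: float) -> tuple[tuple[float, float], float]:
    z = norm.ppf(0.5 + level / 2)
    ci = (estimate - z * se, estimate + z * se)
    p = 2 * norm.sf(abs(estimate) / se) if se > 0 else 0.0
    return ci, float(p)


def _nri_component(name: str, favorable: int, unfavorable: int, n: int,
                   movers_up: int, movers_down: int,
                   level: float = 0.95) -> MetricResult:
    """Net move proportion (favorable - unfavorable)/n with binomial-difference
    inference.

    Variance: ``(p_f + p_u - (p_f - p_u)^2) / n``.  When nobody moved or the
    stratum is empty, the result is flagged ``not_available`` with the point
    estimate 0 retained and no inference.
    """
    if n == 0 or (favorable == 0 and unfavorable == 0):
        return MetricResult(name=name, estimate=0.0, n=n, movers_up=movers_up,
                            movers_down=movers_down, not_available=True)
    p_f, p_u = favorable / n, unfavorable / n
    estimate = p_f - p_u
    var = (p_f + p_u - (p_f - p_u) ** 2) / n
    se = float(np.sqrt(var))
    ci, p = _z_ci_p(estimate, se, level)
    return MetricResult(name=name, estimate=estimate, n=n, se=se, ci=ci,
                        p_value=p, movers_up=movers_up, movers_down=movers_down)


def nri_events(table: ReclassTable, level: float = 0.95) -> MetricResult:
    """NRIe = P(up|event) - P(down|event): net share of events moved up."""
    up, down = int(table.events[0, 1]), int(table.events[1, 0])
    return _nri_component("NRIe", up, down, table.n_events, up, down, level)


def nri_nonevents(table: ReclassTable, level: float = 0.95) -> MetricResult:
    """NRIne = P(down|nonevent) - P(up|nonevent): net share of nonevents moved down."""
    up, down = int(table.nonevents[0, 1]), int(table.nonevents[1, 0])
    return _nri_component("NRIne", down, up, table.n_nonevents, up, down, level)


def nri_overall(table: ReclassTable, level: float = 0.95) -> MetricResult:
    """Sum of the event and nonevent components, SE by independence."""
    e = nri_events(table, level)
    ne = nri_nonevents(table, level)
    estimate = e.estimate + ne.estimate
    n = e.n + ne.n
    if e.not_available or ne.not_available:
        return MetricResult(name="NRI_overall", estimate=estimate, n=n,
                            not_available=True,
                            note="a component had no category changes")
    se = float(np.sqrt(e.se ** 2 + ne.se ** 2))
    ci, p = _z_ci_p(estimate, se, level)
    return MetricResult(name="NRI_overall", estimate=estimate, n=n, se=se,
                        ci=ci, p_value=p)


@dataclass(frozen=True)
class CategoryFreeNRI:
    """Event/nonevent/overall components of the continuous (category-free) NRI."""

    events: MetricResult
    nonevents: MetricResult
    overall: MetricResult
    caveat: str = CATEGORY_FREE_CAVEAT


def category_free_nri(pairs: RiskPairs, level: float = 0.95) -> CategoryFreeNRI:
    """Continuous NRI: any risk increase counts as up, any decrease as down.

    Exact ties are stayers.  The result carries a caveat because the
    category-free variant is known for high false-positive rates.
    """
    up = pairs.new > pairs.old
    down = pairs.new < pairs.old
    ev, ne = pairs.event, ~pairs.event
    up_e, down_e = int((up & ev).sum()), int((down & ev).sum())
    up_n, down_n = int((up & ne).sum()), int((down & ne).sum())
    e = _nri_component("NRIe_categoryfree", up_e, down_e, int(ev.sum()),
                       up_e, down_e, level)
    nev = _nri_component("NRIne_categoryfree", down_n, up_n, int(ne.sum()),
                         up_n, down_n, level)
    estimate = e.estimate + nev.estimate
    if e.not_available or nev.not_available:
        overall = MetricResult(name="NRI_categoryfree", estimate=estimate,
                               n=len(pairs), not_available=True,
                               note=CATEGORY_FREE_CAVEAT)
    else:
        se = float(np.sqrt(e.se ** 2 + nev.se ** 2))
        ci, p = _z_ci_p(estimate, se, level)
        overall = MetricResult(name="NRI_categoryfree", estimate=estimate,
                               n=len(pairs), se=se, ci=ci, p_value=p,
                               note=CATEGORY_FREE_CAVEAT)
    e = replace(e, note=CATEGORY_FREE_CAVEAT)
    nev = replace(nev, note=CATEGORY_FREE_CAVEAT)
    return CategoryFreeNRI(events=e, nonevents=nev, overall=overall)


def discrimination_slope(risks: Sequence[float], events: Sequence[bool]) -> float:
    """Mean predicted risk among events minus mean among nonevents."""
    risks = np.asarray(risks, dtype=float)
    events = np.asarray(events, dtype=bool)
    if risks.shape != events.shape:
        raise ValidationError("risks and events must have equal length")
    if events.all() or (~events).all():
        raise ValidationError(
            "discrimination slope needs both events and nonevents"
        )
    return float(risks[events].mean() - risks[~events].mean())


def idi(pairs: RiskPairs, level: float = 0.95) -> MetricResult:
    """Integrated discrimination improvement: slope(new) - slope(old).

    Equivalently the mean risk increase among events plus the mean risk
    decrease among nonevents.  The SE combines the standard errors of the
    per-subject risk differences within each stratum.
    """
    ev, ne = pairs.event, ~pairs.event
    if not ev.any() or not ne.any():
        raise ValidationError("IDI needs both events and nonevents")
    diff = pairs.new - pairs.old
    d_ev, d_ne = diff[ev], diff[ne]
    estimate = float(d_ev.mean() - d_ne.mean())
    sem_ev = float(d_ev.std(ddof=1) / np.sqrt(len(d_ev))) if len(d_ev) > 1 else 0.0
    sem_ne = float(d_ne.std(ddof=1) / np.sqrt(len(d_ne))) if len(d_ne) > 1 else 0.0
    se = float(np.sqrt(sem_ev ** 2 + sem_ne ** 2))
    if se == 0:
        ci, p = (estimate, estimate), (0.0 if estimate != 0 else 1.0)
    else:
        ci, p = _z_ci_p(estimate, se, level)
    return MetricResult(name="IDI", estimate=estimate, n=len(pairs), se=se,
                        ci=ci, p_value=p)


_METRIC_FUNCS: dict[str, Callable] = {
    "nri_events": lambda pairs, threshold, level: nri_events(
        build_reclass_table(pairs, threshold), level),
    "nri_nonevents": lambda pairs, threshold, level: nri_nonevents(
        build_reclass_table(pairs, threshold), level),
    "nri_overall": lambda pairs, threshold, level: nri_overall(
        build_reclass_table(pairs, threshold), level),
    "idi": lambda pairs, threshold, level: idi(pairs, level),
}


def bootstrap_ci(
    pairs: RiskPairs,
    metric: str | Callable[[RiskPairs], MetricResult],
    threshold: float | None = None,
    replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> MetricResult:
    """Percentile bootstrap CI over case/non-case stratified resamples.

    ``metric`` is one of ``nri_events``, ``nri_nonevents``, ``nri_overall``,
    ``idi`` (threshold required for the first three) or any callable mapping
    a :class:`RiskPairs` to a :class:`MetricResult`.  Deterministic given
    ``seed``.  When the metric is unavailable in more than half of the
    replicates the result is flagged ``not_available``.
    """
    if replicates < 100:
        raise ValidationError("replicates must be >= 100")
    if isinstance(metric, str):
        if metric not in _METRIC_FUNCS:
            raise ValidationError(f"unknown metric {metric!r}")
        if metric != "idi" and threshold is None:
            raise ValidationError(f"metric {metric!r} requires a threshold")
        func = lambda p: _METRIC_FUNCS[metric](p, threshold, level)  # noqa: E731
    else:
        func = metric
    point = func(pairs)
    rng = np.random.default_rng(seed)
    idx_ev = np.flatnonzero(pairs.event)
    idx_ne = np.flatnonzero(~pairs.event)
    estimates = []
    n_na = 0
    for _ in range(replicates):
        take = np.concatenate([
            rng.choice(idx_ev, size=len(idx_ev), replace=True),
            rng.choice(idx_ne, size=len(idx_ne), replace=True),
        ])
        res = func(pairs.subset(take))
        if res.not_available:
            n_na += 1
        else:
            estimates.append(res.estimate)
    if n_na > replicates / 2:
        return replace(point, not_available=True, se=None, ci=None,
                       p_value=None,
                       note=f"metric unavailable in {n_na}/{replicates} "
                            "bootstrap replicates")
    estimates = np.asarray(estimates)
    alpha = 1 - level
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    return replace(
        point,
        se=float(estimates.std(ddof=1)) if len(estimates) > 1 else 0.0,
        ci=(float(lo), float(hi)),
        note=f"percentile bootstrap, {replicates} stratified replicates",
    )


def count_reclassified(table: ReclassTable) -> tuple[int, float]:
    """Workers changing risk category (all four off-diagonal cells) and the cohort share."""
    moved = int(table.events[0, 1] + table.events[1, 0]
                + table.nonevents[0, 1] + table.nonevents[1, 0])
    total = table.n_events + table.n_nonevents
    if total == 0:
        raise ValidationError("empty reclassification table")
    return moved, moved / total
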