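"""End-to-end reclassification study orchestration.

``run_study`` reproduces the full analysis workflow on a cohort (from CSV or
the synthetic generator): complete-case filtering, established and extended
logistic model fits per outcome, Hosmer-Lemeshow calibration for both models,
reclassification tables with event/nonevent NRI at each risk threshold, the
IDI and the category-free NRI.  ``verify_printed_tables`` recomputes every
statistic derivable from the embedded published tables and compares it with
the published value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, ValidationError, complete_cases, read_cohort
from .models import (
    CalibrationResult,
    FittedRiskModel,
    ModelSpec,
    OUTCOME_DEFINITIONS,
    established_spec,
    extended_spec,
    fit_logistic,
    hosmer_lemeshow,
    odds_ratios,
    outcome_labels,
    predict_risk,
)
from .metrics import (
    CategoryFreeNRI,
    MetricResult,
    ReclassTable,
    RiskPairs,
    build_reclass_table,
    category_free_nri,
    count_reclassified,
    idi,
    nri_events,
    nri_nonevents,
    nri_overall,
)
from .simulate import GeneratorParams, default_params, generate_cohort
from .tables import PRINTED_N, PRINTED_STATS, PRINTED_TABLES, printed_table

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "ThresholdResult",
    "OutcomeResult",
    "StudyReport",
    "run_study",
    "verify_printed_tables",
    "render_report",
    "VerificationReport",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one reclassification study run."""

    cohort_csv: str | None = None
    synthetic: GeneratorParams | None = None
    outcomes: tuple[str, ...] = ("high_sa_days", "high_sa_episodes")
    thresholds: tuple[float, ...] = (0.10, 0.20)
    hl_groups: int = 10
    bootstrap_replicates: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of cohort_csv and synthetic must be given"
            )
        for o in self.outcomes:
            if o not in OUTCOME_DEFINITIONS:
                raise ValidationError(f"unknown outcome {o!r}")
        t = self.thresholds
        if not t or any(not 0 < x < 1 for x in t) or list(t) != sorted(set(t)):
            raise ValidationError(
                "thresholds must be strictly increasing probabilities in (0, 1)"
            )
        if self.hl_groups < 3:
            raise ValidationError("hl_groups must be >= 3")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if "outcome_models" in syn:
                from .simulate import OutcomeModel

                syn["outcome_models"] = tuple(
                    OutcomeModel(
                        outcome=m["outcome"],
                        terms=tuple(tuple(t) for t in m["terms"]),
                        target_prevalence=m["target_prevalence"],
                        intercept=m.get("intercept"),
                    )
                    for m in syn["outcome_models"]
                )
            for key in ("srh_probs", "prior_days_category_probs",
                        "prior_episodes_category_probs"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            d["synthetic"] = GeneratorParams(**syn)
        d["outcomes"] = tuple(d.get("outcomes", ("high_sa_days", "high_sa_episodes")))
        d["thresholds"] = tuple(d.get("thresholds", (0.10, 0.20)))
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    table: ReclassTable
    nri_events: MetricResult
    nri_nonevents: MetricResult
    nri_overall: MetricResult
    reclassified: int
    reclassified_fraction: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "table": self.table.to_dict(),
            "nri_events": self.nri_events.to_dict(),
            "nri_nonevents": self.nri_nonevents.to_dict(),
            "nri_overall": self.nri_overall.to_dict(),
            "reclassified": self.reclassified,
            "reclassified_fraction": self.reclassified_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdResult":
        return cls(
            threshold=d["threshold"],
            table=ReclassTable.from_dict(d["table"]),
            nri_events=MetricResult.from_dict(d["nri_events"]),
            nri_nonevents=MetricResult.from_dict(d["nri_nonevents"]),
            nri_overall=MetricResult.from_dict(d["nri_overall"]),
            reclassified=d["reclassified"],
            reclassified_fraction=d["reclassified_fraction"],
        )


def _or_table_dict(model: FittedRiskModel) -> list[dict]:
    return odds_ratios(model).to_dict(orient="records")


@dataclass(frozen=True)
class OutcomeResult:
    outcome: str
    n: int
    n_events: int
    failed: bool = False
    failure_reason: str = ""
    established_or: list = field(default_factory=list)
    extended_or: list = field(default_factory=list)
    hl_established: dict = field(default_factory=dict)
    hl_extended: dict = field(default_factory=dict)
    thresholds: tuple[ThresholdResult, ...] = ()
    idi: MetricResult | None = None
    category_free: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "n_events": self.n_events,
            "failed": self.failed,
            "failure_reason": self.failure_reason,
            "established_or": self.established_or,
            "extended_or": self.extended_or,
            "hl_established": self.hl_established,
            "hl_extended": self.hl_extended,
            "thresholds": [t.to_dict() for t in self.thresholds],
            "idi": self.idi.to_dict() if self.idi else None,
            "category_free": self.category_free,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeResult":
        return cls(
            outcome=d["outcome"],
            n=d["n"],
            n_events=d["n_events"],
            failed=d["failed"],
            failure_reason=d["failure_reason"],
            established_or=d["established_or"],
            extended_or=d["extended_or"],
            hl_established=d["hl_established"],
            hl_extended=d["hl_extended"],
            thresholds=tuple(ThresholdResult.from_dict(t) for t in d["thresholds"]),
            idi=MetricResult.from_dict(d["idi"]) if d["idi"] else None,
            category_free=d["category_free"],
        )


@dataclass(frozen=True)
class StudyReport:
    config_digest: str
    seed: int
    version: str
    n_input: int
    n_complete: int
    outcomes: tuple[OutcomeResult, ...]

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "config_digest": self.config_digest,
                "seed": self.seed,
                "version": self.version,
            },
            "n_input": self.n_input,
            "n_complete": self.n_complete,
            "outcomes": [o.to_dict() for o in self.outcomes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(
            config_digest=d["provenance"]["config_digest"],
            seed=d["provenance"]["seed"],
            version=d["provenance"]["version"],
            n_input=d["n_input"],
            n_complete=d["n_complete"],
            outcomes=tuple(OutcomeResult.from_dict(o) for o in d["outcomes"]),
        )


def _hl_dict(res: CalibrationResult) -> dict:
    return {"chi2": res.chi2, "df": res.df, "p_value": res.p_value}


def _analysis_fields(config: StudyConfig) -> list[str]:
    fields = {"age", "srh", "fatigue"}
    for o in config.outcomes:
        fields.add(OUTCOME_DEFINITIONS[o][0])
        fields.add({"high_sa_days": "prior_sa_days",
                    "high_sa_episodes": "prior_sa_episodes"}[o])
    order = ["age", "srh", "prior_sa_days", "prior_sa_episodes", "fatigue",
             "fu_sa_days", "fu_sa_episodes"]
    return [f for f in order if f in fields]


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full reclassification analysis described by ``config``.

    Models are fit and evaluated in-sample, as reclassification studies
    conventionally do.  A non-converged model marks its outcome as failed and
    the remaining outcomes still run.  Deterministic given the config.
    """
    if config.cohort_csv is not None:
        cohort = read_cohort(config.cohort_csv)
    else:
        cohort = generate_cohort(config.synthetic)
    logger.info("cohort loaded: n=%d", len(cohort))
    analysis = complete_cases(cohort, _analysis_fields(config))
    logger.info("complete cases: n=%d", len(analysis))

    results = []
    for outcome in config.outcomes:
        y = outcome_labels(analysis, outcome).astype(bool).to_numpy()
        try:
            est_model = fit_logistic(analysis, established_spec(outcome))
            ext_model = fit_logistic(analysis, extended_spec(outcome))
            if not (est_model.converged and ext_model.converged):
                raise ValidationError(
                    est_model.diagnostic or ext_model.diagnostic
                    or "model did not converge"
                )
        except ValidationError as exc:
            logger.warning("outcome %s failed: %s", outcome, exc)
            results.append(OutcomeResult(
                outcome=outcome, n=len(analysis), n_events=int(y.sum()),
                failed=True, failure_reason=str(exc),
            ))
            continue
        old = predict_risk(est_model, analysis).to_numpy()
        new = predict_risk(ext_model, analysis).to_numpy()
        pairs = RiskPairs(old, new, y)
        per_threshold = []
        for t in config.thresholds:
            table = build_reclass_table(pairs, t)
            moved, frac = count_reclassified(table)
            per_threshold.append(ThresholdResult(
                threshold=t,
                table=table,
                nri_events=nri_events(table),
                nri_nonevents=nri_nonevents(table),
                nri_overall=nri_overall(table),
                reclassified=moved,
                reclassified_fraction=frac,
            ))
        cf = category_free_nri(pairs)
        results.append(OutcomeResult(
            outcome=outcome,
            n=len(analysis),
            n_events=int(y.sum()),
            established_or=_or_table_dict(est_model),
            extended_or=_or_table_dict(ext_model),
            hl_established=_hl_dict(hosmer_lemeshow(old, y, config.hl_groups)),
            hl_extended=_hl_dict(hosmer_lemeshow(new, y, config.hl_groups)),
            thresholds=tuple(per_threshold),
            idi=idi(pairs),
            category_free={
                "events": cf.events.to_dict(),
                "nonevents": cf.nonevents.to_dict(),
                "overall": cf.overall.to_dict(),
                "caveat": cf.caveat,
            },
        ))
    return StudyReport(
        config_digest=config.digest(),
        seed=config.seed,
        version=__version__,
        n_input=len(cohort),
        n_complete=len(analysis),
        outcomes=tuple(results),
    )


# ---------------------------------------------------------------------------
# Verification against the published tables


@dataclass(frozen=True)
class VerificationReport:
    """Computed-vs-published comparison rows for the embedded tables."""

    rows: tuple[dict, ...]

    @property
    def n_passed(self) -> int:
        return sum(r["passed"] for r in self.rows)

    @property
    def n_point_estimates(self) -> int:
        return sum(1 for r in self.rows if r["kind"] == "point_estimate")

    @property
    def n_point_estimates_passed(self) -> int:
        return sum(r["passed"] for r in self.rows if r["kind"] == "point_estimate")

    @property
    def all_passed(self) -> bool:
        return self.n_passed == len(self.rows)

    def to_markdown(self) -> str:
        lines = [
            "| check | computed | published | pass |",
            "| --- | --- | --- | --- |",
        ]
        for r in self.rows:
            lines.append(
                f"| {r['check']} | {r['computed']} | {r['published']} | "
                f"{'yes' if r['passed'] else 'NO'} |"
            )
        lines.append(
            f"\n{self.n_passed}/{len(self.rows)} checks passed; "
            f"{self.n_point_estimates_passed}/{self.n_point_estimates} "
            "published point estimates reproduced."
        )
        return "\n".join(lines)


def verify_printed_tables() -> VerificationReport:
    """Recompute NRIe/NRIne and reclassified counts from the embedded tables.

    Point estimates must agree with the published percentages to the printed
    precision (within 0.01 of a value printed at 2 decimals); published
    p-values within one unit of their last printed digit; counts exactly.
    """
    rows: list[dict] = []

    def add(check, kind, computed, published, passed):
        rows.append({"check": check, "kind": kind, "computed": computed,
                     "published": published, "passed": bool(passed)})

    for (outcome, threshold), stats in PRINTED_STATS.items():
        table = printed_table(outcome, threshold)
        label = f"{outcome} @ {threshold:.0%}"
        e = nri_events(table)
        ne = nri_nonevents(table)
        if stats.get("nrie_pct") is None:
            add(f"NRIe {label}", "point_estimate", "n.a." if e.not_available
                else round(e.estimate_pct, 2), "n.a.", e.not_available)
        else:
            add(f"NRIe {label}", "point_estimate", round(e.estimate_pct, 2),
                stats["nrie_pct"],
                abs(e.estimate_pct - stats["nrie_pct"]) <= 0.01 + 1e-9)
            lo, hi = (float(x) for x in e.ci_pct)
            plo, phi = stats["nrie_ci_pct"]
            add(f"NRIe CI {label}", "ci", (round(lo, 2), round(hi, 2)),
                (plo, phi), abs(lo - plo) <= 0.15 and abs(hi - phi) <= 0.15)
        add(f"NRIne {label}", "point_estimate", round(ne.estimate_pct, 2),
            stats["nrine_pct"],
            abs(ne.estimate_pct - stats["nrine_pct"]) <= 0.01 + 1e-9)
        lo, hi = (float(x) for x in ne.ci_pct)
        plo, phi = stats["nrine_ci_pct"]
        add(f"NRIne CI {label}", "ci", (round(lo, 2), round(hi, 2)),
            (plo, phi), abs(lo - plo) <= 0.15 and abs(hi - phi) <= 0.15)
        for key, res in (("nrie_p", e), ("nrine_p", ne)):
            if key not in stats:
                continue
            mode, value = stats[key]
            if mode == "lt":
                ok = res.p_value < value
            else:
                ok = abs(res.p_value - value) <= 0.01 + 1e-9
            add(f"{key} {label}", "p_value", round(res.p_value, 3),
                f"{'<' if mode == 'lt' else ''}{value}", ok)
        if "reclassified" in stats:
            moved, frac = count_reclassified(table)
            add(f"reclassified {label}", "count", moved, stats["reclassified"],
                moved == stats["reclassified"])
            if "reclassified_pct" in stats:
                add(f"reclassified % {label}", "count", round(100 * frac),
                    stats["reclassified_pct"],
                    round(100 * frac) == stats["reclassified_pct"])
        n_total = table.n_events + table.n_nonevents
        add(f"cohort size {label}", "count", n_total, PRINTED_N,
            n_total == PRINTED_N)
    return VerificationReport(tuple(rows))


# ---------------------------------------------------------------------------
# Rendering


def _fmt_metric(m: MetricResult) -> str:
    if m.not_available:
        return "n.a."
    lo, hi = m.ci_pct
    return (f"{m.estimate_pct:.2f} % ({lo:.2f} to {hi:.2f} %), "
            f"p = {m.p_value:.3f}")


def _markdown(report: StudyReport) -> str:
    lines = [
        "# Reclassification study report",
        "",
        f"Input records: {report.n_input}; complete cases: {report.n_complete}.",
        "",
    ]
    for res in report.outcomes:
        lines.append(f"## Outcome: {res.outcome}")
        lines.append("")
        if res.failed:
            lines.append(f"Model fitting failed: {res.failure_reason}")
            lines.append("")
            continue
        lines.append(f"{res.n_events} of {res.n} workers had the outcome "
                     f"({100 * res.n_events / res.n:.1f} %).")
        lines.append("")
        for name, table in (("established", res.established_or),
                            ("extended (with fatigue)", res.extended_or)):
            lines.append(f"### Odds ratios, {name} model")
            lines.append("")
            lines.append("| predictor | OR | 95 % CI | p |")
            lines.append("| --- | --- | --- | --- |")
            for row in table:
                lines.append(
                    f"| {row['predictor']} | {row['or']:.2f} | "
                    f"{row['ci_low']:.2f}-{row['ci_high']:.2f} | "
                    f"{row['p']:.3f} |"
                )
            lines.append("")
        lines.append(
            f"Hosmer-Lemeshow: established chi2 = {res.hl_established['chi2']:.1f} "
            f"(df = {res.hl_established['df']}, p = {res.hl_established['p_value']:.2f}); "
            f"extended chi2 = {res.hl_extended['chi2']:.1f} "
            f"(df = {res.hl_extended['df']}, p = {res.hl_extended['p_value']:.2f})."
        )
        lines.append("")
        for tr in res.thresholds:
            lines.append(f"### Reclassification at {tr.threshold:.0%}")
            lines.append("")
            for stratum, tab in (("Events", tr.table.events),
                                 ("Nonevents", tr.table.nonevents)):
                lines.append(f"{stratum} (old category x new category):")
                lines.append("")
                lines.append(f"| | <= {tr.threshold:.0%} | > {tr.threshold:.0%} |")
                lines.append("| --- | --- | --- |")
                lines.append(f"| <= {tr.threshold:.0%} | {tab[0][0]} | {tab[0][1]} |")
                lines.append(f"| > {tr.threshold:.0%} | {tab[1][0]} | {tab[1][1]} |")
                lines.append("")
            lines.append(f"- NRIe: {_fmt_metric(tr.nri_events)}")
            lines.append(f"- NRIne: {_fmt_metric(tr.nri_nonevents)}")
            lines.append(f"- NRI overall: {_fmt_metric(tr.nri_overall)}")
            lines.append(
                f"- reclassified: {tr.reclassified} "
                f"({100 * tr.reclassified_fraction:.0f} % of {res.n})"
            )
            lines.append("")
        if res.idi is not None:
            lines.append(f"IDI: {_fmt_metric(res.idi)}")
        cf = res.category_free
        if cf:
            lines.append(
                "Category-free NRI (caveat: prone to false positives): "
                f"events {_fmt_metric(MetricResult.from_dict(cf['events']))}; "
                f"nonevents {_fmt_metric(MetricResult.from_dict(cf['nonevents']))}."
            )
        lines.append("")
    return "\n".join(lines)


def render_report(report: StudyReport, format: str = "json") -> str:
    """Render a :class:`StudyReport` as ``json`` (lossless) or ``markdown``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format == "markdown":
        return _markdown(report)
    raise ValidationError(f"unknown report format {format!r}")
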