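"""Pipeline orchestration and report rendering.

``run_pipeline`` chains the analysis stages — per-test accuracy alone and
AND-combined with GP judgement, accuracy stratified by GP judgement,
natural-frequency projections, duration summaries, and the clinician
throughput model — into a single bundle of tidy tables plus run metadata
(methods choices, seeds, per-test complete-case denominators).  Reports
never recompute: every rendered number is a module output, rounded only at
render time.  Cells that are not computable are rendered as ".".
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .accuracy import (
    AccuracyEstimate,
    BinaryCall,
    UndefinedEstimateError,
    build_confusion,
    classify_by_threshold,
    dichotomize_gp,
    sensitivity,
    specificity,
)
from .cohort import Cohort, TestFamily
from .natfreq import strategy_natural_frequencies
from .strategies import (
    Strategy,
    StrategyKind,
    Stratum,
    evaluate_strategy,
    stratified_accuracy,
)
from .workload import (
    DEFAULT_MINUTES_PER_WEEK,
    DEFAULT_POPULATION_CAP,
    StratumAccuracy,
    duration_summary,
    informant_effective_duration,
    throughput,
)

__all__ = ["RunMetadata", "ReportBundle", "run_pipeline", "write_bundle"]

NOT_COMPUTABLE = "."


@dataclass
class RunMetadata:
    """Methods provenance embedded in every report."""

    version: str
    seed: int | None
    level: float
    population: int
    ci_method: str = "clopper-pearson"
    auroc_ci_method: str = "delong"
    c95_method: str = "nearest-rank"
    throughput_weighting: str = "gp-judgement mix of stratified C95"
    rounding: str = "x100, half away from zero, at render time only"
    denominators: dict[str, int] = field(default_factory=dict)


@dataclass
class ReportBundle:
    metadata: RunMetadata
    accuracy: pd.DataFrame
    stratified: pd.DataFrame
    natural_frequencies: pd.DataFrame
    durations: pd.DataFrame
    throughput: pd.DataFrame
    bootstrap: pd.DataFrame | None = None

    def to_json(self) -> str:
        """Deterministic JSON rendering (byte-identical across reruns with
        equal inputs and seed)."""
        payload = {"metadata": asdict(self.metadata)}
        for name in (
            "accuracy",
            "stratified",
            "natural_frequencies",
            "durations",
            "throughput",
            "bootstrap",
        ):
            df = getattr(self, name)
            payload[name] = None if df is None else df.to_dict(orient="records")
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=False)


def _pct(est: AccuracyEstimate | None) -> str:
    if est is None:
        return NOT_COMPUTABLE
    p, lo, hi = est.as_percent()
    return f"{p} ({lo} to {hi})"


def _accuracy_rows(cohort: Cohort, level: float) -> pd.DataFrame:
    """One row per test: sensitivity/specificity alone and AND-combined with
    GP judgement (complete-case on the pair, so combined denominators can
    differ from test-alone denominators)."""
    rows = []
    strategies = [("GP Judgement", Strategy(StrategyKind.GP_ALONE), None)]
    for name in cohort.tests:
        strategies.append((name, Strategy(StrategyKind.SINGLE_TEST, test_a=name),
                           Strategy(StrategyKind.GP_AND_TEST, test_a=name)))
    for label, alone, combined in strategies:
        ct = evaluate_strategy(cohort, alone)

        def _try(fn, table):
            try:
                return fn(table, level)
            except UndefinedEstimateError:
                return None

        row = {
            "test": label,
            "n": ct.n,
            "sensitivity": _pct(_try(sensitivity, ct)),
            "specificity": _pct(_try(specificity, ct)),
        }
        if combined is not None:
            cct = evaluate_strategy(cohort, combined)
            row["combined_n"] = cct.n
            row["combined_sensitivity"] = _pct(_try(sensitivity, cct))
            row["combined_specificity"] = _pct(_try(specificity, cct))
        else:
            row["combined_n"] = ct.n
            row["combined_sensitivity"] = NOT_COMPUTABLE
            row["combined_specificity"] = NOT_COMPUTABLE
        rows.append(row)
    return pd.DataFrame(rows)


def _stratified_rows(cohort: Cohort, level: float) -> pd.DataFrame:
    rows = []
    for name in cohort.tests:
        for sa in stratified_accuracy(cohort, name, level):
            roc = sa.auroc
            rows.append(
                {
                    "test": name,
                    "stratum": sa.stratum.value,
                    "n": sa.n,
                    "auroc": NOT_COMPUTABLE
                    if roc is None
                    else f"{roc.auc:.4f} ({roc.ci_low:.4f} to {roc.ci_high:.4f})",
                    "ppv": _pct(sa.ppv),
                    "npv": _pct(sa.npv),
                }
            )
    return pd.DataFrame(rows)


def _natfreq_rows(cohort: Cohort, population: int, reconcile: bool) -> pd.DataFrame:
    rows = []
    strategies = [Strategy(StrategyKind.GP_ALONE)]
    for name in cohort.tests:
        strategies.append(Strategy(StrategyKind.SINGLE_TEST, test_a=name))
        strategies.append(Strategy(StrategyKind.GP_AND_TEST, test_a=name))
    for s in strategies:
        try:
            nf = strategy_natural_frequencies(cohort, s, population, reconcile)
        except ValueError:
            continue
        rows.append(
            {
                "strategy": s.label(),
                "population": nf.population,
                "tp": nf.tp,
                "fp": nf.fp,
                "tn": nf.tn,
                "fn": nf.fn,
                "n_positive_calls": nf.n_positive_calls,
            }
        )
    return pd.DataFrame(rows)


def _stratum_durations(cohort: Cohort, test: str) -> dict[str, list[float]]:
    pos, neg, overall = [], [], []
    for p in cohort.participants:
        d = p.durations_min.get(test)
        if d is None:
            continue
        overall.append(d)
        if dichotomize_gp(p.gp_judgement) is BinaryCall.POSITIVE:
            pos.append(d)
        else:
            neg.append(d)
    return {"overall": overall, "gp_dementia": pos, "gp_not_dementia": neg}


def _duration_rows(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for name in cohort.tests:
        for stratum, values in _stratum_durations(cohort, name).items():
            if not values:
                continue
            s = duration_summary(values, test=name, stratum=stratum)
            rows.append(
                {
                    "test": name,
                    "stratum": stratum,
                    "n": s.n,
                    "median_min": round(s.median_min, 2),
                    "min_min": round(s.min_min, 2),
                    "max_min": round(s.max_min, 2),
                    "c95_min": round(s.c95_min, 2),
                    "bin": s.bin.value,
                }
            )
    return pd.DataFrame(rows)


def _throughput_rows(
    cohort: Cohort,
    level: float,
    minutes_per_week: float,
    population_cap: int,
) -> pd.DataFrame:
    """Throughput per test from GP-stratified accuracy and C95, weighting
    strata by the cohort's GP-judgement mix.  Informant tests are costed at
    the fastest cognitive test's C95 within each stratum."""
    n_total = len(cohort)
    n_pos = sum(
        1 for p in cohort.participants if dichotomize_gp(p.gp_judgement) is BinaryCall.POSITIVE
    )
    gp_mix = {"gp_dementia": n_pos / n_total, "gp_not_dementia": (n_total - n_pos) / n_total}

    stratum_c95: dict[str, dict[str, float]] = {}
    for name in cohort.tests:
        per = _stratum_durations(cohort, name)
        stratum_c95[name] = {
            s: duration_summary(v, test=name, stratum=s).c95_min
            for s, v in per.items()
            if s != "overall" and v
        }
    # informant questionnaires run concurrently with clinician assessment
    cognitive = [t for t in cohort.tests.values() if t.family is TestFamily.COGNITIVE]
    for stratum in ("gp_dementia", "gp_not_dementia"):
        floor = [
            stratum_c95[t.name][stratum]
            for t in cognitive
            if stratum in stratum_c95.get(t.name, {})
        ]
        if floor:
            for t in cohort.tests.values():
                if t.family is TestFamily.INFORMANT:
                    stratum_c95.setdefault(t.name, {})[stratum] = min(floor)

    rows = []
    for name in cohort.tests:
        strata = stratum_c95.get(name, {})
        if set(strata) != {"gp_dementia", "gp_not_dementia"}:
            continue
        acc: dict[str, StratumAccuracy] = {}
        ok = True
        for sa in stratified_accuracy(cohort, name, level):
            if sa.stratum is Stratum.OVERALL:
                continue
            if sa.sensitivity is None or sa.specificity is None or sa.confusion is None:
                ok = False
                break
            prev = sa.confusion.diseased / sa.confusion.n if sa.confusion.n else 0.0
            acc[sa.stratum.value] = StratumAccuracy(
                sensitivity=sa.sensitivity.point,
                specificity=sa.specificity.point,
                prevalence=prev,
            )
        if not ok or set(acc) != set(strata):
            continue
        est = throughput(
            name, acc, strata, gp_mix,
            minutes_per_week=minutes_per_week,
            population_cap=population_cap,
        )
        rows.append(
            {
                "test": name,
                "people_assessed": est.people_assessed,
                "expected_tp": round(est.expected_tp, 1),
                "expected_fp": round(est.expected_fp, 1),
                "expected_tn": round(est.expected_tn, 1),
                "expected_fn": round(est.expected_fn, 1),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cohort: Cohort,
    level: float = 0.95,
    population: int = 1000,
    reconcile_natfreq: bool = False,
    minutes_per_week: float = DEFAULT_MINUTES_PER_WEEK,
    population_cap: int = DEFAULT_POPULATION_CAP,
    seed: int | None = None,
) -> ReportBundle:
    """Run every reporting stage on a cohort and return the bundle."""
    if len(cohort) == 0:
        raise ValueError("cannot report on an empty cohort")
    metadata = RunMetadata(
        version=__version__,
        seed=seed,
        level=level,
        population=population,
        denominators={name: cohort.complete_case_n(name) for name in cohort.tests},
    )
    return ReportBundle(
        metadata=metadata,
        accuracy=_accuracy_rows(cohort, level),
        stratified=_stratified_rows(cohort, level),
        natural_frequencies=_natfreq_rows(cohort, population, reconcile_natfreq),
        durations=_duration_rows(cohort),
        throughput=_throughput_rows(cohort, level, minutes_per_week, population_cap),
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle as tidy CSVs plus a single JSON file; returns the
    paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("accuracy", "stratified", "natural_frequencies", "durations", "throughput"):
        df = getattr(bundle, name)
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if bundle.bootstrap is not None:
        p = outdir / "bootstrap.csv"
        bundle.bootstrap.to_csv(p, index=False)
        written.append(p)
    p = outdir / "bundle.json"
    p.write_text(bundle.to_json() + "\n", encoding="utf-8")
    written.append(p)
    return written
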