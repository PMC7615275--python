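"""Test durations and the clinician-throughput model.

Tests are summarised by their 95th centile of administration time (C95, the
time within which 95% of people finish) and binned as short (< 5 min),
medium (5-10 min inclusive), or long (> 10 min).  The throughput model asks
how many people a full-time clinician (37.5 h/week of pure test
administration, a deliberate simplification) could classify in a population
of up to 1000, using accuracy and C95 stratified by GP judgement.  Informant
questionnaires run in parallel with the clinician's own assessment, so they
are costed at the fastest cognitive test's C95 rather than their own.
Indirect standardization of the potentially eligible population (age-band
list sizes x age-specific incidence) lives here too.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import TestDefinition, TestFamily

__all__ = [
    "DurationBin",
    "DurationSummary",
    "StratumAccuracy",
    "ThroughputEstimate",
    "AgeBand",
    "duration_summary",
    "classify_duration",
    "nearest_rank_c95",
    "throughput",
    "informant_effective_duration",
    "indirect_standardized_eligible",
]

DEFAULT_MINUTES_PER_WEEK = 37.5 * 60  # full-time clinician
DEFAULT_POPULATION_CAP = 1000


class DurationBin(str, enum.Enum):
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"


@dataclass(frozen=True)
class DurationSummary:
    test: str
    stratum: str
    n: int
    median_min: float
    min_min: float
    max_min: float
    c95_min: float
    bin: DurationBin


def classify_duration(c95: float) -> DurationBin:
    """Bin a test by its C95: < 5 min short, 5-10 min (inclusive) medium,
    > 10 min long."""
    if c95 < 0:
        raise ValueError("duration must be nonnegative")
    if c95 < 5:
        return DurationBin.SHORT
    if c95 <= 10:
        return DurationBin.MEDIUM
    return DurationBin.LONG


def nearest_rank_c95(durations: Sequence[float]) -> float:
    """95th centile by the nearest-rank method: element ceil(0.95 n) of the
    sorted sample."""
    xs = sorted(durations)
    if not xs:
        raise ValueError("empty duration collection")
    rank = math.ceil(0.95 * len(xs))
    return xs[rank - 1]


def duration_summary(
    durations: Sequence[float], test: str = "", stratum: str = "overall"
) -> DurationSummary:
    """Median, range, nearest-rank C95 and duration bin for one test."""
    xs = [float(d) for d in durations]
    if not xs:
        raise ValueError("empty duration collection")
    if any(d < 0 for d in xs):
        raise ValueError("durations must be nonnegative")
    c95 = nearest_rank_c95(xs)
    return DurationSummary(
        test=test,
        stratum=stratum,
        n=len(xs),
        median_min=float(np.median(xs)),
        min_min=min(xs),
        max_min=max(xs),
        c95_min=c95,
        bin=classify_duration(c95),
    )


@dataclass(frozen=True)
class StratumAccuracy:
    """Sensitivity, specificity and dementia prevalence within one
    GP-judgement stratum, as inputs to the throughput model."""

    sensitivity: float
    specificity: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "prevalence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ThroughputEstimate:
    test: str
    minutes_per_week: float
    people_assessed: int
    expected_tp: float
    expected_fp: float
    expected_tn: float
    expected_fn: float

    @property
    def expected_correct(self) -> float:
        return self.expected_tp + self.expected_tn


def throughput(
    test: str,
    per_stratum_accuracy: Mapping[str, StratumAccuracy],
    per_stratum_c95: Mapping[str, float],
    gp_mix: Mapping[str, float],
    minutes_per_week: float = DEFAULT_MINUTES_PER_WEEK,
    population_cap: int = DEFAULT_POPULATION_CAP,
) -> ThroughputEstimate:
    """People assessed per week and their expected classification.

    The weekly capacity is ``minutes_per_week`` divided by the C95 averaged
    over the GP-judgement mix (durations are longer in people GPs suspect of
    dementia), capped at ``population_cap``.  Expected confusion cells follow
    by total probability from each stratum's sensitivity, specificity and
    prevalence applied to the assessed mix; the cells sum to the number
    assessed.
    """
    if set(per_stratum_accuracy) != set(per_stratum_c95) or set(gp_mix) != set(per_stratum_c95):
        raise ValueError("strata of accuracy, c95 and mix inputs must agree")
    if abs(sum(gp_mix.values()) - 1.0) > 1e-9:
        raise ValueError("gp_mix must sum to 1")
    for s, c in per_stratum_c95.items():
        if not c > 0:
            raise ValueError(f"stratum {s!r}: c95 must be positive")
    weighted_c95 = sum(gp_mix[s] * per_stratum_c95[s] for s in gp_mix)
    people = min(population_cap, math.floor(minutes_per_week / weighted_c95))
    tp = fp = tn = fn = 0.0
    for s, w in gp_mix.items():
        acc = per_stratum_accuracy[s]
        n_s = people * w
        tp += n_s * acc.prevalence * acc.sensitivity
        fn += n_s * acc.prevalence * (1 - acc.sensitivity)
        tn += n_s * (1 - acc.prevalence) * acc.specificity
        fp += n_s * (1 - acc.prevalence) * (1 - acc.specificity)
    return ThroughputEstimate(
        test=test,
        minutes_per_week=minutes_per_week,
        people_assessed=people,
        expected_tp=tp,
        expected_fp=fp,
        expected_tn=tn,
        expected_fn=fn,
    )


def informant_effective_duration(
    tests: Iterable[TestDefinition],
    summaries: Mapping[str, DurationSummary],
) -> dict[str, float]:
    """Effective C95 for informant questionnaires: the minimum C95 among
    cognitive-family tests, since the informant answers while the clinician
    assesses the patient."""
    tests = list(tests)
    cognitive_c95 = [
        summaries[t.name].c95_min
        for t in tests
        if t.family is TestFamily.COGNITIVE and t.name in summaries
    ]
    if not cognitive_c95:
        raise ValueError("no cognitive-family test with a duration summary")
    floor_c95 = min(cognitive_c95)
    return {t.name: floor_c95 for t in tests if t.family is TestFamily.INFORMANT}


@dataclass(frozen=True)
class AgeBand:
    """One age band of the practice population: list size and the external
    age-specific dementia incidence rate (events per person-year)."""

    age_band: str
    list_size: float
    incidence_rate: float

    def __post_init__(self) -> None:
        if self.list_size < 0 or self.incidence_rate < 0:
            raise ValueError("list sizes and rates must be nonnegative")


def indirect_standardized_eligible(
    bands: Sequence[AgeBand], scale: float = 1.0
) -> float:
    """Expected eligible count by indirect standardization: sum over age
    bands of list size x incidence rate x person-time scale (e.g. the
    recruitment window in years)."""
    if not bands:
        raise ValueError("at least one age band required")
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    return float(sum(b.list_size * b.incidence_rate * scale for b in bands))
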