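"""Natural-frequency projection of strategy accuracy.

Accuracy results are re-expressed as integer counts in a hypothetical
population (1000 people by default, with the study's prevalence): how many
of the 1000 test positive, and how many of those positives are correct.
Communicating accuracy as counts of people rather than conditional
probabilities is the standard natural-frequency format for shared
decision-making.

Each confusion cell is projected independently by rounding half away from
zero, which can make the four cells sum to slightly more or less than the
population; an optional largest-remainder reconciliation restores an exact
sum when tidy totals matter more than cell-wise fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .accuracy import ConfusionTable
from .cohort import Cohort
from .strategies import Strategy, evaluate_strategy

__all__ = [
    "NaturalFrequencyResult",
    "project_count",
    "project_confusion",
    "strategy_natural_frequencies",
]


@dataclass(frozen=True)
class NaturalFrequencyResult:
    """Confusion counts projected onto a hypothetical population."""

    population: int
    tp: int
    fp: int
    tn: int
    fn: int
    source_n: int
    reconciled: bool = False

    @property
    def n_positive_calls(self) -> int:
        return self.tp + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def project_count(numerator: int, denominator: int, population: int) -> int:
    """Project ``numerator/denominator`` onto ``population`` people, rounding
    to the nearest integer with ties half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    x = numerator / denominator * population
    return int(math.floor(x + 0.5))


def _largest_remainder(raw: list[float], population: int) -> list[int]:
    floors = [math.floor(x) for x in raw]
    short = population - sum(floors)
    # distribute the shortfall to the largest fractional parts
    order = sorted(range(len(raw)), key=lambda i: raw[i] - floors[i], reverse=True)
    out = list(floors)
    for i in order[: max(short, 0)]:
        out[i] += 1
    return out


def project_confusion(
    ct: ConfusionTable, population: int = 1000, reconcile: bool = False
) -> NaturalFrequencyResult:
    """Project the four confusion cells onto a population.

    With ``reconcile=True`` the cells are adjusted by the largest-remainder
    rule so they sum exactly to the population; the default keeps each cell's
    independently rounded value.
    """
    n = ct.n
    if n == 0:
        raise ValueError("confusion table has no classified participants")
    if reconcile:
        raw = [c / n * population for c in (ct.tp, ct.fp, ct.tn, ct.fn)]
        tp, fp, tn, fn = _largest_remainder(raw, population)
    else:
        tp, fp, tn, fn = (project_count(c, n, population) for c in (ct.tp, ct.fp, ct.tn, ct.fn))
    return NaturalFrequencyResult(
        population=population,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        source_n=n,
        reconciled=reconcile,
    )


def strategy_natural_frequencies(
    cohort: Cohort,
    strategy: Strategy,
    population: int = 1000,
    reconcile: bool = False,
) -> NaturalFrequencyResult:
    """Evaluate a strategy on the cohort and project its confusion cells onto
    the hypothetical population, using the strategy's complete-case n as the
    denominator."""
    ct = evaluate_strategy(cohort, strategy)
    return project_confusion(ct, population=population, reconcile=reconcile)
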