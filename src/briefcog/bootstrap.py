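"""Bootstrap comparison of misclassification between testing strategies.

Resamples whole participants with replacement to the original cohort size
(simple case resampling, preserving the joint structure of reference
category, GP judgement, and test scores), evaluates two strategies on every
replicate, and summarises the per-replicate differences in false positives,
false negatives, and total misclassifications with percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accuracy import BinaryCall
from .cohort import Cohort
from .strategies import Strategy, strategy_call

__all__ = ["BootstrapComparison", "bootstrap_misclassification"]

_POS, _NEG, _MISS = 1, 0, -1


@dataclass
class DiffSummary:
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class BootstrapComparison:
    """Per-replicate misclassification differences (strategy_a - strategy_b)
    and their percentile summaries."""

    strategy_a: str
    strategy_b: str
    n_replicates: int
    seed: int
    per_replicate_diffs: np.ndarray  # shape (reps, 3): diff_fp, diff_fn, diff_total
    n_missing_replicates: int
    summary: dict[str, DiffSummary] = field(default_factory=dict)

    def plug_in_diff(self) -> tuple[int, int, int] | None:
        return getattr(self, "_plug_in", None)


def _encode_calls(cohort: Cohort, strategy: Strategy) -> np.ndarray:
    codes = np.empty(len(cohort), dtype=np.int8)
    for i, p in enumerate(cohort.participants):
        call = strategy_call(p, strategy, cohort.tests)
        codes[i] = _POS if call is BinaryCall.POSITIVE else _NEG if call is BinaryCall.NEGATIVE else _MISS
    return codes


def _misclass(codes: np.ndarray, diseased: np.ndarray) -> tuple[int, int] | None:
    observed = codes != _MISS
    if not observed.any():
        return None
    fp = int(np.sum((codes == _POS) & ~diseased))
    fn = int(np.sum((codes == _NEG) & diseased))
    return fp, fn


def bootstrap_misclassification(
    cohort: Cohort,
    strategy_a: Strategy,
    strategy_b: Strategy,
    n_replicates: int = 1000,
    seed: int = 0,
) -> BootstrapComparison:
    """Compare two strategies' misclassification counts over bootstrap
    replicates of the cohort.

    Both strategies are evaluated on the same replicate, so the differences
    respect the pairing induced by shared participants.  Deterministic given
    ``seed``.  A replicate on which a strategy has no observed calls is
    recorded as missing and excluded from the summaries; more than 10%
    missing replicates triggers a warning.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if len(cohort) == 0:
        raise ValueError("cannot bootstrap an empty cohort")
    from .accuracy import dichotomize_reference

    diseased = np.array(
        [dichotomize_reference(p.reference) is BinaryCall.POSITIVE for p in cohort.participants]
    )
    codes_a = _encode_calls(cohort, strategy_a)
    codes_b = _encode_calls(cohort, strategy_b)

    n = len(cohort)
    rng = np.random.default_rng(seed)
    diffs = np.empty((n_replicates, 3), dtype=float)
    n_missing = 0
    kept = []
    for r in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        ma = _misclass(codes_a[idx], diseased[idx])
        mb = _misclass(codes_b[idx], diseased[idx])
        if ma is None or mb is None:
            n_missing += 1
            diffs[r] = np.nan
            continue
        d_fp = ma[0] - mb[0]
        d_fn = ma[1] - mb[1]
        diffs[r] = (d_fp, d_fn, d_fp + d_fn)
        kept.append(r)

    if n_missing > 0.1 * n_replicates:
        import warnings

        warnings.warn(
            f"{n_missing}/{n_replicates} bootstrap replicates had no observed "
            "calls for a strategy and were excluded",
            stacklevel=2,
        )

    result = BootstrapComparison(
        strategy_a=strategy_a.label(),
        strategy_b=strategy_b.label(),
        n_replicates=n_replicates,
        seed=seed,
        per_replicate_diffs=diffs,
        n_missing_replicates=n_missing,
    )
    valid = diffs[kept] if kept else np.empty((0, 3))
    for j, name in enumerate(("diff_fp", "diff_fn", "diff_total")):
        if len(valid):
            col = valid[:, j]
            result.summary[name] = DiffSummary(
                mean=float(col.mean()),
                ci_low=float(np.percentile(col, 2.5)),
                ci_high=float(np.percentile(col, 97.5)),
            )
    ma0 = _misclass(codes_a, diseased)
    mb0 = _misclass(codes_b, diseased)
    if ma0 is not None and mb0 is not None:
        result._plug_in = (
            ma0[0] - mb0[0],
            ma0[1] - mb0[1],
            (ma0[0] + ma0[1]) - (mb0[0] + mb0[1]),
        )
    return result
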