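"""Dichotomization, confusion tables, and accuracy statistics.

Accuracy for dementia is always computed against the dichotomized reference
standard: dementia is the target condition, and CIND (cognitive impairment,
not dementia) is grouped with "normal" as non-diseased.  All binomial
proportions carry exact Clopper-Pearson confidence intervals, obtained by
inverting the binomial tail probabilities; likelihood-ratio intervals use the
standard log method; AUROC is the Mann-Whitney estimator with half-credit for
ties and a DeLong (tie-adjusted) variance for its interval.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, CognitiveCategory, Participant, PositiveDirection, TestDefinition

__all__ = [
    "BinaryCall",
    "ConfusionTable",
    "AccuracyEstimate",
    "LikelihoodRatioEstimate",
    "AurocEstimate",
    "UndefinedEstimateError",
    "dichotomize_reference",
    "dichotomize_gp",
    "classify_by_threshold",
    "build_confusion",
    "clopper_pearson",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "likelihood_ratios",
    "auroc",
    "auroc_for_test",
]


class UndefinedEstimateError(ValueError):
    """An accuracy statistic is not computable (zero denominator or a
    single-class stratum); carries which metric failed."""

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} undefined: {reason}")


class BinaryCall(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary classifier against the dichotomized reference.

    ``n_missing`` records participants excluded because the classifier's call
    was missing; it does not take part in equality comparisons.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "n_missing"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def nondiseased(self) -> int:
        return self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp

    @property
    def negatives(self) -> int:
        return self.tn + self.fn

    @property
    def misclassified(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class AccuracyEstimate:
    """A binomial proportion with its exact two-sided confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not (0 <= self.ci_low <= self.point <= self.ci_high <= 1):
            raise ValueError("interval must satisfy 0 <= low <= point <= high <= 1")

    def as_percent(self) -> tuple[int, int, int]:
        """(point, low, high) on the 0-100 scale, rounded half away from zero."""
        return tuple(_round_half_away(100 * v) for v in (self.point, self.ci_low, self.ci_high))


@dataclass(frozen=True)
class LikelihoodRatioEstimate:
    """LR+ or LR- with a log-method interval.

    ``value`` is ``inf`` when the defining denominator is zero (e.g. LR+ with
    no false positives); ``finite`` flags that case.
    """

    value: float
    ci_low: float
    ci_high: float
    finite: bool
    level: float = 0.95


@dataclass(frozen=True)
class AurocEstimate:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError("AUROC interval must satisfy 0 <= low <= auc <= high <= 1")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def dichotomize_reference(category: CognitiveCategory) -> BinaryCall:
    """Dementia is the target condition; CIND and normal are non-diseased."""
    category = CognitiveCategory(category)
    return BinaryCall.POSITIVE if category is CognitiveCategory.DEMENTIA else BinaryCall.NEGATIVE


def dichotomize_gp(judgement: CognitiveCategory) -> BinaryCall:
    """GP judgement as a binary index test: only a 'dementia' call is positive."""
    judgement = CognitiveCategory(judgement)
    return BinaryCall.POSITIVE if judgement is CognitiveCategory.DEMENTIA else BinaryCall.NEGATIVE


def classify_by_threshold(score: float | None, definition: TestDefinition) -> BinaryCall:
    """Dichotomize a test score per the definition's threshold and direction.

    Boundary inclusion is exactly what the direction states; a missing score
    yields a missing call.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return BinaryCall.MISSING
    t = definition.threshold
    d = definition.positive_direction
    if d is PositiveDirection.BELOW:
        positive = score < t
    elif d is PositiveDirection.AT_OR_BELOW:
        positive = score <= t
    elif d is PositiveDirection.ABOVE:
        positive = score > t
    else:  # AT_OR_ABOVE
        positive = score >= t
    return BinaryCall.POSITIVE if positive else BinaryCall.NEGATIVE


def build_confusion(
    cohort: Cohort | Iterable[Participant],
    caller: Callable[[Participant], BinaryCall],
) -> ConfusionTable:
    """Cross-tabulate a classifier's calls against the dichotomized reference.

    Participants whose call is missing are excluded from all four cells and
    counted in ``n_missing``.
    """
    participants = list(cohort)
    if not participants:
        raise ValueError("cannot build a confusion table from an empty cohort")
    tp = fp = fn = tn = miss = 0
    for p in participants:
        call = caller(p)
        if call is BinaryCall.MISSING:
            miss += 1
            continue
        diseased = dichotomize_reference(p.reference) is BinaryCall.POSITIVE
        if call is BinaryCall.POSITIVE:
            tp += diseased
            fp += not diseased
        else:
            fn += diseased
            tn += not diseased
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn, n_missing=miss)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    The bounds invert the binomial tail probabilities; the lower bound is
    exactly 0 when ``successes == 0`` and the upper exactly 1 when
    ``successes == trials``.
    """
    if trials < 1:
        raise UndefinedEstimateError("proportion", "zero trials")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the degenerate edges in some versions
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == trials else float(hi)
    return lo, hi


def _proportion(numerator: int, denominator: int, metric: str, level: float) -> AccuracyEstimate:
    if denominator == 0:
        raise UndefinedEstimateError(metric, "zero denominator")
    lo, hi = clopper_pearson(numerator, denominator, level)
    return AccuracyEstimate(
        point=numerator / denominator,
        ci_low=lo,
        ci_high=hi,
        numerator=numerator,
        denominator=denominator,
        level=level,
    )


def sensitivity(ct: ConfusionTable, level: float = 0.95) -> AccuracyEstimate:
    return _proportion(ct.tp, ct.tp + ct.fn, "sensitivity", level)


def specificity(ct: ConfusionTable, level: float = 0.95) -> AccuracyEstimate:
    return _proportion(ct.tn, ct.tn + ct.fp, "specificity", level)


def ppv(ct: ConfusionTable, level: float = 0.95) -> AccuracyEstimate:
    return _proportion(ct.tp, ct.tp + ct.fp, "ppv", level)


def npv(ct: ConfusionTable, level: float = 0.95) -> AccuracyEstimate:
    return _proportion(ct.tn, ct.tn + ct.fn, "npv", level)


def likelihood_ratios(
    ct: ConfusionTable, level: float = 0.95
) -> tuple[LikelihoodRatioEstimate, LikelihoodRatioEstimate]:
    """(LR+, LR-) with log-method confidence intervals.

    LR+ = sens / (1 - spec); LR- = (1 - sens) / spec.  A zero denominator
    yields an estimate flagged non-finite rather than an exception, mirroring
    how such cells are reported as not computable.
    """
    if ct.diseased == 0 or ct.nondiseased == 0:
        raise UndefinedEstimateError("likelihood_ratio", "single-class table")
    z = stats.norm.ppf(0.5 + level / 2)

    def _lr(num: int, n_num: int, den: int, n_den: int) -> LikelihoodRatioEstimate:
        # ratio of two proportions num/n_num over den/n_den, log-method CI
        if den == 0:
            return LikelihoodRatioEstimate(math.inf, math.nan, math.nan, finite=False, level=level)
        if num == 0:
            return LikelihoodRatioEstimate(0.0, math.nan, math.nan, finite=False, level=level)
        value = (num / n_num) / (den / n_den)
        se_log = math.sqrt(1 / num - 1 / n_num + 1 / den - 1 / n_den)
        return LikelihoodRatioEstimate(
            value,
            value * math.exp(-z * se_log),
            value * math.exp(z * se_log),
            finite=True,
            level=level,
        )

    lr_pos = _lr(ct.tp, ct.diseased, ct.fp, ct.nondiseased)
    lr_neg = _lr(ct.fn, ct.diseased, ct.tn, ct.nondiseased)
    return lr_pos, lr_neg


def _oriented(scores: np.ndarray, orientation: PositiveDirection) -> np.ndarray:
    """Flip scores so that larger oriented score = more disease-like."""
    orientation = PositiveDirection(orientation)
    return -scores if orientation.lower_is_positive else scores


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the Mann-Whitney AUROC, tie-adjusted via midranks."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = _midrank(all_scores)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    # structural components: V10 over positives, V01 over negatives
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auroc(
    scores: Sequence[float],
    labels: Sequence[int] | Sequence[bool],
    orientation: PositiveDirection = PositiveDirection.AT_OR_ABOVE,
    level: float = 0.95,
) -> AurocEstimate:
    """Mann-Whitney AUROC with half-credit for ties and a DeLong interval.

    ``orientation`` states which direction of the raw score is disease-like;
    scores are flipped internally so that larger = more disease-like.
    Missing (NaN) scores are excluded pairwise with their labels.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    x = _oriented(x, orientation)
    pos, neg = x[y], x[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise UndefinedEstimateError("auroc", "needs at least one positive and one negative")
    ranks = _midrank(np.concatenate([pos, neg]))
    auc = (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    var = _delong_variance(pos, neg, auc)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return AurocEstimate(
        auc=float(auc),
        ci_low=float(np.clip(auc - half, 0.0, min(auc, 1.0))),
        ci_high=float(np.clip(auc + half, max(auc, 0.0), 1.0)),
        n_pos=m,
        n_neg=n,
        level=level,
    )


def auroc_for_test(
    cohort: Cohort | Iterable[Participant],
    definition: TestDefinition,
    level: float = 0.95,
) -> AurocEstimate:
    """AUROC of one index test's scores against the dichotomized reference."""
    scores, labels = [], []
    for p in cohort:
        s = p.scores.get(definition.name)
        if s is None:
            continue
        scores.append(s)
        labels.append(dichotomize_reference(p.reference) is BinaryCall.POSITIVE)
    if not scores:
        raise UndefinedEstimateError("auroc", f"no observed scores for {definition.name}")
    return auroc(scores, labels, orientation=definition.positive_direction, level=level)
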