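"""Testing strategies: single tests, AND-combination with GP judgement, and
GP-routed sequential testing.

A strategy maps each participant to a binary dementia classification.  The
AND-combination is positive only when both GP judgement and the index test
are positive, which raises specificity at the cost of sensitivity on a common
denominator.  The sequential strategy lets the GP's judgement route each
patient to one of two confirmatory tests; accuracy can then be examined
within the two judgement strata, where the differing prevalence of dementia
reshapes the predictive values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from .accuracy import (
    AccuracyEstimate,
    AurocEstimate,
    BinaryCall,
    ConfusionTable,
    UndefinedEstimateError,
    auroc_for_test,
    build_confusion,
    classify_by_threshold,
    dichotomize_gp,
    npv,
    ppv,
    sensitivity,
    specificity,
)
from .cohort import Cohort, Participant, TestDefinition

__all__ = [
    "StrategyKind",
    "Strategy",
    "Stratum",
    "StratifiedAccuracy",
    "combine_with_gp",
    "strategy_call",
    "classify_sequential",
    "evaluate_strategy",
    "stratified_accuracy",
    "rank_tests_by_correct",
    "parse_strategy",
]


class StrategyKind(str, enum.Enum):
    SINGLE_TEST = "single_test"
    GP_ALONE = "gp_alone"
    GP_AND_TEST = "gp_and_test"
    GP_ROUTED_SEQUENTIAL = "gp_routed_sequential"


@dataclass(frozen=True)
class Strategy:
    """A rule mapping a participant to a binary dementia classification.

    ``test_a`` is the single test, the test AND-combined with GP judgement,
    or (for the sequential kind) the test applied when the GP judges
    dementia; ``test_b`` is the test applied when the GP judges not-dementia
    and is only meaningful for the sequential kind.
    """

    kind: StrategyKind
    test_a: str | None = None
    test_b: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", StrategyKind(self.kind))
        k = self.kind
        if k is StrategyKind.GP_ALONE:
            if self.test_a or self.test_b:
                raise ValueError("gp_alone takes no tests")
        elif k is StrategyKind.GP_ROUTED_SEQUENTIAL:
            if not (self.test_a and self.test_b):
                raise ValueError("gp_routed_sequential requires test_a and test_b")
        else:
            if not self.test_a or self.test_b:
                raise ValueError(f"{k.value} requires exactly test_a")

    def label(self) -> str:
        if self.kind is StrategyKind.GP_ALONE:
            return "gp-alone"
        if self.kind is StrategyKind.SINGLE_TEST:
            return self.test_a  # type: ignore[return-value]
        if self.kind is StrategyKind.GP_AND_TEST:
            return f"gp+{self.test_a}"
        return f"seq:{self.test_a}/{self.test_b}"


def parse_strategy(text: str) -> Strategy:
    """Parse the CLI strategy syntax.

    ``gp-alone`` | ``TEST`` | ``gp+TEST`` | ``seq:TEST_A/TEST_B``.
    """
    text = text.strip()
    if text == "gp-alone":
        return Strategy(StrategyKind.GP_ALONE)
    if text.startswith("seq:"):
        body = text[4:]
        if "/" not in body:
            raise ValueError(f"sequential strategy needs seq:TEST_A/TEST_B, got {text!r}")
        a, b = body.split("/", 1)
        return Strategy(StrategyKind.GP_ROUTED_SEQUENTIAL, test_a=a, test_b=b)
    if text.startswith("gp+"):
        return Strategy(StrategyKind.GP_AND_TEST, test_a=text[3:])
    return Strategy(StrategyKind.SINGLE_TEST, test_a=text)


def combine_with_gp(gp: BinaryCall, test: BinaryCall) -> BinaryCall:
    """AND-rule: positive only when both GP judgement and test are positive.

    A missing test call makes the combined call missing; GP judgement is
    always observed.
    """
    if gp is BinaryCall.MISSING:
        raise ValueError("GP judgement call cannot be missing")
    if test is BinaryCall.MISSING:
        return BinaryCall.MISSING
    both_pos = gp is BinaryCall.POSITIVE and test is BinaryCall.POSITIVE
    return BinaryCall.POSITIVE if both_pos else BinaryCall.NEGATIVE


def classify_sequential(
    participant: Participant,
    strategy: Strategy,
    definitions: Mapping[str, TestDefinition],
) -> BinaryCall:
    """GP-routed two-test rule: GP-dementia patients get ``test_a``, everyone
    else gets ``test_b``; the routed test's call is final."""
    if strategy.kind is not StrategyKind.GP_ROUTED_SEQUENTIAL:
        raise ValueError("classify_sequential requires a gp_routed_sequential strategy")
    routed = (
        strategy.test_a
        if dichotomize_gp(participant.gp_judgement) is BinaryCall.POSITIVE
        else strategy.test_b
    )
    return classify_by_threshold(participant.scores.get(routed), definitions[routed])


def strategy_call(
    participant: Participant,
    strategy: Strategy,
    definitions: Mapping[str, TestDefinition],
) -> BinaryCall:
    """The strategy's binary classification of one participant."""
    k = strategy.kind
    if k is StrategyKind.GP_ALONE:
        return dichotomize_gp(participant.gp_judgement)
    if k is StrategyKind.SINGLE_TEST:
        d = definitions[strategy.test_a]
        return classify_by_threshold(participant.scores.get(strategy.test_a), d)
    if k is StrategyKind.GP_AND_TEST:
        d = definitions[strategy.test_a]
        return combine_with_gp(
            dichotomize_gp(participant.gp_judgement),
            classify_by_threshold(participant.scores.get(strategy.test_a), d),
        )
    return classify_sequential(participant, strategy, definitions)


def evaluate_strategy(cohort: Cohort, strategy: Strategy) -> ConfusionTable:
    """Confusion table of the strategy's calls against the dichotomized
    reference, complete-case on the strategy's own calls."""
    for t in (strategy.test_a, strategy.test_b):
        if t is not None and t not in cohort.tests:
            raise KeyError(f"strategy references undefined test {t!r}")
    return build_confusion(cohort, lambda p: strategy_call(p, strategy, cohort.tests))


class Stratum(str, enum.Enum):
    OVERALL = "overall"
    GP_DEMENTIA = "gp_dementia"
    GP_NOT_DEMENTIA = "gp_not_dementia"


@dataclass
class StratifiedAccuracy:
    """One test's accuracy within a GP-judgement stratum.

    Metrics that are not computable in the stratum (zero denominator or a
    single reference class) are ``None`` and rendered as "." in reports.
    """

    test: str
    stratum: Stratum
    n: int
    confusion: ConfusionTable | None
    sensitivity: AccuracyEstimate | None
    specificity: AccuracyEstimate | None
    ppv: AccuracyEstimate | None
    npv: AccuracyEstimate | None
    auroc: AurocEstimate | None


def _stratum_members(cohort: Cohort, stratum: Stratum) -> list[Participant]:
    if stratum is Stratum.OVERALL:
        return list(cohort.participants)
    want_positive = stratum is Stratum.GP_DEMENTIA
    return [
        p
        for p in cohort.participants
        if (dichotomize_gp(p.gp_judgement) is BinaryCall.POSITIVE) == want_positive
    ]


def stratified_accuracy(
    cohort: Cohort, test: str, level: float = 0.95
) -> list[StratifiedAccuracy]:
    """Accuracy of a single test overall and within the two GP-judgement
    strata (GP dementia vs GP not-dementia).

    Stratification is always on the dichotomized judgement.  Within-stratum
    PPV/NPV reflect the stratum prevalence, which is why restricting to
    GP-dementia patients raises PPV.
    """
    if test not in cohort.tests:
        raise KeyError(f"undefined test {test!r}")
    definition = cohort.tests[test]
    out: list[StratifiedAccuracy] = []
    for stratum in (Stratum.OVERALL, Stratum.GP_DEMENTIA, Stratum.GP_NOT_DEMENTIA):
        members = _stratum_members(cohort, stratum)
        if not members:
            out.append(
                StratifiedAccuracy(test, stratum, 0, None, None, None, None, None, None)
            )
            continue
        ct = build_confusion(
            members, lambda p: classify_by_threshold(p.scores.get(test), definition)
        )

        def _try(fn, ct=ct):
            try:
                return fn(ct, level)
            except UndefinedEstimateError:
                return None

        try:
            roc = auroc_for_test(members, definition, level)
        except UndefinedEstimateError:
            roc = None
        out.append(
            StratifiedAccuracy(
                test=test,
                stratum=stratum,
                n=len(members),
                confusion=ct,
                sensitivity=_try(sensitivity),
                specificity=_try(specificity),
                ppv=_try(ppv),
                npv=_try(npv),
                auroc=roc,
            )
        )
    return out


def rank_tests_by_correct(
    cohort: Cohort,
    stratum: Stratum = Stratum.OVERALL,
    top: int | None = 3,
) -> list[tuple[str, int]]:
    """Rank tests by true positives + true negatives within a stratum.

    The selection rule used to pick candidate tests for the bootstrap
    comparison; ties break alphabetically for determinism.
    """
    members = _stratum_members(cohort, stratum)
    ranked: list[tuple[str, int]] = []
    for name, definition in cohort.tests.items():
        try:
            ct = build_confusion(
                members, lambda p: classify_by_threshold(p.scores.get(name), definition)
            )
        except ValueError:
            continue
        ranked.append((name, ct.tp + ct.tn))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top] if top is not None else ranked
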