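"""AND-combination, GP stratification, and sequential routing."""

import numpy as np
import pytest

from briefcog import (
    BinaryCall,
    CognitiveCategory,
    Cohort,
    ConfusionTable,
    Strategy,
    StrategyKind,
    Stratum,
    classify_by_threshold,
    classify_sequential,
    combine_with_gp,
    dichotomize_gp,
    evaluate_strategy,
    parse_strategy,
    sensitivity,
    specificity,
    strategy_call,
    stratified_accuracy,
)
from briefcog.strategies import rank_tests_by_correct

from conftest import ALPHA, BETA, make_participant


@pytest.mark.parametrize(
    "gp, test, expected",
    [
        (BinaryCall.POSITIVE, BinaryCall.POSITIVE, BinaryCall.POSITIVE),
        (BinaryCall.POSITIVE, BinaryCall.NEGATIVE, BinaryCall.NEGATIVE),
        (BinaryCall.NEGATIVE, BinaryCall.POSITIVE, BinaryCall.NEGATIVE),
        (BinaryCall.NEGATIVE, BinaryCall.NEGATIVE, BinaryCall.NEGATIVE),
        (BinaryCall.POSITIVE, BinaryCall.MISSING, BinaryCall.MISSING),
    ],
)
def test_and_rule(gp, test, expected):
    assert combine_with_gp(gp, test) is expected


def test_and_rule_rejects_missing_gp():
    with pytest.raises(ValueError):
        combine_with_gp(BinaryCall.MISSING, BinaryCall.POSITIVE)


class TestSequentialRouting:
    SEQ = Strategy(StrategyKind.GP_ROUTED_SEQUENTIAL, test_a="alpha", test_b="beta")

    def test_gp_dementia_routes_to_test_a(self, toy_cohort):
        p = make_participant(90, "dementia", "dementia", {"alpha": 9, "beta": 100})
        # alpha (>=5) positive; beta would be negative but is never consulted
        assert classify_sequential(p, self.SEQ, toy_cohort.tests) is BinaryCall.POSITIVE

    def test_gp_cind_routes_to_test_b(self, toy_cohort):
        p = make_participant(91, "dementia", "cind", {"alpha": 9, "beta": 100})
        assert classify_sequential(p, self.SEQ, toy_cohort.tests) is BinaryCall.NEGATIVE

    def test_routed_missing_score_gives_missing(self, toy_cohort):
        p = make_participant(92, "cind", "normal", {"alpha": 9})
        assert classify_sequential(p, self.SEQ, toy_cohort.tests) is BinaryCall.MISSING

    def test_toy_cohort_matches_routing_enumeration(self, toy_cohort):
        for p in toy_cohort:
            routed = "alpha" if p.gp_judgement is CognitiveCategory.DEMENTIA else "beta"
            expected = classify_by_threshold(p.scores.get(routed), toy_cohort.tests[routed])
            assert classify_sequential(p, self.SEQ, toy_cohort.tests) is expected

    def test_same_test_both_arms_equals_single_test(self, toy_cohort):
        seq = Strategy(StrategyKind.GP_ROUTED_SEQUENTIAL, test_a="alpha", test_b="alpha")
        single = Strategy(StrategyKind.SINGLE_TEST, test_a="alpha")
        for p in toy_cohort:
            assert strategy_call(p, seq, toy_cohort.tests) is strategy_call(
                p, single, toy_cohort.tests
            )


class TestEvaluateStrategy:
    def test_gp_alone_reproduces_study_table(self, table1_cohort):
        ct = evaluate_strategy(table1_cohort, Strategy(StrategyKind.GP_ALONE))
        assert ct == ConfusionTable(74, 12, 58, 96)

    def test_perfect_single_test(self):
        parts = [
            make_participant(i, ref, "cind", {"alpha": 9 if ref == "dementia" else 1})
            for i, ref in enumerate(["dementia", "dementia", "cind", "normal"])
        ]
        cohort = Cohort(parts, [ALPHA])
        ct = evaluate_strategy(cohort, Strategy(StrategyKind.SINGLE_TEST, test_a="alpha"))
        assert ct.fp == 0 and ct.fn == 0

    def test_sequential_on_toy_matches_manual_count(self, toy_cohort):
        seq = Strategy(StrategyKind.GP_ROUTED_SEQUENTIAL, test_a="alpha", test_b="beta")
        ct = evaluate_strategy(toy_cohort, seq)
        tp = fp = fn = tn = miss = 0
        for p in toy_cohort:
            routed = "alpha" if p.gp_judgement is CognitiveCategory.DEMENTIA else "beta"
            call = classify_by_threshold(p.scores.get(routed), toy_cohort.tests[routed])
            if call is BinaryCall.MISSING:
                miss += 1
                continue
            dis = p.reference is CognitiveCategory.DEMENTIA
            pos = call is BinaryCall.POSITIVE
            tp += pos and dis
            fp += pos and not dis
            fn += (not pos) and dis
            tn += (not pos) and not dis
        assert (ct.tp, ct.fp, ct.fn, ct.tn, ct.n_missing) == (tp, fp, fn, tn, miss)

    def test_undefined_test_rejected(self, toy_cohort):
        with pytest.raises(KeyError):
            evaluate_strategy(toy_cohort, Strategy(StrategyKind.SINGLE_TEST, test_a="gamma"))


def _random_complete_cohort(rng, n=60):
    parts = []
    for i in range(n):
        ref = rng.choice(["dementia", "cind", "normal"], p=[0.5, 0.25, 0.25])
        gp = rng.choice(["dementia", "cind", "normal"])
        scores = {"alpha": float(rng.normal(6 if ref == "dementia" else 3, 2))}
        parts.append(make_participant(i, ref, gp, scores))
    return Cohort(parts, [ALPHA])


def test_and_rule_bound_on_complete_case_cohorts():
    """On a common denominator, AND-combination can only lose sensitivity
    and gain specificity relative to each component."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        cohort = _random_complete_cohort(rng)
        gp_ct = evaluate_strategy(cohort, Strategy(StrategyKind.GP_ALONE))
        test_ct = evaluate_strategy(cohort, Strategy(StrategyKind.SINGLE_TEST, test_a="alpha"))
        comb_ct = evaluate_strategy(cohort, Strategy(StrategyKind.GP_AND_TEST, test_a="alpha"))
        if gp_ct.diseased == 0 or gp_ct.nondiseased == 0:
            continue
        assert sensitivity(comb_ct).point <= min(
            sensitivity(gp_ct).point, sensitivity(test_ct).point
        ) + 1e-12
        assert specificity(comb_ct).point >= max(
            specificity(gp_ct).point, specificity(test_ct).point
        ) - 1e-12


class TestStratifiedAccuracy:
    def test_strata_sum_to_overall(self, toy_cohort):
        by = {sa.stratum: sa for sa in stratified_accuracy(toy_cohort, "alpha")}
        overall = by[Stratum.OVERALL].confusion
        dem = by[Stratum.GP_DEMENTIA].confusion
        not_dem = by[Stratum.GP_NOT_DEMENTIA].confusion
        for cell in ("tp", "fp", "fn", "tn"):
            assert getattr(dem, cell) + getattr(not_dem, cell) == getattr(overall, cell)
        assert by[Stratum.GP_DEMENTIA].n + by[Stratum.GP_NOT_DEMENTIA].n == len(toy_cohort)

    def test_independent_test_has_null_auroc_in_both_strata(self):
        rng = np.random.default_rng(3)
        parts = []
        for i in range(4000):
            ref = rng.choice(["dementia", "cind", "normal"], p=[0.5, 0.25, 0.25])
            gp = rng.choice(["dementia", "normal"], p=[0.4, 0.6])
            parts.append(make_participant(i, ref, gp, {"alpha": float(rng.normal(5, 2))}))
        cohort = Cohort(parts, [ALPHA])
        for sa in stratified_accuracy(cohort, "alpha"):
            assert sa.auroc.auc == pytest.approx(0.5, abs=0.04)

    def test_ppv_tracks_stratum_prevalence(self):
        """With fixed sens/spec, Bayes' rule says PPV is higher in the
        high-prevalence (GP dementia) stratum: study-like prevalences 0.86
        and 0.38."""
        rng = np.random.default_rng(5)
        sens_true, spec_true = 0.8, 0.8
        parts = []
        i = 0
        for stratum, prev, n in (("dementia", 0.86, 3000), ("normal", 0.38, 3000)):
            for _ in range(n):
                dis = rng.random() < prev
                positive = rng.random() < (sens_true if dis else 1 - spec_true)
                parts.append(
                    make_participant(
                        i, "dementia" if dis else "normal", stratum,
                        {"alpha": 9.0 if positive else 1.0},
                    )
                )
                i += 1
        cohort = Cohort(parts, [ALPHA])
        by = {sa.stratum: sa for sa in stratified_accuracy(cohort, "alpha")}
        ppv_dem = by[Stratum.GP_DEMENTIA].ppv.point
        ppv_not = by[Stratum.GP_NOT_DEMENTIA].ppv.point
        assert ppv_dem > ppv_not
        # Bayes' rule oracle at the two prevalences
        def bayes_ppv(prev):
            return prev * sens_true / (prev * sens_true + (1 - prev) * (1 - spec_true))
        assert ppv_dem == pytest.approx(bayes_ppv(0.86), abs=0.05)
        assert ppv_not == pytest.approx(bayes_ppv(0.38), abs=0.05)

    def test_twelve_row_toy_matches_hand_built_tables(self):
        rows = [
            ("dementia", "dementia", 9), ("dementia", "dementia", 2),
            ("dementia", "cind", 7), ("dementia", "normal", 1),
            ("cind", "dementia", 8), ("cind", "cind", 3),
            ("cind", "normal", 6), ("normal", "dementia", 2),
            ("normal", "cind", 9), ("normal", "normal", 0),
            ("dementia", "cind", 5), ("normal", "normal", 4),
        ]
        cohort = Cohort(
            [make_participant(i, r, g, {"alpha": s}) for i, (r, g, s) in enumerate(rows)],
            [ALPHA],
        )
        by = {sa.stratum: sa for sa in stratified_accuracy(cohort, "alpha")}
        # hand count, GP-dementia stratum: rows 0,1,4,7 -> calls >=5: 9,2,8,2
        dem = by[Stratum.GP_DEMENTIA].confusion
        assert (dem.tp, dem.fp, dem.fn, dem.tn) == (1, 1, 1, 1)
        nd = by[Stratum.GP_NOT_DEMENTIA].confusion
        # remaining rows: tp rows 2 (7) and 10 (5); fn row 3; fp rows 6, 8; tn rows 5, 9, 11
        assert (nd.tp, nd.fp, nd.fn, nd.tn) == (2, 2, 1, 3)


def test_rank_tests_by_correct(toy_cohort):
    ranked = rank_tests_by_correct(toy_cohort, Stratum.OVERALL, top=2)
    assert len(ranked) == 2
    assert ranked[0][1] >= ranked[1][1]


@pytest.mark.parametrize(
    "text, kind, a, b",
    [
        ("gp-alone", StrategyKind.GP_ALONE, None, None),
        ("MoCA", StrategyKind.SINGLE_TEST, "MoCA", None),
        ("gp+6CIT", StrategyKind.GP_AND_TEST, "6CIT", None),
        ("seq:IQCODE/6CIT", StrategyKind.GP_ROUTED_SEQUENTIAL, "IQCODE", "6CIT"),
    ],
)
def test_parse_strategy(text, kind, a, b):
    s = parse_strategy(text)
    assert (s.kind, s.test_a, s.test_b) == (kind, a, b)


def test_strategy_validation():
    with pytest.raises(ValueError):
        Strategy(StrategyKind.GP_ROUTED_SEQUENTIAL, test_a="x")
    with pytest.raises(ValueError):
        Strategy(StrategyKind.GP_ALONE, test_a="x")
    with pytest.raises(ValueError):
        Strategy(StrategyKind.SINGLE_TEST)
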