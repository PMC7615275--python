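import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from briefcog import (
    CognitiveCategory,
    Cohort,
    Participant,
    PositiveDirection,
    Sex,
    TestDefinition,
    TestFamily,
    default_study_spec,
    study_crosstab_cohort,
)

# domain classes, not test classes
TestDefinition.__test__ = False
TestFamily.__test__ = False

ALPHA = TestDefinition("alpha", 5, PositiveDirection.AT_OR_ABOVE, TestFamily.COGNITIVE)
BETA = TestDefinition("beta", 10, PositiveDirection.BELOW, TestFamily.INFORMANT)


def make_participant(i, ref, gp, scores=None, durations=None, age=80.0):
    return Participant(
        id=f"t{i:03d}",
        age_years=age,
        sex=Sex.MALE if i % 2 else Sex.FEMALE,
        reference=CognitiveCategory(ref),
        gp_judgement=CognitiveCategory(gp),
        scores=scores or {},
        durations_min=durations or {},
    )


@pytest.fixture(scope="session")
def table1_cohort():
    """The 240-participant cohort implied by the published 3x3 GP-judgement
    by reference cross-tabulation (no test scores)."""
    return study_crosstab_cohort()


@pytest.fixture(scope="session")
def study_spec():
    return default_study_spec()


@pytest.fixture
def toy_cohort():
    """10 hand-built participants over two tests (one score missing)."""
    rows = [
        # (ref, gp, alpha_score, beta_score)
        ("dementia", "dementia", 7, 4),
        ("dementia", "dementia", 9, 12),
        ("dementia", "cind", 6, 8),
        ("dementia", "normal", 2, 15),
        ("cind", "cind", 4, 11),
        ("cind", "dementia", 8, 9),
        ("cind", "normal", 1, 14),
        ("normal", "normal", 3, 16),
        ("normal", "cind", 5, None),
        ("normal", "normal", 0, 13),
    ]
    parts = []
    for i, (ref, gp, a, b) in enumerate(rows):
        scores = {"alpha": a}
        if b is not None:
            scores["beta"] = b
        parts.append(make_participant(i, ref, gp, scores))
    return Cohort(participants=parts, tests=[ALPHA, BETA])
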