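"""Cohort domain types and I/O.

The central objects of the package: a :class:`Cohort` of study participants,
each with a three-level reference-standard category (dementia / CIND /
normal), the referring GP's three-level clinical judgement, and per-test
numeric scores and administration times; plus :class:`TestDefinition` objects
that carry each index test's dichotomization rule (threshold and positivity
direction) as configuration, never as code.

Missing-data semantics are fixed here once for the whole package: a missing
score is explicitly absent (never coded as zero), and all downstream
denominators are complete-case per test.  CIND is "cognitive impairment, not
dementia" — a real clinical category, but one that is grouped with "normal"
when test accuracy for dementia is computed downstream.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CognitiveCategory",
    "Sex",
    "PositiveDirection",
    "TestFamily",
    "TestDefinition",
    "Participant",
    "Cohort",
    "CohortError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "read_test_definitions",
    "write_test_definitions",
]

MIN_ELIGIBLE_AGE = 70.0  # study eligibility; violations warn, never fail


class CohortError(ValueError):
    """Invalid cohort structure (duplicate ids, inconsistent tests, ...)."""


class CohortParseError(CohortError):
    """A cohort or test-definition file could not be parsed."""


class CognitiveCategory(str, enum.Enum):
    """Three-level cognitive category used by both the reference standard
    and GP judgement."""

    DEMENTIA = "dementia"
    CIND = "cind"
    NORMAL = "normal"

    @classmethod
    def parse(cls, label: str) -> "CognitiveCategory":
        """Case-insensitive parse of a canonical category label."""
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise CohortParseError(
                f"unknown cognitive category {label!r}; "
                f"expected one of dementia/cind/normal"
            ) from None


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def parse(cls, label: str) -> "Sex":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise CohortParseError(
                f"unknown sex {label!r}; expected male/female"
            ) from None


class PositiveDirection(str, enum.Enum):
    """Which side of the threshold counts as a positive (disease-like) call.

    The direction fully determines boundary handling: ``below`` excludes the
    threshold value, ``at_or_below`` includes it, and symmetrically for the
    other pair.  No implicit polarity is ever applied.
    """

    BELOW = "below"
    AT_OR_BELOW = "at_or_below"
    ABOVE = "above"
    AT_OR_ABOVE = "at_or_above"

    @property
    def lower_is_positive(self) -> bool:
        return self in (PositiveDirection.BELOW, PositiveDirection.AT_OR_BELOW)


class TestFamily(str, enum.Enum):
    COGNITIVE = "cognitive"
    PHYSICAL = "physical"
    INFORMANT = "informant"


@dataclass(frozen=True)
class TestDefinition:
    """A named index test with its prespecified dichotomization rule.

    Parameters
    ----------
    name : str
        Unique test name (e.g. ``"MoCA"``).
    threshold : float
        The prespecified cut-point.
    positive_direction : PositiveDirection
        Side of the threshold (and boundary inclusion) that counts as a
        positive call.
    family : TestFamily
        ``cognitive`` (clinician-administered pencil-and-paper), ``physical``
        (e.g. timed up-and-go), or ``informant`` (questionnaire completed by
        an accompanying informant).
    """

    name: str
    threshold: float
    positive_direction: PositiveDirection
    family: TestFamily

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortError("test name must be non-empty")
        object.__setattr__(
            self, "positive_direction", PositiveDirection(self.positive_direction)
        )
        object.__setattr__(self, "family", TestFamily(self.family))
        object.__setattr__(self, "threshold", float(self.threshold))


@dataclass
class Participant:
    """One study subject.

    ``scores`` and ``durations_min`` map test name to value; a missing
    measurement is simply an absent key.  A duration may only be present when
    the corresponding score is present.
    """

    id: str
    age_years: float
    sex: Sex
    reference: CognitiveCategory
    gp_judgement: CognitiveCategory
    scores: dict[str, float] = field(default_factory=dict)
    durations_min: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reference = CognitiveCategory(self.reference)
        self.gp_judgement = CognitiveCategory(self.gp_judgement)
        self.sex = Sex(self.sex)
        if not self.id:
            raise CohortError("participant id must be non-empty")
        if not self.age_years > 0:
            raise CohortError(f"participant {self.id}: age must be positive")
        if self.age_years < MIN_ELIGIBLE_AGE:
            warnings.warn(
                f"participant {self.id}: age {self.age_years:g} is below the "
                f"eligibility minimum of {MIN_ELIGIBLE_AGE:g} years",
                stacklevel=2,
            )
        extra = set(self.durations_min) - set(self.scores)
        if extra:
            raise CohortError(
                f"participant {self.id}: duration present without score for "
                f"{sorted(extra)}"
            )
        for t, d in self.durations_min.items():
            if not d >= 0:
                raise CohortError(
                    f"participant {self.id}: negative duration for {t}"
                )

    def score(self, test: str) -> float | None:
        return self.scores.get(test)


@dataclass
class Cohort:
    """An ordered collection of participants plus the test definitions that
    give meaning to their score columns."""

    participants: list[Participant]
    tests: dict[str, TestDefinition]

    def __post_init__(self) -> None:
        if isinstance(self.tests, (list, tuple)):
            defs = list(self.tests)
            self.tests = {}
            for d in defs:
                if d.name in self.tests:
                    raise CohortError(f"duplicate test definition {d.name!r}")
                self.tests[d.name] = d
        seen: set[str] = set()
        for p in self.participants:
            if p.id in seen:
                raise CohortError(f"duplicate participant id {p.id!r}")
            seen.add(p.id)
            unknown = set(p.scores) - set(self.tests)
            if unknown:
                raise CohortError(
                    f"participant {p.id}: scores for undefined tests "
                    f"{sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    @property
    def test_names(self) -> list[str]:
        return list(self.tests)

    def reference_counts(self) -> dict[CognitiveCategory, int]:
        out = {c: 0 for c in CognitiveCategory}
        for p in self.participants:
            out[p.reference] += 1
        return out

    def gp_counts(self) -> dict[CognitiveCategory, int]:
        out = {c: 0 for c in CognitiveCategory}
        for p in self.participants:
            out[p.gp_judgement] += 1
        return out

    def crosstab(self) -> pd.DataFrame:
        """3x3 cross-tabulation of GP judgement (rows) by reference (cols)."""
        cats = [c.value for c in CognitiveCategory]
        tab = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
        for p in self.participants:
            tab.loc[p.gp_judgement.value, p.reference.value] += 1
        tab.index.name = "gp_judgement"
        tab.columns.name = "reference"
        return tab

    def complete_case_n(self, test: str) -> int:
        """Number of participants with an observed score for ``test``."""
        return sum(1 for p in self.participants if test in p.scores)

    def to_frame(self) -> pd.DataFrame:
        """Tidy wide table with one row per participant (missing = NaN)."""
        rows = []
        for p in self.participants:
            row: dict[str, object] = {
                "id": p.id,
                "age": p.age_years,
                "sex": p.sex.value,
                "reference": p.reference.value,
                "gp_judgement": p.gp_judgement.value,
            }
            for t in self.tests:
                row[f"score_{t}"] = p.scores.get(t, math.nan)
                row[f"duration_{t}"] = p.durations_min.get(t, math.nan)
            rows.append(row)
        cols = ["id", "age", "sex", "reference", "gp_judgement"]
        for t in self.tests:
            cols += [f"score_{t}", f"duration_{t}"]
        return pd.DataFrame(rows, columns=cols)


def read_test_definitions(path: str | Path) -> list[TestDefinition]:
    """Read a JSON array of test definitions.

    All four fields (``name``, ``threshold``, ``positive_direction``,
    ``family``) are mandatory; no defaults are invented.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise CohortParseError("test-definition file must be a JSON array")
    defs: list[TestDefinition] = []
    names: set[str] = set()
    for i, obj in enumerate(raw):
        missing = {"name", "threshold", "positive_direction", "family"} - set(obj)
        if missing:
            raise CohortParseError(
                f"test definition #{i}: missing fields {sorted(missing)}"
            )
        try:
            d = TestDefinition(
                name=obj["name"],
                threshold=obj["threshold"],
                positive_direction=PositiveDirection(obj["positive_direction"]),
                family=TestFamily(obj["family"]),
            )
        except ValueError as exc:
            raise CohortParseError(f"test definition #{i}: {exc}") from None
        if d.name in names:
            raise CohortParseError(f"duplicate test definition {d.name!r}")
        names.add(d.name)
        defs.append(d)
    return defs


def write_test_definitions(defs: Iterable[TestDefinition], path: str | Path) -> None:
    payload = [
        {
            "name": d.name,
            "threshold": d.threshold,
            "positive_direction": d.positive_direction.value,
            "family": d.family.value,
        }
        for d in defs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_cohort(path: str | Path, tests_path: str | Path) -> Cohort:
    """Read a cohort CSV together with its test-definition JSON.

    The CSV has columns ``id, age, sex, reference, gp_judgement`` plus
    ``score_<test>`` / ``duration_<test>`` pairs; empty cells are missing.
    Category labels are matched case-insensitively.  Row order is preserved.
    """
    defs = read_test_definitions(tests_path)
    def_names = {d.name for d in defs}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "age", "sex", "reference", "gp_judgement"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CohortParseError(f"cohort CSV missing columns {sorted(missing_cols)}")
    score_cols = [c for c in df.columns if c.startswith("score_")]
    duration_cols = [c for c in df.columns if c.startswith("duration_")]
    for c in score_cols + duration_cols:
        test = c.split("_", 1)[1]
        if test not in def_names:
            raise CohortParseError(
                f"column {c!r} has no matching test definition"
            )

    participants: list[Participant] = []
    for i, row in df.iterrows():
        try:
            ref = CognitiveCategory.parse(row["reference"])
            gp = CognitiveCategory.parse(row["gp_judgement"])
            sex = Sex.parse(row["sex"])
        except CohortParseError as exc:
            raise CohortParseError(f"row {i + 1} (id={row['id']!r}): {exc}") from None
        scores: dict[str, float] = {}
        durations: dict[str, float] = {}
        for c in score_cols:
            if row[c] != "":
                scores[c.split("_", 1)[1]] = float(row[c])
        for c in duration_cols:
            if row[c] != "":
                durations[c.split("_", 1)[1]] = float(row[c])
        participants.append(
            Participant(
                id=row["id"],
                age_years=float(row["age"]),
                sex=sex,
                reference=ref,
                gp_judgement=gp,
                scores=scores,
                durations_min=durations,
            )
        )
    return Cohort(participants=participants, tests=defs)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that :func:`read_cohort` parses back identically."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)


def crosstab_cohort(
    counts: Mapping[tuple[CognitiveCategory, CognitiveCategory], int],
    tests: Iterable[TestDefinition] = (),
    age: float = 80.0,
) -> Cohort:
    """Expand a (gp_judgement, reference) -> count table into an individual-
    level cohort with no test scores.

    Useful for reproducing results that depend only on the published 3x3
    cross-tabulation of GP judgement against the reference standard.
    Demographics are filler (constant age, alternating sex).
    """
    participants: list[Participant] = []
    k = 0
    for (gp, ref), n in counts.items():
        for _ in range(int(n)):
            k += 1
            participants.append(
                Participant(
                    id=f"p{k:04d}",
                    age_years=age,
                    sex=Sex.MALE if k % 2 else Sex.FEMALE,
                    reference=ref,
                    gp_judgement=gp,
                )
            )
    return Cohort(participants=participants, tests=list(tests))
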