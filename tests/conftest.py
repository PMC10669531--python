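"""Shared fixtures: a hand-checkable 10-transaction set and record factories."""

from __future__ import annotations

import pytest

from famschool.discretization import Item, Transaction, TransactionSet
from famschool.survey_model import ScoredRecord, default_codebook
from famschool.synthetic_data import default_config, generate_participants


@pytest.fixture(scope="session")
def fix10() -> TransactionSet:
    """Ten transactions over items A, B, Y with hand-countable supports."""
    baskets = [
        {"A", "B", "Y"}, {"A", "B", "Y"}, {"A", "Y"}, {"B", "Y"}, {"A", "B"},
        {"A"}, {"B"}, {"Y"}, set(), {"A", "B", "Y"},
    ]
    catalog = tuple(Item(lbl, "unknown", lbl) for lbl in "ABY")
    return TransactionSet(
        tuple(Transaction(f"T{i + 1}", frozenset(b)) for i, b in enumerate(baskets)),
        catalog,
        "risk",
    )


def make_scored(
    pid: str = "p1",
    gender: str = "male",
    grade: int = 5,
    left_behind: bool = False,
    intact: bool = True,
    edu_low: bool = False,
    ranking: str = "average",
    courses: bool = True,
    counselors: bool = True,
    rooms: bool = True,
    dsrsc: int = 5,
    **totals: int,
) -> ScoredRecord:
    """A ScoredRecord with mid-range defaults; override totals by scale name."""
    base = {
        "cohesion": 48,
        "conflict": 4,
        "financial_strain": 12,
        "teacher_support": 18,
        "peer_support": 32,
        "autonomy_support": 12,
    }
    base.update(totals)
    base["dsrsc"] = dsrsc
    return ScoredRecord(
        participant_id=pid,
        gender=gender,
        grade=grade,
        left_behind=left_behind,
        family_structure_intact=intact,
        parental_education_low=edu_low,
        academic_ranking=ranking,
        school_psych_courses=courses,
        school_counselors=counselors,
        school_counseling_rooms=rooms,
        scale_totals=base,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 2445, seed 7), generated once."""
    return generate_participants(default_config(seed=7))


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()
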