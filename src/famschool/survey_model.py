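"""Survey data model: scales, participant records, scoring and reliability.

The study instruments are six psychometric scales plus a short financial-strain
index, all scored as plain item sums:

================  =====  =========  ==========================================
scale             items  responses  construct
================  =====  =========  ==========================================
cohesion            16     1–5      family emotional closeness (FACES-II)
conflict             9     0–1      family conflict frequency (FES subscale)
financial_strain     5     1–4      frequency of family economic problems
teacher_support      7     1–4      school climate: teacher support
peer_support        13     1–4      school climate: peer support
autonomy_support     5     1–4      school climate: autonomy opportunities
dsrsc               18     0–2      depressive symptoms (DSRSC)
================  =====  =========  ==========================================

Missing responses are represented as ``None``; the analysis is complete-case
only (no imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleDefinition",
    "Codebook",
    "ParticipantRecord",
    "ScoredRecord",
    "SchemaError",
    "ReliabilityError",
    "default_codebook",
    "load_codebook",
    "save_codebook",
    "load_participants",
    "write_participants",
    "filter_complete_cases",
    "score_scales",
    "cronbach_alpha",
]

GENDERS = ("female", "male")
RANKINGS = ("top10", "average", "last10")

#: boolean demographic/flag columns in the participant table, in file order
_BOOL_COLUMNS = (
    "left_behind",
    "family_structure_intact",
    "parental_education_low",
    "school_psych_courses",
    "school_counselors",
    "school_counseling_rooms",
)


class SchemaError(ValueError):
    """A participant table does not match the codebook schema."""


class ReliabilityError(ValueError):
    """Cronbach's alpha is undefined (zero total-score variance)."""


@dataclass(frozen=True)
class ScaleDefinition:
    """Structure of one scale: item count and shared integer response range."""

    name: str
    item_count: int
    response_min: int
    response_max: int
    prefix: str

    def __post_init__(self) -> None:
        if self.item_count < 1:
            raise ValueError(f"{self.name}: item_count must be >= 1")
        if self.response_min >= self.response_max:
            raise ValueError(f"{self.name}: response_min must be < response_max")

    @property
    def min_total(self) -> int:
        return self.item_count * self.response_min

    @property
    def max_total(self) -> int:
        return self.item_count * self.response_max

    @property
    def columns(self) -> list[str]:
        return [f"{self.prefix}_{i:02d}" for i in range(1, self.item_count + 1)]


@dataclass(frozen=True)
class Codebook:
    """Scale registry plus categorical level dictionaries."""

    scales: tuple[ScaleDefinition, ...]
    genders: tuple[str, ...] = GENDERS
    rankings: tuple[str, ...] = RANKINGS

    def __post_init__(self) -> None:
        names = [s.name for s in self.scales]
        if len(set(names)) != len(names):
            raise ValueError("scale names must be unique")

    def scale(self, name: str) -> ScaleDefinition:
        for s in self.scales:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def scale_names(self) -> list[str]:
        return [s.name for s in self.scales]

    @property
    def columns(self) -> list[str]:
        cols = ["participant_id", "gender", "grade", "academic_ranking"]
        cols += list(_BOOL_COLUMNS)
        for s in self.scales:
            cols += s.columns
        return cols


def default_codebook() -> Codebook:
    """The study's instrument battery (item counts and response ranges)."""
    return Codebook(
        scales=(
            ScaleDefinition("cohesion", 16, 1, 5, "coh"),
            ScaleDefinition("conflict", 9, 0, 1, "con"),
            ScaleDefinition("financial_strain", 5, 1, 4, "fin"),
            ScaleDefinition("teacher_support", 7, 1, 4, "tea"),
            ScaleDefinition("peer_support", 13, 1, 4, "pee"),
            ScaleDefinition("autonomy_support", 5, 1, 4, "aut"),
            ScaleDefinition("dsrsc", 18, 0, 2, "dsrsc"),
        )
    )


def save_codebook(codebook: Codebook, path) -> None:
    """Write a codebook as a human-editable YAML document."""
    doc = {
        "scales": [
            {
                "name": s.name,
                "item_count": s.item_count,
                "response_min": s.response_min,
                "response_max": s.response_max,
                "prefix": s.prefix,
            }
            for s in codebook.scales
        ],
        "genders": list(codebook.genders),
        "rankings": list(codebook.rankings),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_codebook(path) -> Codebook:
    """Read a YAML codebook written by :func:`save_codebook`."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return Codebook(
        scales=tuple(ScaleDefinition(**s) for s in doc["scales"]),
        genders=tuple(doc.get("genders", GENDERS)),
        rankings=tuple(doc.get("rankings", RANKINGS)),
    )


@dataclass(frozen=True)
class ParticipantRecord:
    """One respondent: demographics, school-resource flags and item responses.

    ``item_responses`` maps scale name to a tuple of integers, with ``None``
    marking a missing or out-of-range response.  ``school_stage`` is always
    derived from ``grade`` (5–6 primary, 7–9 middle), never stored.
    """

    participant_id: str
    gender: str
    grade: int
    left_behind: bool
    family_structure_intact: bool
    parental_education_low: bool
    academic_ranking: str
    school_psych_courses: bool
    school_counselors: bool
    school_counseling_rooms: bool
    item_responses: dict[str, tuple[int | None, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if not 5 <= self.grade <= 9:
            raise ValueError(f"grade {self.grade} outside 5–9")
        if self.academic_ranking not in RANKINGS:
            raise ValueError(f"unknown academic ranking {self.academic_ranking!r}")

    @property
    def school_stage(self) -> str:
        return "primary" if self.grade <= 6 else "middle"

    @property
    def has_missing(self) -> bool:
        return any(
            r is None for items in self.item_responses.values() for r in items
        )


@dataclass(frozen=True)
class ScoredRecord:
    """A complete participant with scale totals attached."""

    participant_id: str
    gender: str
    grade: int
    left_behind: bool
    family_structure_intact: bool
    parental_education_low: bool
    academic_ranking: str
    school_psych_courses: bool
    school_counselors: bool
    school_counseling_rooms: bool
    scale_totals: dict[str, int] = field(default_factory=dict)

    @property
    def school_stage(self) -> str:
        return "primary" if self.grade <= 6 else "middle"

    @property
    def depression_score(self) -> int:
        return self.scale_totals["dsrsc"]


def _parse_cell(raw: object, row: int, col: str) -> int | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        return int(float(text))
    except ValueError as exc:
        raise ValueError(f"unparseable cell at row {row}, column {col!r}: {raw!r}") from exc


def load_participants(path, codebook: Codebook | None = None) -> list[ParticipantRecord]:
    """Read a delimited participant table into records, preserving row order.

    Out-of-range item responses are flagged missing (``None``); blank cells are
    missing.  Raises :class:`SchemaError` naming the first absent column.
    """
    codebook = codebook or default_codebook()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in codebook.columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    records: list[ParticipantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        responses: dict[str, tuple[int | None, ...]] = {}
        for scale in codebook.scales:
            vals = []
            for col in scale.columns:
                v = _parse_cell(row[col], i, col)
                if v is not None and not scale.response_min <= v <= scale.response_max:
                    v = None
                vals.append(v)
            responses[scale.name] = tuple(vals)
        bools = {}
        for col in _BOOL_COLUMNS:
            v = _parse_cell(row[col], i, col)
            if v is None:
                raise ValueError(f"unparseable cell at row {i}, column {col!r}: blank")
            bools[col] = bool(v)
        grade = _parse_cell(row["grade"], i, "grade")
        if grade is None:
            raise ValueError(f"unparseable cell at row {i}, column 'grade': blank")
        records.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                gender=str(row["gender"]),
                grade=grade,
                academic_ranking=str(row["academic_ranking"]),
                item_responses=responses,
                **bools,
            )
        )
    return records


def write_participants(records, path, codebook: Codebook | None = None) -> None:
    """Write records as a UTF-8 comma-delimited table (missing cell = empty)."""
    codebook = codebook or default_codebook()
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "participant_id": rec.participant_id,
            "gender": rec.gender,
            "grade": rec.grade,
            "academic_ranking": rec.academic_ranking,
        }
        for col in _BOOL_COLUMNS:
            row[col] = int(getattr(rec, col))
        for scale in codebook.scales:
            for col, v in zip(scale.columns, rec.item_responses[scale.name]):
                row[col] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows, columns=codebook.columns).to_csv(path, index=False)


def filter_complete_cases(records) -> list[ParticipantRecord]:
    """Keep records with no missing item responses (complete-case analysis)."""
    kept = [r for r in records if not r.has_missing]
    logger.info("complete-case filter: %d in, %d retained", len(records), len(kept))
    return kept


def score_scales(record: ParticipantRecord, codebook: Codebook | None = None) -> ScoredRecord:
    """Sum item responses per scale.  The record must be complete."""
    codebook = codebook or default_codebook()
    totals: dict[str, int] = {}
    for scale in codebook.scales:
        items = record.item_responses[scale.name]
        if any(v is None for v in items):
            raise ValueError(
                f"record {record.participant_id}: missing {scale.name} item; "
                "apply filter_complete_cases first"
            )
        totals[scale.name] = int(sum(items))
    return ScoredRecord(
        participant_id=record.participant_id,
        gender=record.gender,
        grade=record.grade,
        left_behind=record.left_behind,
        family_structure_intact=record.family_structure_intact,
        parental_education_low=record.parental_education_low,
        academic_ranking=record.academic_ranking,
        school_psych_courses=record.school_psych_courses,
        school_counselors=record.school_counselors,
        school_counseling_rooms=record.school_counseling_rooms,
        scale_totals=totals,
    )


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum(item var) / total var)``.

    Sample variances use ``n - 1`` denominators.  Raises
    :class:`ReliabilityError` when the total score has zero variance.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ReliabilityError("total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
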