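"""Quartile/criterion discretization of scored records into transactions.

Each participant becomes one *transaction*: a set of discrete item labels in
either **risk** mode (items mark adverse conditions, e.g. ``"low family
cohesion"`` for a cohesion total at or below the 25th percentile) or
**protective** mode (items mark resources, e.g. ``"high family cohesion"`` for
a total at or above the 75th percentile).  Quartile cutoffs use the
nearest-rank convention on the full analytic sample.  Every transaction also
carries the participant's demographic level items (gender, school stage,
academic ranking) and exactly one outcome item, ``"depression"`` when the
DSRSC total reaches the screening threshold (default 15, inclusive) and
``"nondepression"`` otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from famschool.survey_model import ScoredRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Item",
    "CutoffTable",
    "OutcomeRule",
    "Transaction",
    "TransactionSet",
    "QUARTILE_SCALES",
    "RISK_ITEMS",
    "PROTECTIVE_ITEMS",
    "DEMOGRAPHIC_ITEMS",
    "OUTCOME_ITEMS",
    "compute_cutoffs",
    "label_outcome",
    "assign_items",
    "build_transactions",
    "write_baskets",
    "to_onehot",
]

DEPRESSION = "depression"
NONDEPRESSION = "nondepression"


@dataclass(frozen=True)
class Item:
    """A discrete analysis item: canonical label, polarity, source variable."""

    label: str
    polarity: str  # risk | protective | demographic | ranking | outcome
    source_variable: str


#: scales discretized by the <=P25 / >=P75 criteria (DSRSC is the outcome)
QUARTILE_SCALES = (
    "cohesion",
    "conflict",
    "financial_strain",
    "teacher_support",
    "peer_support",
    "autonomy_support",
)

# (label, source_variable, scale side) — side "low" means the risk/protective
# criterion is total <= P25, side "high" means total >= P75.
_RISK_QUARTILE = (
    ("low family cohesion", "cohesion", "low"),
    ("high family conflict", "conflict", "high"),
    ("family economic strain", "financial_strain", "high"),
    ("low teacher support", "teacher_support", "low"),
    ("low peer support", "peer_support", "low"),
    ("low autonomy support", "autonomy_support", "low"),
)
_PROTECTIVE_QUARTILE = (
    ("high family cohesion", "cohesion", "high"),
    ("low family conflict", "conflict", "low"),
    ("no family economic strain", "financial_strain", "low"),
    ("high teacher support", "teacher_support", "high"),
    ("high peer support", "peer_support", "high"),
    ("high autonomy support", "autonomy_support", "high"),
)
_RISK_FLAGS = (
    ("family structure risk", "family_structure"),
    ("separation from parents", "left_behind"),
    ("low parental education level", "parental_education"),
    ("absence of psychology courses", "psych_courses"),
    ("absence of counselors in the school", "counselors"),
    ("absence of counseling rooms in the school", "counseling_rooms"),
)
_PROTECTIVE_FLAGS = (
    ("no family structure risk", "family_structure"),
    ("non-left-behind children", "left_behind"),
    ("parental education junior high or above", "parental_education"),
    ("presence of psychology courses", "psych_courses"),
    ("presence of counselors in the school", "counselors"),
    ("presence of counseling rooms in the school", "counseling_rooms"),
)

RISK_ITEMS = tuple(
    [Item(lbl, "risk", var) for lbl, var, _ in _RISK_QUARTILE]
    + [Item(lbl, "risk", var) for lbl, var in _RISK_FLAGS]
)
PROTECTIVE_ITEMS = tuple(
    [Item(lbl, "protective", var) for lbl, var, _ in _PROTECTIVE_QUARTILE]
    + [Item(lbl, "protective", var) for lbl, var in _PROTECTIVE_FLAGS]
)
DEMOGRAPHIC_ITEMS = (
    Item("female", "demographic", "gender"),
    Item("male", "demographic", "gender"),
    Item("primary school students", "demographic", "school_stage"),
    Item("middle school students", "demographic", "school_stage"),
    Item("top-10 academic ranking", "ranking", "academic_ranking"),
    Item("average academic ranking", "ranking", "academic_ranking"),
    Item("last-10 academic ranking", "ranking", "academic_ranking"),
)
OUTCOME_ITEMS = (
    Item(DEPRESSION, "outcome", "outcome"),
    Item(NONDEPRESSION, "outcome", "outcome"),
)

_RANKING_LABEL = {
    "top10": "top-10 academic ranking",
    "average": "average academic ranking",
    "last10": "last-10 academic ranking",
}
_STAGE_LABEL = {"primary": "primary school students", "middle": "middle school students"}


@dataclass(frozen=True)
class CutoffTable:
    """Per-scale 25th/75th nearest-rank percentile values on the score scale."""

    cutoffs: dict[str, tuple[int, int]]

    def p25(self, scale: str) -> int:
        return self.cutoffs[scale][0]

    def p75(self, scale: str) -> int:
        return self.cutoffs[scale][1]

    def degenerate_scales(self) -> set[str]:
        """Scales whose quartiles coincide; they emit no items."""
        return {s for s, (lo, hi) in self.cutoffs.items() if lo == hi}


@dataclass(frozen=True)
class OutcomeRule:
    """DSRSC screening rule: depression when total >= threshold (inclusive)."""

    threshold: int = 15
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 36:
            raise ValueError("threshold must lie in [0, 36]")


@dataclass(frozen=True)
class Transaction:
    participant_id: str
    items: frozenset[str]


@dataclass(frozen=True)
class TransactionSet:
    """Ordered transactions plus the item catalog they draw from."""

    transactions: tuple[Transaction, ...]
    catalog: tuple[Item, ...]
    mode: str

    def __len__(self) -> int:
        return len(self.transactions)

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.catalog]


def nearest_rank(sorted_values, q: float):
    """Value at 1-based position ``ceil(q * n)`` of an ascending sequence."""
    n = len(sorted_values)
    return sorted_values[max(math.ceil(q * n), 1) - 1]


def compute_cutoffs(records, scales=QUARTILE_SCALES) -> CutoffTable:
    """Nearest-rank P25/P75 of each scale's totals over the analytic sample."""
    records = list(records)
    if not records:
        raise ValueError("cannot compute cutoffs from an empty sample")
    table: dict[str, tuple[int, int]] = {}
    for scale in scales:
        totals = sorted(r.scale_totals[scale] for r in records)
        table[scale] = (int(nearest_rank(totals, 0.25)), int(nearest_rank(totals, 0.75)))
    return CutoffTable(table)


def label_outcome(score: int, rule: OutcomeRule = OutcomeRule()) -> str:
    """Map a DSRSC total to ``"depression"`` / ``"nondepression"``."""
    if not 0 <= score <= 36:
        raise ValueError(f"DSRSC total {score} outside [0, 36]")
    if rule.inclusive:
        return DEPRESSION if score >= rule.threshold else NONDEPRESSION
    return DEPRESSION if score > rule.threshold else NONDEPRESSION


def assign_items(
    record: ScoredRecord,
    cutoffs: CutoffTable,
    mode: str,
    *,
    suppress: set[str] | None = None,
) -> set[str]:
    """Emit the mode's factor items whose criteria hold, plus demographic items.

    ``suppress`` lists degenerate scales (P25 == P75) that contribute nothing.
    """
    if mode == "risk":
        quartile_spec, flag_spec = _RISK_QUARTILE, _RISK_FLAGS
    elif mode == "protective":
        quartile_spec, flag_spec = _PROTECTIVE_QUARTILE, _PROTECTIVE_FLAGS
    else:
        raise ValueError(f"unknown mode {mode!r}")
    suppress = suppress or set()
    items: set[str] = set()
    for label, scale, side in quartile_spec:
        if scale in suppress:
            continue
        total = record.scale_totals[scale]
        if side == "low" and total <= cutoffs.p25(scale):
            items.add(label)
        elif side == "high" and total >= cutoffs.p75(scale):
            items.add(label)
    flag_state = {
        "family_structure": not record.family_structure_intact,
        "left_behind": record.left_behind,
        "parental_education": record.parental_education_low,
        "psych_courses": not record.school_psych_courses,
        "counselors": not record.school_counselors,
        "counseling_rooms": not record.school_counseling_rooms,
    }
    for label, var in flag_spec:
        adverse = flag_state[var]
        if (mode == "risk" and adverse) or (mode == "protective" and not adverse):
            items.add(label)
    items.add(record.gender)
    items.add(_STAGE_LABEL[record.school_stage])
    items.add(_RANKING_LABEL[record.academic_ranking])
    return items


def build_transactions(
    records,
    cutoffs: CutoffTable,
    mode: str,
    outcome_rule: OutcomeRule = OutcomeRule(),
    exclude_variables: set[str] | frozenset[str] = frozenset(),
) -> TransactionSet:
    """One transaction per scored record: factor items plus the outcome item.

    Items sourced from any variable in ``exclude_variables`` (typically the
    stratifying variable) are dropped from both the transactions and the
    catalog.  Degenerate scales (P25 == P75) are suppressed and logged.
    """
    exclude = set(exclude_variables)
    suppress = cutoffs.degenerate_scales()
    for scale in sorted(suppress):
        logger.warning("scale %s has P25 == P75; its items are suppressed", scale)
    factor_items = RISK_ITEMS if mode == "risk" else PROTECTIVE_ITEMS
    if mode not in ("risk", "protective"):
        raise ValueError(f"unknown mode {mode!r}")
    catalog = tuple(
        it
        for it in (*factor_items, *DEMOGRAPHIC_ITEMS, *OUTCOME_ITEMS)
        if it.source_variable not in exclude
        and not (it.source_variable in suppress)
    )
    allowed = {it.label for it in catalog}
    transactions = []
    for rec in records:
        items = assign_items(rec, cutoffs, mode, suppress=suppress)
        items &= allowed
        items.add(label_outcome(rec.depression_score, outcome_rule))
        transactions.append(Transaction(rec.participant_id, frozenset(items)))
    return TransactionSet(tuple(transactions), catalog, mode)


def write_baskets(ts: TransactionSet, path) -> None:
    """Basket export: one transaction per line, comma-separated sorted labels."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in ts.transactions:
            fh.write(",".join(sorted(t.items)) + "\n")


def to_onehot(ts: TransactionSet) -> pd.DataFrame:
    """One-hot indicator table (rows = transactions, columns = catalog labels)."""
    labels = ts.labels
    data = [[lbl in t.items for lbl in labels] for t in ts.transactions]
    return pd.DataFrame(data, columns=labels, index=[t.participant_id for t in ts.transactions])
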