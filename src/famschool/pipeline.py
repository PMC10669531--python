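"""Stratified rule-mining analyses, rule-table summaries and reference tables.

The analysis grid mirrors the original study: association rules are mined
separately within strata of gender, age group (primary vs middle school) and
left-behind status, in two modes —

- **risk** mode: consequent fixed to ``"depression"``; thresholds
  min_sup 5% / min_conf 70% for the gender and age-group analyses and
  min_sup 5% / min_conf 80% for the left-behind analysis;
- **protective** mode: consequent fixed to ``"nondepression"``; thresholds
  min_sup 20% / min_conf 80% for all three analyses;

with lift > 1 required everywhere and rules ordered by descending confidence.
The stratifying variable is excluded from its own analysis's item universe
(its level item would have 100% within-stratum support and lift exactly 1).

The package also ships verbatim transcriptions of the study's six published
rule tables; :func:`load_reference_tables` loads them and
:func:`check_reference_tables` recomputes their summary counts, metric ranges
and implied-base-rate consistency, reporting (not resolving) the internal
discrepancies present in the printed tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from famschool.arm_core import (
    AssociationRule,
    MiningParams,
    apriori_frequent_itemsets,
    rules_for_consequent,
    rules_to_frame,
)
from famschool.discretization import (
    DEPRESSION,
    NONDEPRESSION,
    OutcomeRule,
    build_transactions,
    compute_cutoffs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StratumSpec",
    "AnalysisConfig",
    "RuleTable",
    "TableSummary",
    "ReferenceRule",
    "ReferenceTable",
    "PackagingError",
    "STRATIFIERS",
    "run_stratified_analysis",
    "summarize_rule_table",
    "implied_base_rate_check",
    "load_reference_tables",
    "check_reference_tables",
    "write_report",
]


#: stratifier name -> (excluded source variable, ordered levels)
STRATIFIERS: dict[str, tuple[str, tuple[str, str]]] = {
    "gender": ("gender", ("male", "female")),
    "age_group": ("school_stage", ("primary", "middle")),
    "left_behind_status": ("left_behind", ("non_left_behind", "left_behind")),
}


def _in_stratum(record, stratifier: str, level: str) -> bool:
    if stratifier == "gender":
        return record.gender == level
    if stratifier == "age_group":
        return record.school_stage == level
    if stratifier == "left_behind_status":
        return record.left_behind == (level == "left_behind")
    raise KeyError(f"unknown stratifier {stratifier!r}")


@dataclass(frozen=True)
class StratumSpec:
    stratifier: str
    level: str

    def __post_init__(self) -> None:
        if self.stratifier not in STRATIFIERS:
            raise ValueError(f"unknown stratifier {self.stratifier!r}")
        if self.level not in STRATIFIERS[self.stratifier][1]:
            raise ValueError(f"level {self.level!r} not in {self.stratifier!r}")


def _default_params(mode: str) -> dict[str, MiningParams]:
    if mode == "risk":
        return {
            "gender": MiningParams(0.05, 0.70, 1.0),
            "age_group": MiningParams(0.05, 0.70, 1.0),
            "left_behind_status": MiningParams(0.05, 0.80, 1.0),
        }
    if mode == "protective":
        return {s: MiningParams(0.20, 0.80, 1.0) for s in STRATIFIERS}
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Mode, per-stratifier mining thresholds, outcome rule and cutoff scope."""

    mode: str
    params: dict[str, MiningParams] = field(default_factory=dict)
    outcome_rule: OutcomeRule = field(default_factory=OutcomeRule)
    cutoff_scope: str = "pooled"  # "pooled" | "stratum"

    def __post_init__(self) -> None:
        if self.mode not in ("risk", "protective"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cutoff_scope not in ("pooled", "stratum"):
            raise ValueError(f"unknown cutoff_scope {self.cutoff_scope!r}")
        if not self.params:
            object.__setattr__(self, "params", _default_params(self.mode))

    @property
    def rhs(self) -> str:
        return DEPRESSION if self.mode == "risk" else NONDEPRESSION


@dataclass(frozen=True)
class RuleTable:
    """Sorted mined rules for one stratum in one mode."""

    stratum: StratumSpec
    mode: str
    rules: tuple[AssociationRule, ...]
    n_records: int = 0


def run_stratified_analysis(
    records,
    config: AnalysisConfig,
    stratifiers=("gender", "age_group", "left_behind_status"),
) -> list[RuleTable]:
    """Mine rule tables for every level of every requested stratifier."""
    records = list(records)
    pooled_cutoffs = compute_cutoffs(records) if records else None
    tables: list[RuleTable] = []
    for strat in stratifiers:
        variable, levels = STRATIFIERS[strat]
        params = config.params[strat]
        for level in levels:
            subset = [r for r in records if _in_stratum(r, strat, level)]
            spec = StratumSpec(strat, level)
            if not subset:
                logger.warning("stratum %s=%s is empty; emitting empty table", strat, level)
                tables.append(RuleTable(spec, config.mode, (), 0))
                continue
            cutoffs = pooled_cutoffs if config.cutoff_scope == "pooled" else compute_cutoffs(subset)
            ts = build_transactions(
                subset, cutoffs, config.mode, config.outcome_rule, {variable}
            )
            frequent = apriori_frequent_itemsets(ts, params.min_sup)
            rules = rules_for_consequent(frequent, config.rhs, ts, params)
            logger.info(
                "stratum %s=%s: %d records, %d transactions, %d rules",
                strat, level, len(subset), len(ts), len(rules),
            )
            tables.append(RuleTable(spec, config.mode, tuple(rules), len(subset)))
    return tables


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class TableSummary:
    rule_count: int
    counts_by_size: dict[int, int]
    support_range: tuple[float, float] | None
    confidence_range: tuple[float, float] | None
    lift_range: tuple[float, float] | None
    implied_base_rates: tuple[float, ...]
    base_rate_mean: float | None
    base_rate_cv: float | None
    duplicate_lhs_count: int = 0


def _rows(rules):
    """(itemset size, support, confidence, lift) per rule, mined or reference."""
    out = []
    for r in rules:
        if isinstance(r, AssociationRule):
            out.append((r.itemset_size, r.metrics.support, r.metrics.confidence, r.metrics.lift))
        else:
            out.append((len(r.lhs) + 1, r.support, r.confidence, r.lift))
    return out


def implied_base_rate_check(rules):
    """Per-rule confidence/lift (an estimate of the consequent's base rate),
    with mean and coefficient of variation.  Near-zero CV within a stratum is
    an internal-consistency check of a printed rule table.
    """
    rows = _rows(rules)
    if not rows:
        raise ValueError("need at least one rule")
    if any(lift <= 0 for *_, lift in rows):
        raise ValueError("lift must be positive for base-rate imputation")
    rates = tuple(conf / lift for _, _, conf, lift in rows)
    mean = float(np.mean(rates))
    cv = float(np.std(rates, ddof=0) / mean) if mean else float("nan")
    return rates, mean, cv


def summarize_rule_table(table) -> TableSummary:
    """Counts, itemset-size decomposition, metric ranges and implied base rates."""
    rules = table.rules if hasattr(table, "rules") else tuple(table)
    rows = _rows(rules)
    if not rows:
        return TableSummary(0, {}, None, None, None, (), None, None)
    sizes = [s for s, *_ in rows]
    counts = {k: sizes.count(k) for k in sorted(set(sizes))}
    sup = [r[1] for r in rows]
    conf = [r[2] for r in rows]
    lift = [r[3] for r in rows]
    rates, mean, cv = implied_base_rate_check(rules)
    lhs_keys = [
        frozenset(r.lhs) if not isinstance(r, AssociationRule) else r.lhs for r in rules
    ]
    dupes = len(lhs_keys) - len(set(lhs_keys))
    return TableSummary(
        rule_count=len(rows),
        counts_by_size=counts,
        support_range=(min(sup), max(sup)),
        confidence_range=(min(conf), max(conf)),
        lift_range=(min(lift), max(lift)),
        implied_base_rates=rates,
        base_rate_mean=mean,
        base_rate_cv=cv,
        duplicate_lhs_count=dupes,
    )


# ---------------------------------------------------------------------------
# packaged reference tables


class PackagingError(RuntimeError):
    """A packaged reference table does not match its expected shape."""


@dataclass(frozen=True)
class ReferenceRule:
    """One printed rule row: metrics as fractions (support 5.56% -> 0.0556)."""

    lhs: tuple[str, ...]
    rhs: str
    support: float
    confidence: float
    lift: float


@dataclass(frozen=True)
class ReferenceTable:
    """One published analysis: mode, stratifier and its two strata (parts)."""

    analysis: str
    mode: str
    stratifier: str
    parts: dict[str, tuple[ReferenceRule, ...]]


#: analysis id -> (mode, stratifier, expected rows per stratum)
_REFERENCE_INDEX = {
    "risk_by_gender": ("risk", "gender", {"male": 2, "female": 28}),
    "risk_by_age": ("risk", "age_group", {"primary": 1, "middle": 30}),
    "risk_by_leftbehind": ("risk", "left_behind_status", {"non_left_behind": 1, "left_behind": 18}),
    "protective_by_gender": ("protective", "gender", {"male": 12, "female": 9}),
    "protective_by_age": ("protective", "age_group", {"primary": 10, "middle": 12}),
    "protective_by_leftbehind": (
        "protective", "left_behind_status", {"non_left_behind": 17, "left_behind": 2},
    ),
}


def load_reference_tables() -> dict[str, ReferenceTable]:
    """Load the six packaged transcriptions of the published rule tables."""
    tables: dict[str, ReferenceTable] = {}
    for analysis, (mode, stratifier, expected) in _REFERENCE_INDEX.items():
        path = resources.files("famschool.fixtures") / f"{analysis}.tsv"
        with resources.as_file(path) as p:
            df = pd.read_csv(p, sep="\t")
        rhs = DEPRESSION if mode == "risk" else NONDEPRESSION
        parts: dict[str, list[ReferenceRule]] = {}
        for row in df.itertuples(index=False):
            parts.setdefault(row.stratum, []).append(
                ReferenceRule(
                    lhs=tuple(x.strip() for x in row.lhs.split(";")),
                    rhs=rhs,
                    support=row.support_pct / 100.0,
                    confidence=row.confidence_pct / 100.0,
                    lift=row.lift,
                )
            )
        got = {k: len(v) for k, v in parts.items()}
        if got != expected:
            raise PackagingError(f"{analysis}: expected rows {expected}, found {got}")
        tables[analysis] = ReferenceTable(
            analysis, mode, stratifier, {k: tuple(v) for k, v in parts.items()}
        )
    return tables


def check_reference_tables(base_rate_cv_limit: float = 0.015) -> dict:
    """Summaries plus consistency diagnostics for the packaged tables.

    For each analysis the report carries per-part summaries, cross-part metric
    ranges, the implied-base-rate coefficient of variation with a pass flag
    (risk tables are held to ``base_rate_cv_limit``), and any duplicated LHS
    (a known transcription erratum in the printed left-behind risk table).
    """
    report: dict[str, dict] = {}
    for analysis, table in load_reference_tables().items():
        part_reports = {}
        all_rows = []
        for part, rules in table.parts.items():
            summary = summarize_rule_table(rules)
            part_reports[part] = {
                "summary": summary,
                "base_rate_cv_ok": (
                    summary.base_rate_cv is not None
                    and summary.base_rate_cv < base_rate_cv_limit
                ),
                "duplicate_lhs": summary.duplicate_lhs_count,
            }
            all_rows.extend(rules)
        overall = summarize_rule_table(all_rows)
        report[analysis] = {
            "mode": table.mode,
            "stratifier": table.stratifier,
            "parts": part_reports,
            "overall_support_range": overall.support_range,
            "overall_confidence_range": overall.confidence_range,
            "overall_lift_range": overall.lift_range,
        }
    return report


# ---------------------------------------------------------------------------
# reporting


def _round2(x: float) -> Decimal:
    return Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def write_report(tables, summaries, destination) -> None:
    """Full-precision delimited tables plus a rounded human-readable report.

    Byte output is deterministic for fixed input: tables are written in the
    given order, percentages and lift rounded half-up to two decimals.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    lines = ["Association-rule tables", "=" * 23, ""]
    for table, summary in zip(tables, summaries):
        name = f"{table.mode}_{table.stratum.stratifier}_{table.stratum.level}"
        rules_to_frame(table.rules).to_csv(dest / f"rules_{name}.tsv", sep="\t", index=False)
        lines.append(f"[{name}] {summary.rule_count} rules")
        sizes = ", ".join(f"{v} x {k}-item" for k, v in sorted(summary.counts_by_size.items()))
        if sizes:
            lines.append(f"  itemset sizes: {sizes}")
        for rule in table.rules:
            m = rule.metrics
            lines.append(
                f"  {';'.join(sorted(rule.lhs))} => {rule.rhs} "
                f"{_round2(100 * m.support)} {_round2(100 * m.confidence)} {_round2(m.lift)}"
            )
        lines.append("")
    (dest / "report.txt").write_text("\n".join(lines), encoding="utf-8")
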