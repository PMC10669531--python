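"""From-scratch Apriori mining and rule metrics.

Frequent itemsets are found levelwise: frequent 1-itemsets first, then
candidate k-itemsets joined from frequent (k-1)-itemsets sharing a (k-2)-item
prefix under a fixed lexicographic item order, pruned by anti-monotonicity
(every (k-1)-subset must itself be frequent) and counted exactly with one
bitset intersection per candidate.

Rule metrics, for a rule ``X => Y`` over ``n`` transactions with exact counts:

    support    = |{t : X u {Y} in t}| / n
    confidence = |{t : X u {Y} in t}| / |{t : X in t}|
    lift       = confidence / (|{t : Y in t}| / n)

Thresholds are applied as support >= min_sup and confidence >= min_conf
(inclusive) and lift > min_lift (exclusive).  ``min_sup`` applies to the
support of the full itemset ``X u {Y}``.

An exhaustive brute-force enumerator over all non-empty subsets of the item
catalog serves as the independent testing oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from famschool.discretization import Item, Transaction, TransactionSet

__all__ = [
    "FrequentItemSet",
    "RuleMetrics",
    "AssociationRule",
    "MiningParams",
    "apriori_frequent_itemsets",
    "brute_force_frequent_itemsets",
    "rules_for_consequent",
    "evaluate_rule",
    "filter_sort_rules",
    "rules_to_frame",
    "transactions_from_baskets",
    "transactions_from_onehot",
]


@dataclass(frozen=True)
class FrequentItemSet:
    items: frozenset[str]
    support_count: int
    n_transactions: int

    @property
    def support(self) -> float:
        return self.support_count / self.n_transactions

    @property
    def size(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class RuleMetrics:
    """Exact counts behind a rule; metrics are derived, never stored rounded."""

    n_total: int
    n_lhs: int
    n_rhs: int
    n_both: int

    @property
    def support(self) -> float:
        return self.n_both / self.n_total

    @property
    def confidence(self) -> float:
        return self.n_both / self.n_lhs

    @property
    def lift(self) -> float:
        return self.confidence / (self.n_rhs / self.n_total)


@dataclass(frozen=True)
class AssociationRule:
    lhs: frozenset[str]
    rhs: str
    metrics: RuleMetrics

    def __post_init__(self) -> None:
        if not self.lhs:
            raise ValueError("rule LHS must be non-empty")
        if self.rhs in self.lhs:
            raise ValueError("rule LHS and RHS must be disjoint")

    @property
    def itemset_size(self) -> int:
        """k of the underlying k-item set (consequent included)."""
        return len(self.lhs) + 1

    def __str__(self) -> str:
        m = self.metrics
        return (
            f"{';'.join(sorted(self.lhs))} => {self.rhs} "
            f"(sup {100 * m.support:.2f}%, conf {100 * m.confidence:.2f}%, "
            f"lift {m.lift:.2f})"
        )


@dataclass(frozen=True)
class MiningParams:
    min_sup: float
    min_conf: float
    min_lift: float = 1.0
    max_itemset_size: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_sup <= 1.0:
            raise ValueError("min_sup must lie in (0, 1]")
        if not 0.0 < self.min_conf <= 1.0:
            raise ValueError("min_conf must lie in (0, 1]")


def _min_count(min_sup: float, n: int) -> int:
    """Smallest count c with c / n >= min_sup (robust to float fuzz)."""
    return max(math.ceil(min_sup * n - 1e-9), 1)


def _bitmasks(ts: TransactionSet) -> dict[str, int]:
    """Per-label transaction-membership bitsets (bit j = transaction j)."""
    masks: dict[str, int] = {lbl: 0 for lbl in ts.labels}
    for j, t in enumerate(ts.transactions):
        bit = 1 << j
        for lbl in t.items:
            if lbl in masks:
                masks[lbl] |= bit
    return masks


def apriori_frequent_itemsets(
    ts: TransactionSet, min_sup: float, max_size: int | None = None
) -> list[FrequentItemSet]:
    """All itemsets with support >= min_sup, with exact counts.

    Output is deterministically ordered by itemset size, then lexicographically.
    """
    if len(ts) == 0:
        raise ValueError("empty transaction set")
    n = len(ts)
    minc = _min_count(min_sup, n)
    masks = _bitmasks(ts)
    order = sorted(masks)  # fixed global lexicographic item order

    result: list[FrequentItemSet] = []
    level: dict[tuple[str, ...], int] = {}
    for lbl in order:
        m = masks[lbl]
        c = m.bit_count()
        if c >= minc:
            level[(lbl,)] = m
            result.append(FrequentItemSet(frozenset((lbl,)), c, n))

    k = 2
    while level and (max_size is None or k <= max_size):
        frequent_prev = set(level)
        keys = sorted(level)
        nxt: dict[tuple[str, ...], int] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: shared (k-2)-prefix block is contiguous
                cand = a + (b[-1],)
                # anti-monotone prune: every (k-1)-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in frequent_prev
                    for j in range(len(cand) - 2)
                ):
                    continue
                m = level[a] & masks[b[-1]]
                if m.bit_count() >= minc:
                    nxt[cand] = m
        for cand in sorted(nxt):
            result.append(FrequentItemSet(frozenset(cand), nxt[cand].bit_count(), n))
        level = nxt
        k += 1
    return result


def brute_force_frequent_itemsets(
    ts: TransactionSet, min_sup: float, max_catalog: int = 20
) -> list[FrequentItemSet]:
    """Testing oracle: exhaustive enumeration of all non-empty catalog subsets."""
    if len(ts.catalog) > max_catalog:
        raise ValueError(f"catalog has {len(ts.catalog)} items; oracle guard is {max_catalog}")
    n = len(ts)
    minc = _min_count(min_sup, n)
    masks = _bitmasks(ts)
    order = sorted(masks)
    result = []
    for size in range(1, len(order) + 1):
        for combo in itertools.combinations(order, size):
            m = ~0
            for lbl in combo:
                m &= masks[lbl]
            full = (1 << n) - 1
            c = (m & full).bit_count()
            if c >= minc:
                result.append(FrequentItemSet(frozenset(combo), c, n))
    return result


def evaluate_rule(lhs, rhs: str, ts: TransactionSet) -> RuleMetrics:
    """Exact counts and metrics for ``lhs => rhs`` over the transaction set."""
    lhs = frozenset(lhs)
    if not lhs:
        raise ValueError("rule LHS must be non-empty")
    known = set(ts.labels)
    unknown = (lhs | {rhs}) - known
    if unknown:
        raise KeyError(f"unknown item labels: {sorted(unknown)}")
    n_lhs = n_rhs = n_both = 0
    for t in ts.transactions:
        has_lhs = lhs <= t.items
        has_rhs = rhs in t.items
        n_lhs += has_lhs
        n_rhs += has_rhs
        n_both += has_lhs and has_rhs
    if n_lhs == 0:
        raise ZeroDivisionError("LHS occurs in no transaction; confidence undefined")
    return RuleMetrics(len(ts), n_lhs, n_rhs, n_both)


def rules_for_consequent(
    frequent: list[FrequentItemSet],
    rhs: str,
    ts: TransactionSet,
    params: MiningParams,
) -> list[AssociationRule]:
    """Fixed-consequent rules (S \\ {rhs}) => rhs from frequent itemsets S.

    ``frequent`` must have been mined at ``params.min_sup`` on ``ts``; since
    min_sup applies to support(X u {Y}) the support filter is already implied.
    """
    if rhs not in set(ts.labels):
        raise KeyError(f"consequent {rhs!r} not in item catalog")
    support_count = {fs.items: fs.support_count for fs in frequent}
    n = len(ts)
    rhs_count = support_count.get(frozenset((rhs,)))
    if rhs_count is None:
        # consequent itself below min_sup: count it directly
        rhs_count = sum(rhs in t.items for t in ts.transactions)
    rules = []
    for fs in frequent:
        if rhs not in fs.items or fs.size < 2:
            continue
        if params.max_itemset_size is not None and fs.size > params.max_itemset_size:
            continue
        lhs = fs.items - {rhs}
        n_lhs = support_count.get(lhs)
        if n_lhs is None:
            n_lhs = sum(lhs <= t.items for t in ts.transactions)
        metrics = RuleMetrics(n, n_lhs, rhs_count, fs.support_count)
        if (
            metrics.support >= params.min_sup - 1e-12
            and metrics.confidence >= params.min_conf - 1e-12
            and metrics.lift > params.min_lift
        ):
            rules.append(AssociationRule(lhs, rhs, metrics))
    return filter_sort_rules(rules)


def filter_sort_rules(rules) -> list[AssociationRule]:
    """Deterministic order: confidence desc, support desc, lexicographic LHS."""
    return sorted(
        rules,
        key=lambda r: (-r.metrics.confidence, -r.metrics.support, tuple(sorted(r.lhs))),
    )


def rules_to_frame(rules) -> pd.DataFrame:
    """Rules as a delimited-table-ready frame (full precision)."""
    return pd.DataFrame(
        {
            "lhs": [";".join(sorted(r.lhs)) for r in rules],
            "rhs": [r.rhs for r in rules],
            "support": [r.metrics.support for r in rules],
            "confidence": [r.metrics.confidence for r in rules],
            "lift": [r.metrics.lift for r in rules],
            "n_total": [r.metrics.n_total for r in rules],
            "n_lhs": [r.metrics.n_lhs for r in rules],
            "n_rhs": [r.metrics.n_rhs for r in rules],
            "n_both": [r.metrics.n_both for r in rules],
        }
    )


def transactions_from_baskets(path, mode: str = "risk") -> TransactionSet:
    """Read a basket-format file (one comma-separated transaction per line)."""
    transactions = []
    labels: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            items = frozenset(x.strip() for x in line.strip().split(",") if x.strip())
            labels |= items
            transactions.append(Transaction(str(i), items))
    catalog = tuple(Item(lbl, "unknown", lbl) for lbl in sorted(labels))
    return TransactionSet(tuple(transactions), catalog, mode)


def transactions_from_onehot(df: pd.DataFrame, mode: str = "risk") -> TransactionSet:
    """Build a transaction set from a boolean one-hot indicator table."""
    catalog = tuple(Item(str(c), "unknown", str(c)) for c in df.columns)
    transactions = tuple(
        Transaction(str(idx), frozenset(str(c) for c in df.columns if bool(row[c])))
        for idx, row in df.iterrows()
    )
    return TransactionSet(transactions, catalog, mode)
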