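"""Apriori core: worked examples, oracle equivalence, metric identities."""

from fractions import Fraction

import numpy as np
import pytest

from famschool.arm_core import (
    AssociationRule,
    MiningParams,
    RuleMetrics,
    apriori_frequent_itemsets,
    brute_force_frequent_itemsets,
    evaluate_rule,
    filter_sort_rules,
    rules_for_consequent,
)
from famschool.discretization import Item, Transaction, TransactionSet


def random_instance(rng, n_items=None, n_transactions=None) -> TransactionSet:
    n_items = n_items or int(rng.integers(3, 13))
    n_transactions = n_transactions or int(rng.integers(10, 301))
    labels = [f"i{j:02d}" for j in range(n_items)]
    p = rng.uniform(0.05, 0.7, size=n_items)
    transactions = tuple(
        Transaction(str(t), frozenset(l for l, q in zip(labels, p) if rng.random() < q))
        for t in range(n_transactions)
    )
    catalog = tuple(Item(l, "unknown", l) for l in labels)
    return TransactionSet(transactions, catalog, "risk")


class TestFrequentItemsets:
    def test_fix10_at_min_sup_04(self, fix10):
        result = apriori_frequent_itemsets(fix10, 0.4)
        got = {tuple(sorted(fs.items)): fs.support for fs in result}
        assert got == {
            ("A",): 0.6, ("B",): 0.6, ("Y",): 0.6,
            ("A", "B"): 0.4, ("A", "Y"): 0.4, ("B", "Y"): 0.4,
        }

    def test_fix10_above_max_support_is_empty(self, fix10):
        assert apriori_frequent_itemsets(fix10, 0.7) == []

    def test_brute_force_fix10_includes_triple(self, fix10):
        result = brute_force_frequent_itemsets(fix10, 0.3)
        supports = {frozenset(fs.items): fs.support for fs in result}
        assert supports[frozenset("ABY")] == pytest.approx(0.3)

    def test_single_transaction_full_support(self):
        ts = TransactionSet(
            (Transaction("t", frozenset("A")),), (Item("A", "unknown", "A"),), "risk"
        )
        [fs] = brute_force_frequent_itemsets(ts, 1.0)
        assert fs.items == frozenset("A") and fs.support == 1.0

    def test_empty_catalog_brute_force_is_empty(self):
        ts = TransactionSet((Transaction("t", frozenset()),), (), "risk")
        assert brute_force_frequent_itemsets(ts, 0.5) == []

    def test_empty_transaction_set_raises(self):
        ts = TransactionSet((), (Item("A", "unknown", "A"),), "risk")
        with pytest.raises(ValueError):
            apriori_frequent_itemsets(ts, 0.1)

    def test_brute_force_guard_on_large_catalogs(self):
        catalog = tuple(Item(f"x{i}", "unknown", f"x{i}") for i in range(25))
        ts = TransactionSet((Transaction("t", frozenset()),), catalog, "risk")
        with pytest.raises(ValueError, match="guard"):
            brute_force_frequent_itemsets(ts, 0.5)

    def test_deterministic_output_order(self, fix10):
        result = apriori_frequent_itemsets(fix10, 0.3)
        keys = [(fs.size, tuple(sorted(fs.items))) for fs in result]
        assert keys == sorted(keys)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            ts = random_instance(rng)
            min_sup = float(rng.uniform(0.05, 0.5))
            fast = apriori_frequent_itemsets(ts, min_sup)
            slow = brute_force_frequent_itemsets(ts, min_sup)
            assert {fs.items: fs.support_count for fs in fast} == {
                fs.items: fs.support_count for fs in slow
            }

    def test_anti_monotonicity_of_reported_itemsets(self):
        rng = np.random.default_rng(5)
        ts = random_instance(rng, n_items=8, n_transactions=150)
        result = apriori_frequent_itemsets(ts, 0.1)
        support = {fs.items: fs.support_count for fs in result}
        for fs in result:
            for item in fs.items:
                sub = fs.items - {item}
                if sub:
                    assert sub in support
                    assert support[sub] >= fs.support_count


class TestRules:
    PARAMS = MiningParams(min_sup=0.3, min_conf=0.7, min_lift=1.0)

    def test_fix10_worked_example(self, fix10):
        frequent = apriori_frequent_itemsets(fix10, 0.3)
        rules = rules_for_consequent(frequent, "Y", fix10, self.PARAMS)
        assert len(rules) == 1
        [rule] = rules
        assert rule.lhs == frozenset("AB") and rule.rhs == "Y"
        assert rule.metrics.support == pytest.approx(0.30)
        assert rule.metrics.confidence == pytest.approx(0.75)
        assert rule.metrics.lift == pytest.approx(1.25)

    def test_fix10_single_antecedent_below_min_conf(self, fix10):
        # {A} => Y has confidence 4/6 ~ 66.67%, below 70%
        m = evaluate_rule({"A"}, "Y", fix10)
        assert m.confidence == pytest.approx(4 / 6)
        frequent = apriori_frequent_itemsets(fix10, 0.3)
        rules = rules_for_consequent(frequent, "Y", fix10, self.PARAMS)
        assert frozenset("A") not in {r.lhs for r in rules}

    def test_consequent_absent_from_transactions_yields_no_rules(self, fix10):
        ts = TransactionSet(
            tuple(Transaction(t.participant_id, t.items - {"Y"}) for t in fix10.transactions),
            fix10.catalog,
            "risk",
        )
        frequent = apriori_frequent_itemsets(ts, 0.3)
        assert rules_for_consequent(frequent, "Y", ts, self.PARAMS) == []

    def test_unknown_consequent_raises(self, fix10):
        frequent = apriori_frequent_itemsets(fix10, 0.3)
        with pytest.raises(KeyError):
            rules_for_consequent(frequent, "Z", fix10, self.PARAMS)

    def test_lift_above_one_iff_confidence_above_base_rate(self):
        rng = np.random.default_rng(13)
        ts = random_instance(rng, n_items=6, n_transactions=200)
        frequent = apriori_frequent_itemsets(ts, 0.05)
        rhs = ts.labels[0]
        rules = rules_for_consequent(
            frequent, rhs, ts, MiningParams(0.05, 0.01, min_lift=0.0)
        )
        base = sum(rhs in t.items for t in ts.transactions) / len(ts)
        for r in rules:
            assert (r.metrics.lift > 1) == (r.metrics.confidence > base)

    def test_metric_identities_exact_in_rational_arithmetic(self, fix10):
        m = evaluate_rule({"A", "B"}, "Y", fix10)
        sup = Fraction(m.n_both, m.n_total)
        conf = Fraction(m.n_both, m.n_lhs)
        lift = conf / Fraction(m.n_rhs, m.n_total)
        assert float(sup) == m.support
        assert float(conf) == m.confidence
        assert float(lift) == m.lift
        assert 0 <= sup <= conf <= 1


class TestEvaluateRule:
    def test_independent_items_have_lift_near_one(self):
        rng = np.random.default_rng(99)
        n = 20_000
        a, y = rng.random(n) < 0.4, rng.random(n) < 0.3
        transactions = tuple(
            Transaction(str(i), frozenset(l for l, f in (("A", a[i]), ("Y", y[i])) if f))
            for i in range(n)
        )
        catalog = (Item("A", "unknown", "A"), Item("Y", "unknown", "Y"))
        ts = TransactionSet(transactions, catalog, "risk")
        m = evaluate_rule({"A"}, "Y", ts)
        se = np.sqrt((1 - 0.3) / (0.3 * 0.4 * n))  # rough lift SE under independence
        assert abs(m.lift - 1.0) < 3 * se

    def test_empty_lhs_is_contract_error(self, fix10):
        with pytest.raises(ValueError):
            evaluate_rule(set(), "Y", fix10)

    def test_zero_count_lhs_confidence_undefined(self, fix10):
        ts = TransactionSet(
            fix10.transactions, fix10.catalog + (Item("Z", "unknown", "Z"),), "risk"
        )
        with pytest.raises(ZeroDivisionError):
            evaluate_rule({"Z"}, "Y", ts)


class TestSorting:
    def _rule(self, lhs, conf_n, conf_d, sup_n, n=100, rhs_n=50):
        return AssociationRule(
            frozenset(lhs), "Y", RuleMetrics(n, conf_d, rhs_n, conf_n)
        )

    def test_confidence_descending(self):
        r1 = self._rule({"A"}, 80, 100, 80)
        r2 = self._rule({"B"}, 75, 100, 75)
        assert filter_sort_rules([r2, r1]) == [r1, r2]

    def test_support_breaks_confidence_ties(self):
        r1 = self._rule({"A"}, 8, 10, 8)  # conf 0.8, sup 0.08
        r2 = self._rule({"B"}, 4, 5, 4)   # conf 0.8, sup 0.04
        assert filter_sort_rules([r2, r1]) == [r1, r2]

    def test_sort_is_idempotent(self, fix10):
        frequent = apriori_frequent_itemsets(fix10, 0.1)
        rules = rules_for_consequent(frequent, "Y", fix10, MiningParams(0.1, 0.1, 0.0))
        once = filter_sort_rules(rules)
        assert filter_sort_rules(once) == once
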