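from fractions import Fraction
from itertools import chain, combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmrules.mining import (
    MiningConfig,
    MiningError,
    TransactionSet,
    brute_force_rules,
    enumerate_frequent_itemsets,
    mine_rules,
    rules_to_frame,
    sort_rules,
)
from conftest import random_transactions


def counts_of(t: TransactionSet, items: frozenset) -> int:
    return sum(1 for tr in t.transactions if items <= tr)


def test_toy_frequent_itemsets(toy_transactions):
    """Hand enumeration over the 5-transaction toy: exactly H, D, S, HD at 40%."""
    out = enumerate_frequent_itemsets(toy_transactions, 40, 3)
    got = {tuple(sorted(k)): v.count for k, v in out.items()}
    assert got == {("H",): 3, ("D",): 3, ("S",): 2, ("D", "H"): 2}
    assert out[frozenset("H")].support_pct == 60.0


def test_no_itemset_above_full_support(toy_transactions):
    assert enumerate_frequent_itemsets(toy_transactions, 100.0 + 1e-9, 3) == {}


def test_single_transaction_full_support():
    t = TransactionSet("one", (frozenset({"H"}),))
    out = enumerate_frequent_itemsets(t, 50, 2)
    assert out[frozenset({"H"})].support_pct == 100.0


def test_enumerate_rejects_degenerate_inputs(toy_transactions):
    with pytest.raises(MiningError):
        enumerate_frequent_itemsets(TransactionSet("empty", ()), 10, 2)
    with pytest.raises(MiningError):
        enumerate_frequent_itemsets(toy_transactions, 10, 0)
    with pytest.raises(MiningError):
        MiningConfig(min_support_pct=-1)


def test_toy_rule_rejected_by_lift(toy_transactions):
    """D -> H has support 40, confidence 66.67, lift 1.111: passes support and
    confidence but fails the strict lift threshold of 1.5."""
    strict = mine_rules(toy_transactions, MiningConfig(40, 20, 1.5, 5))
    assert strict == []
    lenient = mine_rules(toy_transactions, MiningConfig(40, 20, 1.0, 5))
    by_sig = {r.signature: r for r in lenient}
    r = by_sig[(("D",), "H")]
    assert r.support_pct == pytest.approx(40.0)
    assert r.confidence_pct == pytest.approx(200 / 3)
    assert r.lift == pytest.approx(10 / 9)


def test_perfect_implication():
    """B occurs exactly in the transactions containing A: confidence 100,
    lift = 1 / P(B)."""
    t = TransactionSet(
        "x", tuple(map(frozenset, [{"A", "B"}, {"A", "B"}, {"C"}, {"C"}, {"C"}]))
    )
    rules = mine_rules(t, MiningConfig(20, 20, 1.2, 5))
    r = {x.signature: x for x in rules}[(("A",), "B")]
    assert r.confidence_pct == pytest.approx(100.0)
    assert r.lift == pytest.approx(1 / 0.4)


def test_independent_items_have_unit_lift():
    """Exact product structure: P(A,B) = P(A)P(B), so lift is exactly 1 and
    no rule survives a lift threshold above 1."""
    t = TransactionSet(
        "ind", tuple(map(frozenset, [{"A", "B"}, {"A"}, {"B"}, set()] * 10))
    )
    assert mine_rules(t, MiningConfig(1, 1, 1.0, 5)) == []


def test_support_threshold_boundary_is_inclusive():
    """A rule with joint support of exactly 1.5% is retained (count-exact
    comparison, no float jitter): 3 of 200 transactions."""
    transactions = [frozenset({"A", "B"})] * 3 + [frozenset({"A"})] * 3 + [frozenset()] * 194
    t = TransactionSet("edge", tuple(transactions))
    rules = mine_rules(t, MiningConfig(1.5, 20, 1.5, 5))
    sigs = {r.signature for r in rules}
    assert (("A",), "B") in sigs
    # and at a hair above the boundary it disappears
    assert mine_rules(t, MiningConfig(1.5 + 1e-9, 20, 1.5, 5)) == []


def test_lift_threshold_is_strict():
    """Engineered so lift(A -> B) is exactly 1.5: excluded by the strict >."""
    tr = [frozenset({"A", "B"})] * 3 + [frozenset({"A"})] * 1 + [frozenset({"B"})] * 3 + [
        frozenset()
    ] * 5
    t = TransactionSet("lift", tuple(tr))
    # P(AB)=0.25, P(A)=1/3, P(B)=0.5 => lift = 0.25/(1/6) = 1.5 exactly
    assert mine_rules(t, MiningConfig(1, 1, 1.5, 5)) == []
    kept = mine_rules(t, MiningConfig(1, 1, 1.4999, 5))
    assert (("A",), "B") in {r.signature for r in kept}


def test_max_antecedents_cap():
    t = TransactionSet("cap", (frozenset("ABCD"),) * 10)
    rules = mine_rules(t, MiningConfig(10, 10, 0.5, 2))
    assert rules and all(len(r.antecedent) <= 2 for r in rules)


def test_antecedent_support_dialect():
    """A rule whose joint support is below threshold but antecedent support is
    above appears only in the antecedent dialect."""
    tr = [frozenset({"A", "B"})] * 4 + [frozenset({"A"})] * 12 + [frozenset()] * 84
    t = TransactionSet("d", tuple(tr))
    cfg_rule = MiningConfig(10, 20, 1.2, 5, support_on="rule")  # joint 4% < 10%
    cfg_ante = MiningConfig(10, 20, 1.2, 5, support_on="antecedent")  # P(A)=16%
    assert (("A",), "B") not in {r.signature for r in mine_rules(t, cfg_rule)}
    assert (("A",), "B") in {r.signature for r in mine_rules(t, cfg_ante)}


def test_downward_closure_and_antimonotonicity():
    rng = np.random.default_rng(11)
    t = random_transactions(rng, 8, 300, density=0.4)
    frequent = enumerate_frequent_itemsets(t, 5, 6)
    for items, itemset in frequent.items():
        for k in range(1, len(items)):
            for sub in combinations(sorted(items), k):
                assert frozenset(sub) in frequent
                assert itemset.count <= frequent[frozenset(sub)].count


def test_metric_identities_exact():
    """confidence * P(A) = support and lift * P(B) * 100 = confidence,
    exactly on the underlying counts."""
    rng = np.random.default_rng(5)
    t = random_transactions(rng, 7, 250, density=0.45)
    n = t.n
    for r in mine_rules(t, MiningConfig(2, 10, 1.05, 5)):
        ab = r.antecedent | {r.consequent}
        c_ab = counts_of(t, ab)
        c_a = counts_of(t, r.antecedent)
        c_b = counts_of(t, frozenset({r.consequent}))
        assert Fraction(100 * c_ab, n) == Fraction(c_ab * 100, c_a) * Fraction(c_a, n)
        assert r.support_pct == pytest.approx(100 * c_ab / n, abs=1e-12)
        assert r.confidence_pct == pytest.approx(100 * c_ab / c_a, abs=1e-12)
        assert r.lift == pytest.approx((c_ab * n) / (c_a * c_b), abs=1e-12)
        assert r.confidence_pct >= r.support_pct


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(3, 6), st.integers(5, 60))
def test_oracle_equivalence_property(seed, n_items, n_transactions):
    """Apriori path equals exhaustive brute force on random small instances."""
    rng = np.random.default_rng(seed)
    t = random_transactions(rng, n_items, n_transactions, density=0.5)
    cfg = MiningConfig(
        min_support_pct=float(rng.choice([5, 10, 20])),
        min_confidence_pct=float(rng.choice([10, 30])),
        min_lift=float(rng.choice([1.0, 1.2])),
        max_antecedents=int(rng.choice([2, 5])),
    )
    assert mine_rules(t, cfg) == brute_force_rules(t, cfg)


def test_brute_force_refuses_large_vocabulary():
    t = TransactionSet("big", (frozenset(f"i{j}" for j in range(19)),))
    with pytest.raises(MiningError):
        brute_force_rules(t)


def test_rule_output_sorted_and_framed(toy_transactions):
    rules = mine_rules(toy_transactions, MiningConfig(20, 10, 1.0, 5))
    assert rules == sort_rules(rules)
    df = rules_to_frame(rules)
    assert list(df.columns) == [
        "consequent", "antecedent", "support_pct", "confidence_pct", "lift"
    ]
    assert len(df) == len(rules)


def test_basket_export(toy_transactions):
    lines = toy_transactions.to_basket().splitlines()
    assert lines[0] == "D H" and lines[-1] == "S"
    assert len(lines) == toy_transactions.n
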