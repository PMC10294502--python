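"""From-scratch Apriori frequent-itemset mining and association rules.

Transactions are per-participant condition sets. Mining is level-wise:
frequent single items first, then size-(k+1) candidates built by
prefix-joining frequent size-k itemsets and pruned by downward closure
(every subset of a frequent itemset must itself be frequent). Support is
counted on vertical transaction-id sets, which is fast at cohort scale
and exact.

Rule metrics follow the standard definitions, reported as percentages:

    support(A -> B)    = 100 * P(A, B)
    confidence(A -> B) = 100 * P(A, B) / P(A)
    lift(A -> B)       = confidence(A -> B) / (100 * P(B))

All threshold comparisons are done on exact rationals built from the
integer occurrence counts, so a rule with joint support of exactly the
minimum is kept and no floating-point jitter can flip a boundary case.
The lift threshold is strict (>); support and confidence are inclusive
(>=), and the support threshold applies to the rule's joint support by
default (an ``antecedent`` dialect is available, matching miners that
threshold P(A) instead).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Literal

import pandas as pd


class MiningError(ValueError):
    pass


def _as_fraction(x: float | int | str | Fraction) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(str(x))


@dataclass(frozen=True)
class TransactionSet:
    """One stratum's transactions: a condition set per participant."""

    stratum: str
    transactions: tuple[frozenset[str], ...]

    @property
    def n(self) -> int:
        return len(self.transactions)

    @property
    def vocabulary(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t
        return frozenset(out)

    @classmethod
    def from_profiles(cls, profiles, stratum: str | None = None) -> "TransactionSet":
        label = stratum or (profiles[0].stratum.value if profiles else "?")
        return cls(label, tuple(p.conditions for p in profiles))

    def to_basket(self) -> str:
        """Basket export: one space-separated line of item codes per participant."""
        return "\n".join(" ".join(sorted(t)) for t in self.transactions)


@dataclass(frozen=True)
class Itemset:
    items: frozenset[str]
    count: int
    support_pct: float


@dataclass(frozen=True)
class AssociationRule:
    """A -> B with a single-item consequent; metrics in percent."""

    antecedent: frozenset[str]
    consequent: str
    support_pct: float
    confidence_pct: float
    lift: float

    @property
    def order(self) -> int:
        """Number of distinct conditions involved (|A| + 1)."""
        return len(self.antecedent) + 1

    @property
    def signature(self) -> tuple[tuple[str, ...], str]:
        """Canonical identity: (sorted antecedent, consequent); metrics ignored."""
        return (tuple(sorted(self.antecedent)), self.consequent)

    def rounded(self, ndigits: int = 2) -> "AssociationRule":
        """Table-formatting copy: percentages and lift rounded."""
        return AssociationRule(
            self.antecedent,
            self.consequent,
            round(self.support_pct, ndigits),
            round(self.confidence_pct, ndigits),
            round(self.lift, ndigits),
        )


@dataclass(frozen=True)
class MiningConfig:
    """Mining thresholds: joint support >= 1.5%, confidence >= 20%,
    lift strictly > 1.5, at most 5 antecedent items."""

    min_support_pct: float = 1.5
    min_confidence_pct: float = 20.0
    min_lift: float = 1.5
    max_antecedents: int = 5
    support_on: Literal["rule", "antecedent"] = "rule"

    def __post_init__(self) -> None:
        if self.min_support_pct <= 0 or self.min_confidence_pct <= 0 or self.min_lift <= 0:
            raise MiningError("all thresholds must be positive")
        if self.max_antecedents < 1:
            raise MiningError("max_antecedents must be >= 1")


def _tidsets(t: TransactionSet) -> dict[str, frozenset[int]]:
    out: dict[str, set[int]] = {}
    for i, items in enumerate(t.transactions):
        for item in items:
            out.setdefault(item, set()).add(i)
    return {k: frozenset(v) for k, v in out.items()}


def enumerate_frequent_itemsets(
    t: TransactionSet,
    min_support_pct: float | Fraction,
    max_size: int,
) -> dict[frozenset[str], Itemset]:
    """All itemsets of size <= max_size with support >= min_support_pct.

    Level-wise Apriori: candidates of size k+1 are joins of frequent
    size-k itemsets sharing a (k-1)-prefix, pruned when any k-subset is
    infrequent, then counted by tid-set intersection. Output keys are
    frozensets; iteration order is deterministic (canonical item order).
    """
    if t.n < 1:
        raise MiningError("empty transaction set")
    if max_size < 1:
        raise MiningError("max_size must be >= 1")
    thr = _as_fraction(min_support_pct)
    if thr <= 0:
        raise MiningError("min_support_pct must be positive")
    n = t.n

    def frequent(count: int) -> bool:
        return Fraction(100 * count, n) >= thr

    tid = _tidsets(t)
    result: dict[frozenset[str], Itemset] = {}
    # level 1
    level: dict[tuple[str, ...], frozenset[int]] = {
        (item,): ids for item, ids in sorted(tid.items()) if frequent(len(ids))
    }
    for key, ids in level.items():
        fs = frozenset(key)
        result[fs] = Itemset(fs, len(ids), 100 * len(ids) / n)

    k = 1
    while level and k < max_size:
        keys = sorted(level)
        nxt: dict[tuple[str, ...], frozenset[int]] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: prefix join exhausted
                cand = a + (b[-1],)
                # downward-closure prune: every k-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in level for j in range(len(cand) - 2)
                ):
                    continue
                ids = level[a] & level[b]
                if frequent(len(ids)):
                    nxt[cand] = ids
        for key, ids in nxt.items():
            fs = frozenset(key)
            result[fs] = Itemset(fs, len(ids), 100 * len(ids) / n)
        level = nxt
        k += 1
    return result


def _qualify(
    count_ab: int, count_a: int, count_b: int, n: int, cfg: MiningConfig
) -> tuple[bool, float, float, float]:
    """Apply thresholds on exact rationals; return (keep, support, conf, lift)."""
    sup = Fraction(100 * count_ab, n)
    conf = Fraction(100 * count_ab, count_a)
    lift = Fraction(count_ab * n, count_a * count_b)
    sup_basis = Fraction(100 * count_a, n) if cfg.support_on == "antecedent" else sup
    keep = (
        sup_basis >= _as_fraction(cfg.min_support_pct)
        and conf >= _as_fraction(cfg.min_confidence_pct)
        and lift > _as_fraction(cfg.min_lift)
    )
    return keep, float(sup), float(conf), float(lift)


def derive_rules(
    frequent: dict[frozenset[str], Itemset],
    t: TransactionSet,
    cfg: MiningConfig,
) -> list[AssociationRule]:
    """Single-consequent rules from frequent itemsets, under the thresholds.

    For every frequent itemset of size >= 2 and every single-item
    consequent B, the antecedent is the rest of the itemset. Counts for
    A and {B} are read from the frequent collection (guaranteed present
    by downward closure).
    """
    n = t.n
    rules: list[AssociationRule] = []
    for items, itemset in frequent.items():
        if len(items) < 2 or len(items) > cfg.max_antecedents + 1:
            continue
        for b in items:
            a = items - {b}
            count_a = frequent[a].count
            count_b = frequent[frozenset({b})].count
            if count_b == 0:  # cannot happen for a frequent itemset
                raise MiningError(f"internal: zero-support consequent {b!r}")
            keep, sup, conf, lift = _qualify(itemset.count, count_a, count_b, n, cfg)
            if keep:
                rules.append(AssociationRule(a, b, sup, conf, lift))
    return sort_rules(rules)


def mine_rules(t: TransactionSet, cfg: MiningConfig = MiningConfig()) -> list[AssociationRule]:
    """Apriori end to end: frequent itemsets, then qualified rules.

    In the ``antecedent`` support dialect, itemsets are enumerated down
    to the joint-support floor min_support * min_confidence / 100 (the
    smallest joint support a qualifying rule can have), so no rule is
    lost to pruning.
    """
    floor = _as_fraction(cfg.min_support_pct)
    if cfg.support_on == "antecedent":
        floor = floor * _as_fraction(cfg.min_confidence_pct) / 100
    frequent = enumerate_frequent_itemsets(t, floor, cfg.max_antecedents + 1)
    return derive_rules(frequent, t, cfg)


def brute_force_rules(
    t: TransactionSet, cfg: MiningConfig = MiningConfig()
) -> list[AssociationRule]:
    """Testing oracle: exhaustive rule enumeration without Apriori pruning.

    Counts every itemset by scanning the raw transactions and applies the
    same thresholds. Refuses vocabularies too large to enumerate.
    """
    vocab = sorted(t.vocabulary)
    if len(vocab) > 18:
        raise MiningError(f"vocabulary of {len(vocab)} items too large for brute force")
    n = t.n
    counts: dict[frozenset[str], int] = {}
    for size in range(1, len(vocab) + 1):
        for combo in combinations(vocab, size):
            fs = frozenset(combo)
            counts[fs] = sum(1 for tr in t.transactions if fs <= tr)
    rules: list[AssociationRule] = []
    for items, count_ab in counts.items():
        if len(items) < 2 or len(items) > cfg.max_antecedents + 1 or count_ab == 0:
            continue
        for b in items:
            a = items - {b}
            if counts[a] == 0 or counts[frozenset({b})] == 0:
                continue
            keep, sup, conf, lift = _qualify(
                count_ab, counts[a], counts[frozenset({b})], n, cfg
            )
            if keep:
                rules.append(AssociationRule(a, b, sup, conf, lift))
    return sort_rules(rules)


def sort_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Deterministic order: by consequent, then antecedent lexicographically."""
    return sorted(rules, key=lambda r: (r.consequent, tuple(sorted(r.antecedent))))


def rules_to_frame(rules: Iterable[AssociationRule], ndigits: int = 2) -> pd.DataFrame:
    """Rule table in the published layout: consequent, antecedent
    (semicolon-joined), support, confidence, lift, rounded for display."""
    rows = [
        {
            "consequent": r.consequent,
            "antecedent": ";".join(sorted(r.antecedent)),
            "support_pct": round(r.support_pct, ndigits),
            "confidence_pct": round(r.confidence_pct, ndigits),
            "lift": round(r.lift, ndigits),
        }
        for r in rules
    ]
    return pd.DataFrame(
        rows, columns=["consequent", "antecedent", "support_pct", "confidence_pct", "lift"]
    )


def rules_to_jsonl(rules: Iterable[AssociationRule]) -> str:
    lines = [
        json.dumps(
            {
                "antecedent": sorted(r.antecedent),
                "consequent": r.consequent,
                "support_pct": r.support_pct,
                "confidence_pct": r.confidence_pct,
                "lift": r.lift,
            }
        )
        for r in rules
    ]
    return "\n".join(lines)
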