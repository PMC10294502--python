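"""Duplicate removal and rule-order classification.

A symmetric pair of two-variable rules (A -> B) and (B -> A) carries no
additional predictive information — the pair always co-occurs — so only
the member with the higher confidence is kept. The rule is applied to
order-2 rules only: published rule tables retain both members of
higher-order symmetric pairs, and so does this implementation.
"""

from __future__ import annotations

from .mining import AssociationRule, sort_rules

_ORDER_NAMES = {2: "two-variable", 3: "three-variable", 4: "four-variable",
                5: "five-variable", 6: "six-variable"}


def classify_rule_order(rule: AssociationRule) -> str:
    """Name the rule order: |antecedent| + 1 distinct conditions."""
    return _ORDER_NAMES.get(rule.order, f"{rule.order}-variable")


def dedup_symmetric_pairs(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Drop the lower-confidence member of each order-2 symmetric pair.

    Confidence ties are broken by keeping the rule whose consequent is
    lexicographically smaller, so the result is invariant under input
    order and the operation is idempotent. Rules of order >= 3 pass
    through untouched.
    """
    by_sig = {r.signature: r for r in rules}
    keep: list[AssociationRule] = []
    for r in rules:
        if r.order != 2:
            keep.append(r)
            continue
        (a,) = r.antecedent
        twin = by_sig.get(((r.consequent,), a))
        if twin is None:
            keep.append(r)
        elif r.confidence_pct > twin.confidence_pct:
            keep.append(r)
        elif r.confidence_pct == twin.confidence_pct and r.consequent < twin.consequent:
            keep.append(r)
    return sort_rules(keep)
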