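"""Comparing mined rule sets between the exercise strata.

Rules are matched by signature (canonical antecedent set + consequent;
metrics ignored), diffed into shared and stratum-exclusive parts, and
summarised per disease: how often each condition appears as a consequent
or inside an antecedent in each rule set, and the frequency-increase
statistic 100*(B - A)/A comparing the second set (typically the inactive
group) against the first (the active group).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mining import AssociationRule

RuleSignature = tuple[tuple[str, ...], str]


@dataclass(frozen=True)
class RuleSetDiff:
    shared: frozenset[RuleSignature]
    first_only: frozenset[RuleSignature]
    second_only: frozenset[RuleSignature]

    def swap(self) -> "RuleSetDiff":
        return RuleSetDiff(self.shared, self.second_only, self.first_only)


def diff_rulesets(
    first: list[AssociationRule], second: list[AssociationRule]
) -> RuleSetDiff:
    """Partition the signature union into shared and exclusive parts."""
    s1 = {r.signature for r in first}
    s2 = {r.signature for r in second}
    return RuleSetDiff(
        shared=frozenset(s1 & s2),
        first_only=frozenset(s1 - s2),
        second_only=frozenset(s2 - s1),
    )


def count_appearances(rules: list[AssociationRule]) -> dict[str, tuple[int, int, int]]:
    """Per disease: (consequent count, antecedent count, total), one
    increment per rule row."""
    cons: dict[str, int] = {}
    ante: dict[str, int] = {}
    for r in rules:
        cons[r.consequent] = cons.get(r.consequent, 0) + 1
        for a in r.antecedent:
            ante[a] = ante.get(a, 0) + 1
    out: dict[str, tuple[int, int, int]] = {}
    for d in sorted(set(cons) | set(ante)):
        c, a = cons.get(d, 0), ante.get(d, 0)
        out[d] = (c, a, c + a)
    return out


def percent_increase(a: int, b: int) -> int | None:
    """Frequency increase 100*(b - a)/a, rounded to the nearest integer.

    Undefined (None, printed as "-") when the baseline count a is zero.
    """
    if a == 0:
        return None
    return round(100 * (b - a) / a)


def frequency_table(
    first: list[AssociationRule],
    second: list[AssociationRule],
    labels: tuple[str, str] = ("AG", "IG"),
) -> pd.DataFrame:
    """Per-disease appearance counts in both rule sets plus the increase
    statistic (and an overall rule-count row)."""
    c1, c2 = count_appearances(first), count_appearances(second)
    l1, l2 = labels
    rows = []
    for d in sorted(set(c1) | set(c2)):
        a = c1.get(d, (0, 0, 0))
        b = c2.get(d, (0, 0, 0))
        rows.append(
            {
                "disease": d,
                f"{l1}_consequent": a[0], f"{l1}_antecedent": a[1], f"{l1}_total": a[2],
                f"{l2}_consequent": b[0], f"{l2}_antecedent": b[1], f"{l2}_total": b[2],
                "increase_pct": percent_increase(a[2], b[2]),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["rule_counts"] = {l1: len(first), l2: len(second)}
    df.attrs["rule_count_increase_pct"] = percent_increase(len(first), len(second))
    return df
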