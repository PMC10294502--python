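"""Reference rule tables reported for the restricted 2020 survey cohort.

The original KHPS microdata are access-restricted, so the mined rule
tables cannot be recomputed from raw data here. The published tables are
shipped as machine-readable CSVs instead: one rule per row with its
support, confidence and lift (percent scale), plus a flag marking rules
reported as exclusive to that stratum. They feed regression tests and
the comparison-only mode of the pipeline.

The published per-disease frequency-comparison table is shipped too. Its
inactive-stratum columns (and the hypertension and cardiovascular rows
throughout) match a naive per-rule recount of the rule tables, but three
of its active-stratum antecedent counts do not; where a worked example
cites the printed totals, this fixture supplies them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mining import AssociationRule, sort_rules

_FILES = {"AG": "rules_active.csv", "IG": "rules_inactive.csv"}

#: published headline counts for the two strata
REFERENCE_RULE_COUNTS = {"AG": 23, "IG": 37}
#: published MCD headline: cases / cohort size
REFERENCE_MCD_COUNT = 3317
REFERENCE_COHORT_N = 8477


def _read(name: str) -> pd.DataFrame:
    with resources.files("mmrules.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_rules(stratum: str) -> list[AssociationRule]:
    """The published rule set for one stratum ('AG' or 'IG')."""
    df = _read(_FILES[stratum])
    rules = [
        AssociationRule(
            antecedent=frozenset(str(r["antecedent"]).split(";")),
            consequent=str(r["consequent"]),
            support_pct=float(r["support_pct"]),
            confidence_pct=float(r["confidence_pct"]),
            lift=float(r["lift"]),
        )
        for _, r in df.iterrows()
    ]
    return sort_rules(rules)


def load_reference_exclusive_flags(stratum: str) -> dict[tuple[tuple[str, ...], str], bool]:
    """Signature -> was the rule flagged stratum-exclusive in the source table."""
    df = _read(_FILES[stratum])
    return {
        (tuple(sorted(str(r["antecedent"]).split(";"))), str(r["consequent"])): bool(
            int(r["exclusive"])
        )
        for _, r in df.iterrows()
    }


def load_reference_frequency() -> pd.DataFrame:
    """The published per-disease appearance counts and increase statistic."""
    return _read("frequency_reference.csv")
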