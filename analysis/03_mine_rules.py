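#!/usr/bin/env python
"""Mine association rules separately in the two exercise strata.

Thresholds: rule support >= 1.5%, confidence >= 20%, lift > 1.5, at most
5 antecedents; symmetric two-variable duplicates removed keeping the
higher-confidence direction. Writes results/rules_AG.csv and
results/rules_IG.csv.
"""

from pathlib import Path

from mmrules.cohort import Stratum, build_profiles
from mmrules.io import read_cohort_csv, write_rules_csv
from mmrules.mining import MiningConfig, TransactionSet, mine_rules
from mmrules.postprocess import classify_rule_order, dedup_symmetric_pairs

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    records = read_cohort_csv(ROOT / "scratch" / "cohort.csv")
    profiles = build_profiles(records)
    cfg = MiningConfig()
    for stratum in Stratum:
        members = [p for p in profiles if p.stratum is stratum]
        t = TransactionSet.from_profiles(members, stratum.value)
        rules = dedup_symmetric_pairs(mine_rules(t, cfg))
        write_rules_csv(rules, RESULTS / f"rules_{stratum.value}.csv")
        orders = [classify_rule_order(r) for r in rules]
        print(
            f"{stratum.value}: n={t.n}, {len(rules)} rules "
            f"({', '.join(f'{orders.count(o)} {o}' for o in dict.fromkeys(orders))})"
        )


if __name__ == "__main__":
    main()
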