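#!/usr/bin/env python
"""Compare the mined rule sets of the two strata.

Diffs the rule signatures, counts per-disease appearances, and computes
the frequency-increase statistic 100*(B-A)/A. Writes
results/frequency_comparison.csv and results/rule_diff.json.
"""

import json
from pathlib import Path

from mmrules.io import read_rules_csv
from mmrules.pipeline import compare_rule_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ag = read_rules_csv(RESULTS / "rules_AG.csv")
    ig = read_rules_csv(RESULTS / "rules_IG.csv")
    diff, freq = compare_rule_tables(ag, ig)
    freq.to_csv(RESULTS / "frequency_comparison.csv", index=False)
    payload = {
        "shared": sorted([list(a), c] for a, c in diff.shared),
        "AG_only": sorted([list(a), c] for a, c in diff.first_only),
        "IG_only": sorted([list(a), c] for a, c in diff.second_only),
        "rule_counts": freq.attrs["rule_counts"],
        "rule_count_increase_pct": freq.attrs["rule_count_increase_pct"],
    }
    (RESULTS / "rule_diff.json").write_text(json.dumps(payload, indent=2))
    print(
        f"AG {len(ag)} rules, IG {len(ig)} rules "
        f"(increase {freq.attrs['rule_count_increase_pct']}%)"
    )
    print(f"shared {len(diff.shared)}, AG-only {len(diff.first_only)}, "
          f"IG-only {len(diff.second_only)}")


if __name__ == "__main__":
    main()
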