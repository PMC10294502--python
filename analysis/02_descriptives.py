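#!/usr/bin/env python
"""Participant characteristics and the comorbidity network.

Reads results/cohort.csv, derives condition profiles, and writes the
prevalence table (MCD by sex, age band, education, exercise stratum with
chi-square tests) plus the disease co-occurrence network (edges with at
least 20 co-affected participants) as CSV and GraphML.
"""

from pathlib import Path

from mmrules.cohort import build_profiles
from mmrules.descriptives import network_summary, prevalence_table
from mmrules.io import read_cohort_csv, write_graphml
from mmrules.pipeline import cohort_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    records = read_cohort_csv(ROOT / "scratch" / "cohort.csv")
    profiles = build_profiles(records)
    cohort = cohort_table(records, profiles)

    prevalence = prevalence_table(cohort)
    prevalence.to_csv(RESULTS / "prevalence.csv", index=False)
    total = prevalence[prevalence["variable"] == "total"].iloc[0]
    print(f"eligible cohort: {total['n']}; MCD {total['mcd_count']} ({total['mcd_pct']}%)")

    net = network_summary(profiles, min_links=20)
    net.edge_frame().to_csv(RESULTS / "network_edges.csv", index=False)
    write_graphml(net, RESULTS / "network.graphml")
    top = sorted(net.nodes.items(), key=lambda kv: -kv[1]["prevalence_pct"])[:3]
    print("top prevalences:", ", ".join(f"{d} {a['prevalence_pct']:.1f}%" for d, a in top))
    print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges with >=20 links")


if __name__ == "__main__":
    main()
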