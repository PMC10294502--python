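"""End-to-end pipeline: cohort -> profiles -> stratified mining -> comparison.

One call runs the whole analysis the way the study design prescribes:
eligibility filtering, condition profiling, stratification by exercise
habit, association-rule mining separately in each stratum, symmetric-
duplicate removal, rule-set comparison with the frequency-increase
statistic, descriptive statistics, and the comorbidity network. Every
artefact is written under an output directory together with a manifest
(thresholds, seed, stage counts, package version) that makes the run
reproducible: the same config and seed give byte-identical rule tables.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import ConditionProfile, Stratum, SurveyRecord, build_profiles
from .comparison import RuleSetDiff, diff_rulesets, frequency_table
from .descriptives import ComorbidityNetwork, age_band, network_summary, prevalence_table
from .io import ColumnMap, read_cohort_csv, write_cohort_csv, write_graphml, write_rules_csv
from .mining import AssociationRule, MiningConfig, TransactionSet, mine_rules
from .postprocess import dedup_symmetric_pairs
from .synthetic import SyntheticConfig, config_to_yaml, simulate_cohort


@dataclass(frozen=True)
class RunConfig:
    """Exactly one of ``input_path`` / ``synthetic`` must be given."""

    input_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    seed: int = 0
    mining: MiningConfig = field(default_factory=MiningConfig)
    mcd_includes_obesity: bool = True
    min_links: int = 20
    column_map: ColumnMap = field(default_factory=ColumnMap)
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path / synthetic must be set")


@dataclass
class PipelineResult:
    records: list[SurveyRecord]
    profiles: list[ConditionProfile]
    cohort: pd.DataFrame
    prevalence: pd.DataFrame
    network: ComorbidityNetwork
    rules: dict[str, list[AssociationRule]]
    diff: RuleSetDiff
    frequency: pd.DataFrame
    manifest: dict


def cohort_table(
    records: list[SurveyRecord], profiles: list[ConditionProfile]
) -> pd.DataFrame:
    """Merge demographics with derived profile flags for descriptives."""
    by_id = {r.participant_id: r for r in records}
    rows = []
    for p in profiles:
        r = by_id[p.participant_id]
        rows.append(
            {
                "participant_id": p.participant_id,
                "sex": r.sex,
                "age": r.age,
                "age_band": age_band(r.age),
                "education": r.education,
                "stratum": p.stratum.value,
                "mcd": p.mcd,
                "n_conditions": len(p.conditions),
            }
        )
    return pd.DataFrame(rows)


def _diff_json(diff: RuleSetDiff, labels: tuple[str, str]) -> dict:
    def fmt(sigs):
        return sorted([list(a), c] for a, c in sigs)

    return {
        "shared": fmt(diff.shared),
        f"{labels[0]}_only": fmt(diff.first_only),
        f"{labels[1]}_only": fmt(diff.second_only),
    }


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    if cfg.synthetic is not None:
        records = simulate_cohort(cfg.synthetic, cfg.seed)
    else:
        records = read_cohort_csv(cfg.input_path, cfg.column_map)

    profiles = build_profiles(records, mcd_includes_obesity=cfg.mcd_includes_obesity)
    if not profiles:
        raise ValueError("no eligible participants after filtering")
    cohort = cohort_table(records, profiles)
    prevalence = prevalence_table(cohort)
    network = network_summary(profiles, cfg.min_links)

    rules: dict[str, list[AssociationRule]] = {}
    for stratum in (Stratum.AG, Stratum.IG):
        members = [p for p in profiles if p.stratum is stratum]
        if not members:
            raise ValueError(f"stratum {stratum.value} is empty; cannot mine")
        mined = mine_rules(TransactionSet.from_profiles(members, stratum.value), cfg.mining)
        rules[stratum.value] = dedup_symmetric_pairs(mined)

    diff = diff_rulesets(rules["AG"], rules["IG"])
    frequency = frequency_table(rules["AG"], rules["IG"])

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "input": str(cfg.input_path) if cfg.input_path else "synthetic",
        "mining": {
            "min_support_pct": cfg.mining.min_support_pct,
            "min_confidence_pct": cfg.mining.min_confidence_pct,
            "min_lift": cfg.mining.min_lift,
            "max_antecedents": cfg.mining.max_antecedents,
            "support_on": cfg.mining.support_on,
        },
        "mcd_includes_obesity": cfg.mcd_includes_obesity,
        "min_links": cfg.min_links,
        "counts": {
            "records": len(records),
            "eligible": len(profiles),
            "AG": int((cohort["stratum"] == "AG").sum()),
            "IG": int((cohort["stratum"] == "IG").sum()),
            "rules_AG": len(rules["AG"]),
            "rules_IG": len(rules["IG"]),
            "mcd": int(cohort["mcd"].sum()),
        },
    }

    result = PipelineResult(
        records, profiles, cohort, prevalence, network, rules, diff, frequency, manifest
    )
    if cfg.outdir is not None:
        write_outputs(result, cfg)
    return result


def write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(result.records, out / "cohort.csv")
    result.prevalence.to_csv(out / "prevalence.csv", index=False)
    result.network.edge_frame().to_csv(out / "network_edges.csv", index=False)
    write_graphml(result.network, out / "network.graphml")
    for stratum, rules in result.rules.items():
        write_rules_csv(rules, out / f"rules_{stratum}.csv")
    result.frequency.to_csv(out / "frequency_comparison.csv", index=False)
    (out / "rule_diff.json").write_text(
        json.dumps(_diff_json(result.diff, ("AG", "IG")), indent=2)
    )
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    if cfg.synthetic is not None:
        (out / "synthetic_config.yaml").write_text(config_to_yaml(cfg.synthetic))


def compare_rule_tables(
    first: list[AssociationRule],
    second: list[AssociationRule],
    labels: tuple[str, str] = ("AG", "IG"),
) -> tuple[RuleSetDiff, pd.DataFrame]:
    """Comparison-only mode: diff and frequency table for externally
    supplied (already deduplicated) rule tables."""
    return diff_rulesets(first, second), frequency_table(first, second, labels)
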