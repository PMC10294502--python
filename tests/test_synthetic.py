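import math

import numpy as np
import pytest
from scipy.special import expit, logit

from mmrules.cohort import build_profiles
from mmrules.io import cohort_to_frame
from mmrules.mining import MiningConfig, TransactionSet, mine_rules
from mmrules.synthetic import (
    DEFAULT_MARGINALS,
    PlantedAssociation,
    SyntheticConfig,
    config_from_yaml,
    config_to_yaml,
    expected_stratum_size,
    planted_rule_truth,
    simulate_cohort,
)
from mmrules.vocab import CONDITIONS, OBESITY, RAW_CODES, DEFAULT_GROUPING


def test_reproducible_given_seed():
    cfg = SyntheticConfig(n=500)
    a = cohort_to_frame(simulate_cohort(cfg, 42))
    b = cohort_to_frame(simulate_cohort(cfg, 42))
    c = cohort_to_frame(simulate_cohort(cfg, 43))
    assert a.equals(b)
    assert not a.equals(c)


def test_zero_marginals_give_disease_free_cohort():
    cfg = SyntheticConfig(
        n=300, marginal_prevalence={d: 0.0 for d in CONDITIONS}, planted_associations=()
    )
    profiles = build_profiles(simulate_cohort(cfg, 1))
    assert all(p.conditions == frozenset() and not p.mcd for p in profiles)


def test_marginal_prevalence_recovered():
    """One disease at 40%, no associations: sample prevalence within 3
    binomial standard errors at n=10,000."""
    cfg = SyntheticConfig(
        n=10_000,
        marginal_prevalence={"hypertension": 0.4},
        planted_associations=(),
    )
    profiles = build_profiles(simulate_cohort(cfg, 3))
    prev = np.mean([("hypertension" in p.conditions) for p in profiles])
    se = math.sqrt(0.4 * 0.6 / 10_000)
    assert abs(prev - 0.4) < 3 * se


def test_records_are_eligible_and_valid():
    recs = simulate_cohort(SyntheticConfig(n=200), 5)
    assert all(r.age >= 46 and r.height > 0 and r.weight > 0 for r in recs)
    assert all(r.raw_conditions <= frozenset(RAW_CODES) for r in recs)


def test_raw_code_expansion_recovers_groups():
    """Grouping the emitted raw codes reproduces exactly the planted grouped
    diseases (plus obesity via BMI)."""
    cfg = SyntheticConfig(n=800)
    raw = simulate_cohort(cfg, 9)
    grouped_cfg = SyntheticConfig(**{**cfg.__dict__, "emit_raw_codes": False})
    grouped = simulate_cohort(grouped_cfg, 9)
    for a, b in zip(raw, grouped):
        assert DEFAULT_GROUPING.apply(a.raw_conditions) == b.raw_conditions


def test_bmi_consistent_with_obesity_indicator():
    """BMI is drawn on the matching side of 28, so the profile's obesity flag
    has the planted marginal prevalence (and never disagrees with BMI)."""
    cfg = SyntheticConfig(n=20_000, planted_associations=())
    profiles = build_profiles(simulate_cohort(cfg, 11))
    prev = np.mean([(OBESITY in p.conditions) for p in profiles])
    target = DEFAULT_MARGINALS[OBESITY]
    se = math.sqrt(target * (1 - target) / 20_000)
    assert abs(prev - target) < 3 * se


def test_truth_independence_lift_is_one():
    cfg = SyntheticConfig(planted_associations=())
    t = planted_rule_truth(cfg, "AG", {"hypertension"}, "diabetes")
    assert t.lift == pytest.approx(1.0, abs=1e-12)
    assert t.p_ab == pytest.approx(t.p_a * t.p_b, abs=1e-15)


def test_truth_single_pair_closed_form():
    """Pair {x, y} with log-odds boost log(4), marginals 0.2 each: hand
    closed-form from the sequential construction."""
    cfg = SyntheticConfig(
        marginal_prevalence={"hypertension": 0.2, "diabetes": 0.2},
        planted_associations=(
            PlantedAssociation(frozenset({"hypertension", "diabetes"}), math.log(4)),
        ),
    )
    t = planted_rule_truth(cfg, "IG", {"hypertension"}, "diabetes")
    p_d_given_h = expit(logit(0.2) + math.log(4))  # = 0.5
    p_ab = 0.2 * p_d_given_h
    p_b = p_ab + 0.8 * 0.2
    assert t.p_a == pytest.approx(0.2, abs=1e-12)
    assert t.p_ab == pytest.approx(p_ab, abs=1e-12)
    assert t.p_b == pytest.approx(p_b, abs=1e-12)
    assert t.lift == pytest.approx(p_ab / (0.2 * p_b), abs=1e-12)


def test_truth_stratum_restricted_boost():
    cfg = SyntheticConfig(
        planted_associations=(
            PlantedAssociation(
                frozenset({"hypertension", "depression"}), math.log(3), frozenset({"IG"})
            ),
        )
    )
    ag = planted_rule_truth(cfg, "AG", {"depression"}, "hypertension")
    ig = planted_rule_truth(cfg, "IG", {"depression"}, "hypertension")
    assert ag.lift == pytest.approx(1.0, abs=1e-12)
    assert ig.lift > 1.0


def test_stratum_restricted_plant_raises_lift_only_there():
    """Mining recovers a higher lift in the boosted stratum than the other."""
    cfg = SyntheticConfig(
        n=12_000,
        marginal_prevalence={"hypertension": 0.4, "diabetes": 0.2},
        planted_associations=(
            PlantedAssociation(
                frozenset({"hypertension", "diabetes"}), math.log(4), frozenset({"IG"})
            ),
        ),
    )
    profiles = build_profiles(simulate_cohort(cfg, 21))
    lenient = MiningConfig(1.0, 1.0, 0.1, 5)
    lifts = {}
    for stratum in ("AG", "IG"):
        members = [p for p in profiles if p.stratum.value == stratum]
        rules = mine_rules(TransactionSet.from_profiles(members, stratum), lenient)
        lifts[stratum] = {r.signature: r.lift for r in rules}
    sig = (("hypertension",), "diabetes")
    assert lifts["IG"][sig] > lifts["AG"][sig]
    assert lifts["AG"][sig] == pytest.approx(1.0, abs=0.15)


def test_config_yaml_roundtrip():
    cfg = SyntheticConfig(n=123)
    again = config_from_yaml(config_to_yaml(cfg))
    assert again == cfg


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(marginal_prevalence={"not_a_disease": 0.5})
    with pytest.raises(ValueError):
        PlantedAssociation(frozenset({"hypertension"}), 1.0)
    with pytest.raises(ValueError):
        PlantedAssociation(frozenset({"hypertension", "unknown"}), 1.0)
    with pytest.raises(ValueError):
        SyntheticConfig(exercise_prob=1.5)


def test_expected_stratum_sizes_partition_n():
    cfg = SyntheticConfig(n=8477, exercise_prob=0.556)
    assert expected_stratum_size(cfg, "AG") + expected_stratum_size(cfg, "IG") == 8477
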