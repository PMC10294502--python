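"""Synthetic health-panel cohorts with plantable comorbidity structure.

The generator emulates the survey cohort the analysis assumes: roughly
8,500 participants older than 45, about 55.6% reporting regular
exercise, and 15 binary chronic conditions whose marginal prevalences
default to the study's three printed values (hypertension 40.2%,
spondylosis 18.7%, diabetes 17.6%) plus round placeholders for the rest.

Dependence between conditions uses a sequential logistic model over a
fixed disease order: for disease j,

    logit P(d_j = 1 | earlier diseases) = logit(m_j) + sum of boosts

where a planted association contributes its log-odds boost when all its
other members precede j in the order and are present, and its stratum
restriction covers the participant's stratum. This gives closed-form
joint probabilities by chaining conditionals, so the exact support,
confidence and lift implied by any plant can be computed by enumeration
(:func:`planted_rule_truth`) and compared against mined estimates.

Obesity is drawn as an ordinary indicator in the sequence and the BMI is
then sampled from a lognormal truncated on the matching side of 28, so
profiles rebuilt from height and weight reproduce the planted indicator
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import SurveyRecord
from .vocab import CONDITIONS, DEFAULT_GROUPING, OBESITY

STRATA = ("AG", "IG")

#: marginal prevalences; hypertension/spondylosis/diabetes are the printed
#: cohort values, the other twelve are round placeholder defaults
DEFAULT_MARGINALS: dict[str, float] = {
    "hypertension": 0.402,
    "diabetes": 0.176,
    "chronic_liver_disease": 0.03,
    "gonarthrosis": 0.16,
    "arthritis": 0.06,
    "spondylosis": 0.187,
    "cancer": 0.07,
    "cardiovascular_disease": 0.04,
    "cerebrovascular_disease": 0.03,
    "chronic_respiratory_disease": 0.04,
    "thyroid_disease": 0.06,
    "depression": 0.05,
    "alzheimers_disease": 0.03,
    "chronic_renal_failure": 0.01,
    OBESITY: 0.07,
}

#: age-band shares (46-55, 56-65, 66-75, >75) and education shares
DEFAULT_AGE_BAND_PROBS = (0.217, 0.297, 0.292, 0.195)
DEFAULT_EDUCATION_PROBS = (0.297, 0.183, 0.328, 0.191)
EDUCATION_LEVELS = ("elementary_or_below", "middle", "high", "university_or_above")
_AGE_BANDS = ((46, 55), (56, 65), (66, 75), (76, 90))

#: BMI lognormal: median 23.5 kg/m2, log-sd 0.12 => ~7% above 28
DEFAULT_BMI_LOG_MEAN = math.log(23.5)
DEFAULT_BMI_LOG_SD = 0.12


@dataclass(frozen=True)
class PlantedAssociation:
    """A positive log-odds coupling between a set of conditions.

    The boost raises the conditional odds of the association's last
    member (in the generator's disease order) when all its other members
    are already present; ``strata`` restricts where it applies.
    """

    diseases: frozenset[str]
    log_odds: float
    strata: frozenset[str] = frozenset(STRATA)

    def __post_init__(self) -> None:
        if len(self.diseases) < 2:
            raise ValueError("an association needs at least two diseases")
        unknown = self.diseases - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown diseases in planted association: {sorted(unknown)}")
        if not self.strata <= set(STRATA):
            raise ValueError(f"strata must be within {STRATA}")


def _log(x: float) -> float:
    return math.log(x)


#: default plants: core comorbidity couplings, stronger in the inactive stratum
DEFAULT_PLANTED: tuple[PlantedAssociation, ...] = (
    PlantedAssociation(frozenset({"hypertension", "diabetes"}), _log(2.2), frozenset({"AG"})),
    PlantedAssociation(frozenset({"hypertension", "diabetes"}), _log(3.0), frozenset({"IG"})),
    PlantedAssociation(frozenset({"gonarthrosis", "spondylosis"}), _log(3.0)),
    PlantedAssociation(frozenset({"gonarthrosis", OBESITY}), _log(2.0)),
    PlantedAssociation(
        frozenset({"hypertension", "cardiovascular_disease"}), _log(1.8), frozenset({"AG"})
    ),
    PlantedAssociation(
        frozenset({"hypertension", "cardiovascular_disease"}), _log(2.5), frozenset({"IG"})
    ),
    PlantedAssociation(frozenset({"hypertension", "depression"}), _log(2.0), frozenset({"IG"})),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 8477
    exercise_prob: float = 0.556
    marginal_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    planted_associations: tuple[PlantedAssociation, ...] = DEFAULT_PLANTED
    disease_order: tuple[str, ...] = CONDITIONS
    female_prob: float = 0.56
    age_band_probs: tuple[float, ...] = DEFAULT_AGE_BAND_PROBS
    education_probs: tuple[float, ...] = DEFAULT_EDUCATION_PROBS
    bmi_log_mean: float = DEFAULT_BMI_LOG_MEAN
    bmi_log_sd: float = DEFAULT_BMI_LOG_SD
    emit_raw_codes: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.exercise_prob <= 1:
            raise ValueError("exercise_prob must be a probability")
        if set(self.disease_order) != set(CONDITIONS):
            raise ValueError("disease_order must be a permutation of the 15 conditions")
        for d, p in self.marginal_prevalence.items():
            if d not in CONDITIONS:
                raise ValueError(f"unknown disease in marginals: {d!r}")
            if not 0 <= p <= 1:
                raise ValueError(f"marginal for {d!r} outside [0, 1]")

    def marginal(self, disease: str) -> float:
        return self.marginal_prevalence.get(disease, 0.0)


def config_to_yaml(cfg: SyntheticConfig) -> str:
    doc = {
        "n": cfg.n,
        "exercise_prob": cfg.exercise_prob,
        "marginal_prevalence": dict(cfg.marginal_prevalence),
        "planted_associations": [
            {
                "diseases": sorted(a.diseases),
                "log_odds": a.log_odds,
                "strata": sorted(a.strata),
            }
            for a in cfg.planted_associations
        ],
        "disease_order": list(cfg.disease_order),
        "female_prob": cfg.female_prob,
        "age_band_probs": list(cfg.age_band_probs),
        "education_probs": list(cfg.education_probs),
        "bmi_log_mean": cfg.bmi_log_mean,
        "bmi_log_sd": cfg.bmi_log_sd,
        "emit_raw_codes": cfg.emit_raw_codes,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> SyntheticConfig:
    doc = yaml.safe_load(text)
    planted = tuple(
        PlantedAssociation(
            frozenset(a["diseases"]), float(a["log_odds"]), frozenset(a.get("strata", STRATA))
        )
        for a in doc.pop("planted_associations", [])
    )
    for key in ("disease_order", "age_band_probs", "education_probs"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return SyntheticConfig(planted_associations=planted, **doc)


def _boost_plan(
    cfg: SyntheticConfig,
) -> dict[str, list[tuple[frozenset[str], float, frozenset[str]]]]:
    """For each disease: the plants that boost it (those whose other
    members all precede it in the disease order)."""
    pos = {d: i for i, d in enumerate(cfg.disease_order)}
    plan: dict[str, list[tuple[frozenset[str], float, frozenset[str]]]] = {
        d: [] for d in cfg.disease_order
    }
    for a in cfg.planted_associations:
        last = max(a.diseases, key=pos.__getitem__)
        plan[last].append((a.diseases - {last}, a.log_odds, a.strata))
    return plan


def simulate_cohort(cfg: SyntheticConfig, seed: int) -> list[SurveyRecord]:
    """Draw a cohort: stratum, demographics, conditions, then BMI.

    Deterministic given (config, seed). Every record is eligible (age
    46-90, complete fields).
    """
    rng = np.random.default_rng(seed)
    n = cfg.n
    is_ag = rng.random(n) < cfg.exercise_prob
    sex = np.where(rng.random(n) < cfg.female_prob, "female", "male")
    band_p = np.asarray(cfg.age_band_probs, dtype=float)
    band_idx = rng.choice(len(_AGE_BANDS), size=n, p=band_p / band_p.sum())
    lows = np.array([b[0] for b in _AGE_BANDS])[band_idx]
    highs = np.array([b[1] for b in _AGE_BANDS])[band_idx]
    ages = rng.integers(lows, highs + 1)
    edu_p = np.asarray(cfg.education_probs, dtype=float)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=edu_p / edu_p.sum())

    # sequential logistic draw of the 15 indicators
    plan = _boost_plan(cfg)
    present: dict[str, np.ndarray] = {}
    for d in cfg.disease_order:
        m = cfg.marginal(d)
        if m <= 0.0:
            present[d] = np.zeros(n, dtype=bool)
            continue
        if m >= 1.0:
            present[d] = np.ones(n, dtype=bool)
            continue
        eta = np.full(n, logit(m))
        for others, beta, strata in plan[d]:
            mask = np.ones(n, dtype=bool)
            if strata != frozenset(STRATA):
                mask &= is_ag if strata == {"AG"} else ~is_ag
            for o in others:
                mask &= present[o]
            eta = np.where(mask, eta + beta, eta)
        present[d] = rng.random(n) < expit(eta)

    # BMI consistent with the drawn obesity indicator (truncated lognormal)
    split = norm.cdf(math.log(28.0), loc=cfg.bmi_log_mean, scale=cfg.bmi_log_sd)
    u = 1e-6 + rng.random(n) * (1 - 2e-6)  # keep away from the ppf's infinities
    u = np.where(present[OBESITY], split + u * (1 - split), u * split)
    bmi = np.exp(norm.ppf(u, loc=cfg.bmi_log_mean, scale=cfg.bmi_log_sd))
    height = np.clip(rng.normal(1.61, 0.09, size=n), 1.40, 1.95)
    weight = bmi * height**2

    group_members: dict[str, list[str]] = {}
    for raw, grp in DEFAULT_GROUPING.mapping.items():
        group_members.setdefault(grp, []).append(raw)

    records: list[SurveyRecord] = []
    for i in range(n):
        diseases = [d for d in cfg.disease_order if d != OBESITY and present[d][i]]
        if cfg.emit_raw_codes:
            conds = frozenset(
                group_members[d][rng.integers(len(group_members[d]))] for d in diseases
            )
        else:
            conds = frozenset(diseases)
        records.append(
            SurveyRecord(
                participant_id=f"P{i:05d}",
                sex=str(sex[i]),
                age=int(ages[i]),
                education=str(education[i]),
                regular_exercise=bool(is_ag[i]),
                height=float(round(height[i], 3)),
                weight=float(round(weight[i], 2)),
                raw_conditions=conds,
            )
        )
    return records


# ---------------------------------------------------------------------------
# exact implied truth for planted structure


@dataclass(frozen=True)
class RuleTruth:
    """Exact model-implied metrics of a candidate rule within one stratum."""

    stratum: str
    antecedent: frozenset[str]
    consequent: str
    p_a: float
    p_b: float
    p_ab: float

    @property
    def support_pct(self) -> float:
        return 100 * self.p_ab

    @property
    def confidence_pct(self) -> float:
        return 100 * self.p_ab / self.p_a

    @property
    def lift(self) -> float:
        return self.p_ab / (self.p_a * self.p_b)

    def standard_errors(self, n_stratum: float) -> dict[str, float]:
        """Approximate Monte-Carlo standard errors of the mined estimates
        at stratum size ``n_stratum`` (binomial/delta-method)."""
        c = self.p_ab / self.p_a
        se_support = 100 * math.sqrt(self.p_ab * (1 - self.p_ab) / n_stratum)
        se_conf = 100 * math.sqrt(c * (1 - c) / (n_stratum * self.p_a))
        rel = (1 - c) / (c * n_stratum * self.p_a) + (1 - self.p_b) / (
            n_stratum * self.p_b
        )
        se_lift = self.lift * math.sqrt(rel)
        return {"support_pct": se_support, "confidence_pct": se_conf, "lift": se_lift}


def _closure(cfg: SyntheticConfig, diseases: frozenset[str]) -> list[str]:
    """Diseases whose joint law is entangled with the given set, in order."""
    s = set(diseases)
    changed = True
    while changed:
        changed = False
        for a in cfg.planted_associations:
            if a.diseases & s and not a.diseases <= s:
                s |= a.diseases
                changed = True
    return [d for d in cfg.disease_order if d in s]


def stratum_pattern_probabilities(
    cfg: SyntheticConfig, stratum: str, diseases: frozenset[str]
) -> dict[frozenset[str], float]:
    """Exact joint law over the dependency closure of ``diseases``.

    Enumerates every on/off pattern of the closure, chaining the
    sequential model's conditional probabilities; diseases outside the
    closure are independent of it and are marginalised away implicitly.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    order = _closure(cfg, diseases)
    plan = _boost_plan(cfg)
    out: dict[frozenset[str], float] = {}
    for bits in product((0, 1), repeat=len(order)):
        present = {d: bool(b) for d, b in zip(order, bits)}
        prob = 1.0
        for d in order:
            m = cfg.marginal(d)
            if m <= 0.0:
                p = 0.0
            elif m >= 1.0:
                p = 1.0
            else:
                eta = logit(m)
                for others, beta, strata in plan[d]:
                    if stratum in strata and all(present.get(o, False) for o in others):
                        eta += beta
                p = float(expit(eta))
            prob *= p if present[d] else 1 - p
            if prob == 0.0:
                break
        out[frozenset(d for d in order if present[d])] = prob
    return out


def _event_probability(
    patterns: dict[frozenset[str], float], event: frozenset[str]
) -> float:
    return sum(p for pat, p in patterns.items() if event <= pat)


def planted_rule_truth(
    cfg: SyntheticConfig,
    stratum: str,
    antecedent: frozenset[str] | set[str],
    consequent: str,
) -> RuleTruth:
    """Exact model-implied P(A), P(B), P(A,B) and hence support,
    confidence and lift for a candidate rule in one stratum."""
    a = frozenset(antecedent)
    ab = a | {consequent}
    patterns = stratum_pattern_probabilities(cfg, stratum, ab)
    return RuleTruth(
        stratum=stratum,
        antecedent=a,
        consequent=consequent,
        p_a=_event_probability(patterns, a),
        p_b=_event_probability(patterns, frozenset({consequent})),
        p_ab=_event_probability(patterns, ab),
    )


def expected_stratum_size(cfg: SyntheticConfig, stratum: str) -> float:
    return cfg.n * (cfg.exercise_prob if stratum == "AG" else 1 - cfg.exercise_prob)
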