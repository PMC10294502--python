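"""Survey records -> analysis-ready binary condition profiles.

One participant is a :class:`SurveyRecord` (demographics, exercise habit,
anthropometrics, raw condition flags). Eligibility filtering keeps
participants aged over 45 with complete exercise, condition and
anthropometric data. Each eligible record becomes a
:class:`ConditionProfile`: the set of grouped chronic diseases plus
obesity (BMI strictly above 28), a multimorbidity flag (two or more
conditions), and the exercise stratum — AG for those reporting regular
exercise (walking counts), IG otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

from .vocab import CONDITIONS, GROUPED_DISEASES, OBESITY, GroupingMap, DEFAULT_GROUPING

log = logging.getLogger(__name__)

#: BMI above which a participant is classed obese (strict inequality)
OBESITY_BMI_THRESHOLD = 28.0
#: eligibility: strictly older than 45 integer years, i.e. age >= 46
MIN_ELIGIBLE_AGE = 46
#: multimorbidity = at least this many conditions
MCD_MIN_CONDITIONS = 2


class Stratum(str, Enum):
    """Exercise stratum: active group vs inactive group."""

    AG = "AG"
    IG = "IG"


class InvalidRecordError(ValueError):
    """A record whose fields violate basic validity (not mere missingness)."""


@dataclass(frozen=True)
class SurveyRecord:
    """One raw survey participant.

    ``height`` is in meters, ``weight`` in kilograms. Missing values are
    ``None`` (or NaN for floats); missingness makes a record ineligible
    rather than invalid.
    """

    participant_id: str
    sex: str | None
    age: int | None
    education: str | None
    regular_exercise: bool | None
    height: float | None
    weight: float | None
    raw_conditions: frozenset[str] | None


@dataclass(frozen=True)
class ConditionProfile:
    """The 15-condition binary profile of one participant (a transaction)."""

    participant_id: str
    conditions: frozenset[str]
    mcd: bool
    stratum: Stratum


def compute_bmi(weight: float, height: float, participant_id: str = "?") -> float:
    """Body mass index, weight (kg) divided by squared height (m)."""
    if not (weight > 0) or not (height > 0):
        raise InvalidRecordError(
            f"participant {participant_id}: non-positive weight ({weight}) or height ({height})"
        )
    return weight / height**2


def derive_obesity(bmi: float) -> bool:
    """Obesity flag: BMI strictly greater than 28."""
    if not math.isfinite(bmi):
        raise InvalidRecordError(f"non-finite BMI: {bmi}")
    return bmi > OBESITY_BMI_THRESHOLD


def group_conditions(
    raw_conditions: set[str] | frozenset[str], grouping: GroupingMap = DEFAULT_GROUPING
) -> frozenset[str]:
    """Collapse raw condition codes into grouped diseases.

    Idempotent when given already-grouped codes; raises
    :class:`~mmrules.vocab.VocabularyError` on unknown codes.
    """
    return grouping.apply(raw_conditions)


def build_profile(
    record: SurveyRecord,
    grouping: GroupingMap = DEFAULT_GROUPING,
    *,
    mcd_includes_obesity: bool = True,
) -> ConditionProfile:
    """Derive the condition profile of one (complete) survey record.

    The multimorbidity (MCD) flag counts either all 15 conditions
    (default, obesity included) or only the 14 grouped diseases when
    ``mcd_includes_obesity`` is False.
    """
    bmi = compute_bmi(record.weight, record.height, record.participant_id)
    conditions = set(group_conditions(record.raw_conditions, grouping))
    if derive_obesity(bmi):
        conditions.add(OBESITY)
    counted = conditions if mcd_includes_obesity else conditions - {OBESITY}
    return ConditionProfile(
        participant_id=record.participant_id,
        conditions=frozenset(conditions),
        mcd=len(counted) >= MCD_MIN_CONDITIONS,
        stratum=Stratum.AG if record.regular_exercise else Stratum.IG,
    )


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _complete(r: SurveyRecord) -> bool:
    return not any(
        _is_missing(v)
        for v in (r.age, r.regular_exercise, r.height, r.weight, r.raw_conditions)
    )


def filter_eligible(records: list[SurveyRecord]) -> list[SurveyRecord]:
    """Keep participants aged > 45 with complete exercise/condition/anthropometric data.

    Listwise deletion: dropped records are logged, never fatal.
    """
    kept: list[SurveyRecord] = []
    n_age, n_missing = 0, 0
    for r in records:
        if not _complete(r):
            n_missing += 1
            log.info("dropping %s: incomplete record", r.participant_id)
            continue
        if r.age < MIN_ELIGIBLE_AGE:
            n_age += 1
            continue
        kept.append(r)
    log.info(
        "eligibility: kept %d of %d (%d under age %d, %d incomplete)",
        len(kept), len(records), n_age, MIN_ELIGIBLE_AGE, n_missing,
    )
    return kept


def build_profiles(
    records: list[SurveyRecord],
    grouping: GroupingMap = DEFAULT_GROUPING,
    *,
    mcd_includes_obesity: bool = True,
) -> list[ConditionProfile]:
    """Filter, then profile, every eligible record."""
    return [
        build_profile(r, grouping, mcd_includes_obesity=mcd_includes_obesity)
        for r in filter_eligible(records)
    ]


def stratify(profiles: list[ConditionProfile]) -> dict[Stratum, list[ConditionProfile]]:
    """Partition profiles into the active (AG) and inactive (IG) strata."""
    out: dict[Stratum, list[ConditionProfile]] = {Stratum.AG: [], Stratum.IG: []}
    for p in profiles:
        out[p.stratum].append(p)
    return out
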