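"""Reading and writing the delimited formats the pipeline speaks.

Cohort files are plain CSV/TSV with a header: one row per participant,
demographics plus one 0/1 column per condition code (raw survey codes or
already-grouped diseases — the grouping map is idempotent on the
latter). Column names are bound through a :class:`ColumnMap`, which also
declares the height unit (files recording centimeters are converted on
read). Rule tables round-trip through CSV with semicolon-joined
antecedents; networks export to GraphML via networkx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .cohort import SurveyRecord
from .descriptives import ComorbidityNetwork
from .mining import AssociationRule, rules_to_frame
from .vocab import CONDITIONS, RAW_CODES


@dataclass(frozen=True)
class ColumnMap:
    participant_id: str = "participant_id"
    sex: str = "sex"
    age: str = "age"
    education: str = "education"
    regular_exercise: str = "regular_exercise"
    height: str = "height_m"
    weight: str = "weight_kg"
    height_unit: str = "m"  # "m" or "cm"
    condition_columns: tuple[str, ...] | None = None  # default: any vocabulary code

    def __post_init__(self) -> None:
        if self.height_unit not in ("m", "cm"):
            raise ValueError("height_unit must be 'm' or 'cm'")


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return cast(value)


def read_cohort_csv(
    path: str | Path, colmap: ColumnMap = ColumnMap(), sep: str = ","
) -> list[SurveyRecord]:
    df = pd.read_csv(path, sep=sep)
    if colmap.condition_columns is not None:
        cond_cols = list(colmap.condition_columns)
    else:
        known = set(RAW_CODES) | set(CONDITIONS)
        cond_cols = [c for c in df.columns if c in known]
    scale = 0.01 if colmap.height_unit == "cm" else 1.0
    records = []
    for _, row in df.iterrows():
        flags = {c: row[c] for c in cond_cols}
        if any(pd.isna(v) for v in flags.values()):
            conds = None
        else:
            conds = frozenset(c for c, v in flags.items() if int(v) == 1)
        height = _opt(row[colmap.height], float)
        records.append(
            SurveyRecord(
                participant_id=str(row[colmap.participant_id]),
                sex=_opt(row[colmap.sex], str),
                age=_opt(row[colmap.age], int),
                education=_opt(row[colmap.education], str),
                regular_exercise=_opt(row[colmap.regular_exercise], lambda v: bool(int(v))),
                height=None if height is None else height * scale,
                weight=_opt(row[colmap.weight], float),
                raw_conditions=conds,
            )
        )
    return records


def cohort_to_frame(records: list[SurveyRecord]) -> pd.DataFrame:
    """Cohort as the canonical delimited layout (height in meters)."""
    all_codes = sorted({c for r in records if r.raw_conditions for c in r.raw_conditions})
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "sex": r.sex,
            "age": r.age,
            "education": r.education,
            "regular_exercise": None if r.regular_exercise is None else int(r.regular_exercise),
            "height_m": r.height,
            "weight_kg": r.weight,
        }
        for c in all_codes:
            row[c] = None if r.raw_conditions is None else int(c in r.raw_conditions)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[SurveyRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def write_rules_csv(rules: list[AssociationRule], path: str | Path, ndigits: int = 2) -> None:
    rules_to_frame(rules, ndigits).to_csv(path, index=False)


def read_rules_csv(path: str | Path) -> list[AssociationRule]:
    df = pd.read_csv(path)
    return [
        AssociationRule(
            antecedent=frozenset(str(row["antecedent"]).split(";")),
            consequent=str(row["consequent"]),
            support_pct=float(row["support_pct"]),
            confidence_pct=float(row["confidence_pct"]),
            lift=float(row["lift"]),
        )
        for _, row in df.iterrows()
    ]


def write_graphml(network: ComorbidityNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), str(path))
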