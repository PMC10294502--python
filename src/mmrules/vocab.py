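"""Condition vocabularies and the raw-to-grouped disease map.

The health-panel survey records 30 raw chronic-condition codes. For
multimorbidity analysis these are collapsed into 14 grouped diseases
(e.g. chronic hepatitis, alcoholic hepatitis and hepatic cirrhosis all
become ``chronic_liver_disease``). Obesity, derived from BMI, is the
15th analysis condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

OBESITY = "obesity"


class VocabularyError(KeyError):
    """A condition code outside the declared vocabulary."""


@dataclass(frozen=True)
class GroupingMap:
    """Total map from raw survey condition codes onto grouped diseases.

    Idempotent on already-grouped codes: every group name maps to itself,
    so a file that ships pre-grouped indicators passes through unchanged.
    """

    mapping: dict[str, str]
    groups: tuple[str, ...]
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.mapping.values()) - set(self.groups)
        if missing:
            raise ValueError(f"mapping targets outside declared groups: {sorted(missing)}")
        if set(self.groups) - set(self.mapping.values()):
            raise ValueError("grouping map is not surjective onto the declared groups")
        lookup = dict(self.mapping)
        for g in self.groups:  # idempotence on grouped codes
            lookup.setdefault(g, g)
        object.__setattr__(self, "_lookup", lookup)

    @property
    def raw_codes(self) -> frozenset[str]:
        return frozenset(self.mapping)

    def __getitem__(self, raw_code: str) -> str:
        try:
            return self._lookup[raw_code]
        except KeyError:
            raise VocabularyError(f"unknown condition code: {raw_code!r}") from None

    def apply(self, raw_conditions: set[str] | frozenset[str]) -> frozenset[str]:
        """Image of a raw condition set under the map (never larger)."""
        return frozenset(self[c] for c in raw_conditions)


def load_grouping_map() -> GroupingMap:
    """Load the packaged 30-code -> 14-group map."""
    text = resources.files("mmrules.data").joinpath("grouping_map.yaml").read_text()
    doc = yaml.safe_load(text)
    return GroupingMap(mapping=doc["mapping"], groups=tuple(doc["groups"]))


DEFAULT_GROUPING = load_grouping_map()
RAW_CODES: tuple[str, ...] = tuple(sorted(DEFAULT_GROUPING.raw_codes))
GROUPED_DISEASES: tuple[str, ...] = DEFAULT_GROUPING.groups
#: the 15 analysis conditions: 14 grouped diseases plus BMI-derived obesity
CONDITIONS: tuple[str, ...] = GROUPED_DISEASES + (OBESITY,)
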