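"""Variable dictionary: canonical category codes for household variables.

All classifiers resolve water / sanitation / housing-material / cooking-fuel
codes through a :class:`VariableDictionary`, so that the JMP-style
improved/unimproved and durable/non-durable groupings live in one versioned
config file rather than being scattered through the code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

__all__ = ["VariableDictionary", "default_dictionary"]


@dataclass(frozen=True)
class VariableDictionary:
    """Code lists and their quality groupings for categorical household variables."""

    version: int
    assets: tuple[str, ...]
    water_improved: frozenset[str]
    water_unimproved: frozenset[str]
    water_on_premises: frozenset[str]
    sanitation_improved: frozenset[str]
    sanitation_unimproved: frozenset[str]
    sanitation_none: frozenset[str]
    floor_durable: frozenset[str]
    floor_non_durable: frozenset[str]
    wall_durable: frozenset[str]
    wall_non_durable: frozenset[str]
    roof_durable: frozenset[str]
    roof_non_durable: frozenset[str]
    fuel_clean: frozenset[str]
    fuel_unclean: frozenset[str]

    @property
    def water_codes(self) -> frozenset[str]:
        return self.water_improved | self.water_unimproved

    @property
    def sanitation_codes(self) -> frozenset[str]:
        return self.sanitation_improved | self.sanitation_unimproved | self.sanitation_none

    @property
    def floor_codes(self) -> frozenset[str]:
        return self.floor_durable | self.floor_non_durable

    @property
    def wall_codes(self) -> frozenset[str]:
        return self.wall_durable | self.wall_non_durable

    @property
    def roof_codes(self) -> frozenset[str]:
        return self.roof_durable | self.roof_non_durable

    @property
    def fuel_codes(self) -> frozenset[str]:
        return self.fuel_clean | self.fuel_unclean

    @classmethod
    def from_mapping(cls, raw: dict) -> "VariableDictionary":
        fs = frozenset
        return cls(
            version=int(raw["version"]),
            assets=tuple(raw["assets"]),
            water_improved=fs(raw["water_sources"]["improved"]),
            water_unimproved=fs(raw["water_sources"]["unimproved"]),
            water_on_premises=fs(raw["water_on_premises"]),
            sanitation_improved=fs(raw["sanitation"]["improved"]),
            sanitation_unimproved=fs(raw["sanitation"]["unimproved"]),
            sanitation_none=fs(raw["sanitation"]["none"]),
            floor_durable=fs(raw["floor_materials"]["durable"]),
            floor_non_durable=fs(raw["floor_materials"]["non_durable"]),
            wall_durable=fs(raw["wall_materials"]["durable"]),
            wall_non_durable=fs(raw["wall_materials"]["non_durable"]),
            roof_durable=fs(raw["roof_materials"]["durable"]),
            roof_non_durable=fs(raw["roof_materials"]["non_durable"]),
            fuel_clean=fs(raw["cooking_fuels"]["clean"]),
            fuel_unclean=fs(raw["cooking_fuels"]["unclean"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "VariableDictionary":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


_DEFAULT: VariableDictionary | None = None


def default_dictionary() -> VariableDictionary:
    """The dictionary shipped with the package (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("urbanpoverty.data").joinpath("variable_dictionary.yaml").read_text()
        _DEFAULT = VariableDictionary.from_mapping(yaml.safe_load(text))
    return _DEFAULT
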