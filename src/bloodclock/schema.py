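"""Variable schema for CHARLS-like cohort tables.

The schema declares every column a cohort table may carry — the 24 clock
predictors (16 blood panel variables, sex, a fasting flag, 6 biometric
variables), the 10 disease-history flags, the raw psychosocial and
demographic covariates, and meta variables — together with units, broad
physiological plausibility ranges used by the exclusion stage, categorical
levels, and the covariate → binary-indicator mapping used by the
attribution stage.

A default schema ships with the package as YAML (``data/schema.yaml``);
custom schemas can be loaded from a YAML file of the same shape.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["Variable", "VariableSchema", "SchemaError", "default_schema"]

#: Binary indicators of the attribution design, in canonical report order.
INDICATOR_ORDER = (
    "is_male",
    "is_married",
    "is_widowed",
    "is_rural",
    "rarely_bothered",
    "rarely_lacks_focus",
    "rarely_depressed",
    "rarely_hopeful",
    "rarely_fearful",
    "restless_sleep_is_rare",
    "rarely_happy",
    "rarely_lonely",
    "currently_smoking",
)

#: The eight psychological-wellbeing indicators (subset of INDICATOR_ORDER).
PSYCH_INDICATORS = (
    "rarely_bothered",
    "rarely_lacks_focus",
    "rarely_depressed",
    "rarely_hopeful",
    "rarely_fearful",
    "restless_sleep_is_rare",
    "rarely_happy",
    "rarely_lonely",
)


class SchemaError(ValueError):
    """A schema definition or a table violates the schema contract."""


@dataclass(frozen=True)
class Variable:
    """One declared cohort column."""

    name: str
    role: str  # predictor | meta | disease_flag | covariate | id
    kind: str = "continuous"  # continuous | binary | categorical | ordinal | key
    units: str = ""
    range: tuple[float, float] | None = None
    levels: tuple | None = None
    group: str = ""
    indicator: str | None = None  # target indicator name for psych items


@dataclass
class VariableSchema:
    """Ordered collection of :class:`Variable` declarations with accessors."""

    variables: Sequence[Variable] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name = {v.name: v for v in self.variables}
        if len(self._by_name) != len(self.variables):
            raise SchemaError("duplicate variable names in schema")
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_mapping(cls, doc: dict) -> "VariableSchema":
        variables = []
        for entry in doc["variables"]:
            entry = dict(entry)
            if entry.get("range") is not None:
                entry["range"] = tuple(float(x) for x in entry["range"])
            if entry.get("levels") is not None:
                entry["levels"] = tuple(entry["levels"])
            variables.append(Variable(**entry))
        return cls(variables)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableSchema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        doc = {"variables": []}
        for v in self.variables:
            entry: dict = {"name": v.name, "role": v.role, "kind": v.kind}
            if v.units:
                entry["units"] = v.units
            if v.range is not None:
                entry["range"] = list(v.range)
            if v.levels is not None:
                entry["levels"] = list(v.levels)
            if v.group:
                entry["group"] = v.group
            if v.indicator:
                entry["indicator"] = v.indicator
            doc["variables"].append(entry)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`SchemaError` if broken."""
        preds = self.predictor_names
        if len(preds) != 24:
            raise SchemaError(
                f"schema must declare exactly 24 predictors, found {len(preds)}"
            )
        if len(self.blood_predictors) != 16:
            raise SchemaError("schema must declare 16 blood predictors")
        if len(self.biometric_predictors) != 6:
            raise SchemaError("schema must declare 6 biometric predictors")
        for v in self.variables:
            if v.range is not None:
                low, high = v.range
                if not (low < high):
                    raise SchemaError(f"{v.name}: range low must be < high")

    # -- accessors --------------------------------------------------------
    def __getitem__(self, name: str) -> Variable:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def _names(self, role: str, **filters) -> list[str]:
        out = []
        for v in self.variables:
            if v.role != role:
                continue
            if any(getattr(v, k) != val for k, val in filters.items()):
                continue
            out.append(v.name)
        return out

    @property
    def predictor_names(self) -> list[str]:
        """All 24 clock predictors, in declaration order."""
        return self._names("predictor")

    @property
    def continuous_predictors(self) -> list[str]:
        return [n for n in self.predictor_names if self[n].kind == "continuous"]

    @property
    def blood_predictors(self) -> list[str]:
        return self._names("predictor", group="blood")

    @property
    def biometric_predictors(self) -> list[str]:
        return self._names("predictor", group="biometric")

    @property
    def disease_flags(self) -> list[str]:
        return self._names("disease_flag")

    @property
    def serious_conditions(self) -> list[str]:
        """Conditions that route a participant to the discovery set."""
        return self._names("disease_flag", group="serious")

    @property
    def mild_conditions(self) -> list[str]:
        """Conditions still admitted to the test set."""
        return self._names("disease_flag", group="mild")

    @property
    def covariate_names(self) -> list[str]:
        return self._names("covariate")

    @property
    def psych_items(self) -> list[str]:
        """Raw 4-level frequency items behind the psychological indicators."""
        return self._names("covariate", group="psych")

    def indicator_for(self, item: str) -> str:
        ind = self[item].indicator
        if ind is None:
            raise SchemaError(f"{item!r} has no indicator mapping")
        return ind

    @property
    def indicator_names(self) -> list[str]:
        return list(INDICATOR_ORDER)

    @property
    def column_order(self) -> list[str]:
        """Canonical CSV column order for cohort tables."""
        return [v.name for v in self.variables]


def default_schema() -> VariableSchema:
    """The packaged CHARLS-like default schema."""
    ref = importlib.resources.files("bloodclock.data").joinpath("schema.yaml")
    return VariableSchema.from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))
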