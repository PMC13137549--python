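"""Indicator registries for the dual capability assessment framework.

Two fixed registries drive the whole pipeline: 28 indicators of individual
functional capability (basic and instrumental activities of daily living,
mobility, cognition, communication, behavioural/emotional status, sensory
function, social participation, health status) and 8 indicators of family
caregiving capability (economic capacity, caregiving capacity, emotional
support capacity). Every indicator is scored on the same five-point ordinal
scale: 0 means no capability (heaviest need) and 4 full capability (lightest
need). Registry order is the binding coordinate order of all portrait
vectors, so indicator j of a portrait is always ``registry.indicators[j]``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .errors import RegistryError

INDIVIDUAL = "individual"
FAMILY = "family"
KINDS = (INDIVIDUAL, FAMILY)

#: required registry cardinality per portrait kind
REGISTRY_SIZES = {INDIVIDUAL: 28, FAMILY: 8}

#: names of registries shipped with the package
BUILTIN_REGISTRIES = {
    "individual_v1": "registry_individual_v1.json",
    "family_v1": "registry_family_v1.json",
}

SCALE_MIN = 0
SCALE_MAX = 4


@dataclass(frozen=True)
class IndicatorDefinition:
    """One assessed capability indicator on the 0-4 ordinal scale."""

    id: str
    name: str
    domain: str
    portrait_kind: str
    scale_min: int = SCALE_MIN
    scale_max: int = SCALE_MAX
    level_notes: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.portrait_kind not in KINDS:
            raise RegistryError(f"unknown portrait kind {self.portrait_kind!r}")
        if (self.scale_min, self.scale_max) != (SCALE_MIN, SCALE_MAX):
            raise RegistryError(
                f"indicator {self.id!r}: scale must be {SCALE_MIN}..{SCALE_MAX}, "
                f"got {self.scale_min}..{self.scale_max}"
            )
        if self.level_notes is not None and len(self.level_notes) != 5:
            raise RegistryError(f"indicator {self.id!r}: level_notes must have 5 entries")


@dataclass(frozen=True)
class IndicatorRegistry:
    """Ordered, fixed-cardinality set of indicators of one portrait kind."""

    kind: str
    indicators: tuple[IndicatorDefinition, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise RegistryError(f"unknown registry kind {self.kind!r}")
        expected = REGISTRY_SIZES[self.kind]
        if len(self.indicators) != expected:
            raise RegistryError(
                f"{self.kind} registry must have exactly {expected} indicators, "
                f"got {len(self.indicators)}"
            )
        ids = [ind.id for ind in self.indicators]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RegistryError(f"duplicate indicator ids: {sorted(dupes)}")
        for ind in self.indicators:
            if ind.portrait_kind != self.kind:
                raise RegistryError(
                    f"indicator {ind.id!r} has kind {ind.portrait_kind!r} "
                    f"inside a {self.kind!r} registry"
                )
        object.__setattr__(self, "_index", {i: j for j, i in enumerate(ids)})

    def __len__(self) -> int:
        return len(self.indicators)

    def __iter__(self) -> Iterator[IndicatorDefinition]:
        return iter(self.indicators)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.indicators)

    @property
    def domains(self) -> tuple[str, ...]:
        """Distinct domain labels in first-appearance order."""
        seen: dict[str, None] = {}
        for ind in self.indicators:
            seen.setdefault(ind.domain, None)
        return tuple(seen)

    def position(self, indicator_id: str) -> int:
        try:
            return self._index[indicator_id]
        except KeyError:
            raise RegistryError(f"unknown indicator id {indicator_id!r}") from None

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._index


def _registry_from_dict(doc: dict, source: str) -> IndicatorRegistry:
    try:
        kind = doc["kind"]
        raw = doc["indicators"]
    except KeyError as exc:
        raise RegistryError(f"{source}: missing key {exc}") from None
    indicators = tuple(
        IndicatorDefinition(
            id=entry["id"],
            name=entry.get("name", entry["id"]),
            domain=entry.get("domain", ""),
            portrait_kind=kind,
            scale_min=int(entry.get("scale_min", SCALE_MIN)),
            scale_max=int(entry.get("scale_max", SCALE_MAX)),
            level_notes=tuple(entry["level_notes"]) if entry.get("level_notes") else None,
        )
        for entry in raw
    )
    return IndicatorRegistry(kind=kind, indicators=indicators)


def load_registry(source: str | Path) -> IndicatorRegistry:
    """Load a registry from a built-in name or a JSON file.

    Built-in names are ``individual_v1`` (the 28-indicator individual
    functional capability system) and ``family_v1`` (the 8-indicator family
    caregiving capability system), both in their published table order.
    """
    if isinstance(source, str) and source in BUILTIN_REGISTRIES:
        text = (
            resources.files("caremap.data")
            .joinpath(BUILTIN_REGISTRIES[source])
            .read_text(encoding="utf-8")
        )
        return _registry_from_dict(json.loads(text), source)
    path = Path(source)
    if not path.exists():
        raise RegistryError(
            f"registry source {source!r} is neither a built-in name "
            f"({', '.join(sorted(BUILTIN_REGISTRIES))}) nor an existing file"
        )
    return _registry_from_dict(json.loads(path.read_text(encoding="utf-8")), str(path))
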