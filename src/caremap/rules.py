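"""Capability-to-service-need mapping matrices and stage-1 rule mapping.

A mapping matrix is a *total* rule table: for every indicator of the bound
registry and every score level 0..4 there is exactly one rule listing the
service items that capability state triggers (28x5 = 140 rules for the
individual matrix, 8x5 = 40 for the family matrix). Service items carry an
intervention intensity grade from 1 (lightest, preventive) to 5 (heaviest,
full care); in the shipped fixtures grade = 5 - score_level, mirroring the
table columns running from score 4 (lightest needs) to score 0 (heaviest).

Stage 1 of need identification is purely deterministic: look up every
indicator of a portrait at its observed score and flatten the triggered
items into candidate needs, in registry order.

Shipped fixtures:

* ``family_v1`` — the full 8x5 family caregiving matrix, transcribed from
  the published table.
* ``individual_demo`` — the three published illustrative individual
  indicators (eating, personal grooming, bathing) transcribed, padded to
  totality for the remaining 25 indicators with template items marked
  ``provenance=synthetic`` in the CSV.
"""
from __future__ import annotations

import csv
import io as _io
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import RuleMatrixError
from .portraits import Portrait
from .registry import KINDS, SCALE_MAX, SCALE_MIN, IndicatorRegistry

#: controlled service category vocabulary, in canonical (tie-break) order
CATEGORIES = (
    "daily living assistance",
    "nursing",
    "rehabilitation",
    "safety/home modification",
    "nutrition",
    "psychological support",
    "social participation",
    "financial/welfare linkage",
    "caregiver training",
    "monitoring",
)
_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}

INTENSITY_MIN = 1
INTENSITY_MAX = 5

BUILTIN_MATRICES = {
    "family_v1": "rules_family_v1.csv",
    "individual_demo": "rules_individual_demo.csv",
}

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Casefolded, whitespace-collapsed service label (dedup key part)."""
    return _WS.sub(" ", label.strip()).casefold()


def category_rank(category: str) -> tuple[int, str]:
    """Sort key placing controlled categories first, unknown ones after."""
    return (_CATEGORY_RANK.get(category, len(CATEGORIES)), category)


@dataclass(frozen=True)
class ServiceItem:
    """One community service with its intervention intensity grade."""

    label: str
    category: str
    intensity_grade: int

    def __post_init__(self) -> None:
        if not self.label.strip():
            raise RuleMatrixError("service item label must be nonempty")
        if not INTENSITY_MIN <= self.intensity_grade <= INTENSITY_MAX:
            raise RuleMatrixError(
                f"intensity grade must be {INTENSITY_MIN}..{INTENSITY_MAX}, "
                f"got {self.intensity_grade} for {self.label!r}"
            )

    @property
    def dedup_key(self) -> tuple[str, str]:
        return (normalize_label(self.label), self.category)


@dataclass(frozen=True)
class MappingRule:
    """Service items triggered by one (indicator, score level) state."""

    portrait_kind: str
    indicator_id: str
    score_level: int
    items: tuple[ServiceItem, ...]

    def __post_init__(self) -> None:
        if self.portrait_kind not in KINDS:
            raise RuleMatrixError(f"unknown portrait kind {self.portrait_kind!r}")
        if not SCALE_MIN <= self.score_level <= SCALE_MAX:
            raise RuleMatrixError(
                f"score level {self.score_level} outside {SCALE_MIN}..{SCALE_MAX}"
            )
        if not self.items:
            raise RuleMatrixError(
                f"rule ({self.indicator_id}, {self.score_level}) has no service items"
            )


@dataclass(frozen=True)
class MappingMatrix:
    """Total rule table bound to an indicator registry."""

    kind: str
    registry: IndicatorRegistry
    rules: dict[tuple[str, int], MappingRule]
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.registry.kind != self.kind:
            raise RuleMatrixError(
                f"matrix kind {self.kind!r} does not match registry kind "
                f"{self.registry.kind!r}"
            )
        expected = len(self.registry) * (SCALE_MAX - SCALE_MIN + 1)
        missing = [
            (ind, lvl)
            for ind in self.registry.ids
            for lvl in range(SCALE_MIN, SCALE_MAX + 1)
            if (ind, lvl) not in self.rules
        ]
        if missing:
            raise RuleMatrixError(
                f"matrix {self.name!r} is not total: missing {len(missing)} "
                f"cells, first {missing[:3]}"
            )
        if len(self.rules) != expected:
            extra = sorted(set(self.rules) - {
                (ind, lvl)
                for ind in self.registry.ids
                for lvl in range(SCALE_MIN, SCALE_MAX + 1)
            })
            raise RuleMatrixError(
                f"matrix {self.name!r} has {len(self.rules)} rules, expected "
                f"{expected}; unknown keys {extra[:3]}"
            )

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class CandidateNeed:
    """A rule-triggered service item with its provenance trigger."""

    subject_id: str
    item: ServiceItem
    source_kind: str
    trigger_indicator: str
    trigger_score: int


#: a trigger as recorded on merged candidates: (source_kind, indicator, score)
Trigger = tuple[str, str, int]


@dataclass(frozen=True)
class MergedCandidate:
    """Deduplicated candidate carrying every trigger that produced it."""

    subject_id: str
    item: ServiceItem
    triggers: tuple[Trigger, ...]

    @property
    def dedup_key(self) -> tuple[str, str]:
        return self.item.dedup_key

    @property
    def individually_triggered(self) -> bool:
        return all(kind == "individual" for kind, _, _ in self.triggers)


def _rules_from_rows(
    rows: Iterable[dict], registry: IndicatorRegistry, name: str
) -> MappingMatrix:
    grouped: dict[tuple[str, int], list[ServiceItem]] = {}
    kind_seen: set[str] = set()
    for n, row in enumerate(rows, start=1):
        try:
            kind = row["portrait_kind"].strip()
            ind = row["indicator_id"].strip()
            level = int(row["score_level"])
            item = ServiceItem(
                label=row["item_label"].strip(),
                category=row["category"].strip(),
                intensity_grade=int(row["intensity_grade"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RuleMatrixError(f"{name}: bad rule row {n}: {exc}") from None
        kind_seen.add(kind)
        if kind != registry.kind:
            raise RuleMatrixError(
                f"{name}: row {n} kind {kind!r} does not match registry "
                f"kind {registry.kind!r}"
            )
        if ind not in registry:
            raise RuleMatrixError(f"{name}: row {n}: unknown indicator_id {ind!r}")
        if not SCALE_MIN <= level <= SCALE_MAX:
            raise RuleMatrixError(f"{name}: row {n}: score_level {level} outside 0..4")
        grouped.setdefault((ind, level), []).append(item)
    rules = {
        key: MappingRule(
            portrait_kind=registry.kind,
            indicator_id=key[0],
            score_level=key[1],
            items=tuple(items),
        )
        for key, items in grouped.items()
    }
    return MappingMatrix(kind=registry.kind, registry=registry, rules=rules, name=name)


def _rules_from_json(doc: dict, registry: IndicatorRegistry, name: str) -> MappingMatrix:
    rows = []
    for rule in doc.get("rules", []):
        for item in rule.get("items", []):
            rows.append(
                {
                    "portrait_kind": doc.get("kind", registry.kind),
                    "indicator_id": rule.get("indicator_id", ""),
                    "score_level": rule.get("score_level"),
                    "item_label": item.get("label", ""),
                    "category": item.get("category", ""),
                    "intensity_grade": item.get("intensity_grade"),
                }
            )
    return _rules_from_rows(rows, registry, name)


def load_mapping_matrix(source: str | Path, registry: IndicatorRegistry) -> MappingMatrix:
    """Load a rule matrix from a built-in name or a CSV/JSON file.

    The CSV schema is ``portrait_kind, indicator_id, score_level, item_label,
    category, intensity_grade`` (one row per item; extra columns such as
    ``provenance`` are ignored). JSON carries ``kind`` plus ``rules``
    entries with nested ``items``. Loading validates totality against the
    bound registry and rejects unknown indicators and duplicate keys.
    """
    if isinstance(source, str) and source in BUILTIN_MATRICES:
        text = (
            resources.files("caremap.data")
            .joinpath(BUILTIN_MATRICES[source])
            .read_text(encoding="utf-8")
        )
        reader = csv.DictReader(_io.StringIO(text))
        return _rules_from_rows(reader, registry, source)
    path = Path(source)
    if not path.exists():
        raise RuleMatrixError(
            f"mapping matrix source {source!r} is neither a built-in name "
            f"({', '.join(sorted(BUILTIN_MATRICES))}) nor an existing file"
        )
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return _rules_from_json(json.loads(text), registry, path.name)
    reader = csv.DictReader(_io.StringIO(text))
    return _rules_from_rows(reader, registry, path.name)


def lookup(matrix: MappingMatrix, indicator_id: str, score: int) -> tuple[ServiceItem, ...]:
    """Service items triggered by ``indicator_id`` at ``score``; pure lookup."""
    try:
        return matrix.rules[(indicator_id, score)].items
    except KeyError:
        raise RuleMatrixError(
            f"no rule for ({indicator_id!r}, {score}) in matrix {matrix.name!r}"
        ) from None


def map_portrait(portrait: Portrait, matrix: MappingMatrix) -> list[CandidateNeed]:
    """Stage-1 rule mapping: one lookup per indicator, in registry order."""
    if portrait.kind != matrix.kind:
        raise RuleMatrixError(
            f"portrait kind {portrait.kind!r} does not match matrix kind {matrix.kind!r}"
        )
    candidates: list[CandidateNeed] = []
    for indicator_id, score in zip(matrix.registry.ids, portrait.scores):
        for item in lookup(matrix, indicator_id, score):
            candidates.append(
                CandidateNeed(
                    subject_id=portrait.subject_id,
                    item=item,
                    source_kind=portrait.kind,
                    trigger_indicator=indicator_id,
                    trigger_score=score,
                )
            )
    return candidates


def merge_candidates(
    individual_needs: Sequence[CandidateNeed],
    family_needs: Sequence[CandidateNeed],
) -> list[MergedCandidate]:
    """Union of both stage-1 lists with deduplication.

    Items sharing a normalized (label, category) key collapse to one
    candidate keeping the highest intensity grade and the union of triggers.
    The result is sorted by dedup key, making the merge commutative and
    idempotent. Both lists must belong to the same subject.
    """
    subjects = {c.subject_id for c in individual_needs} | {
        c.subject_id for c in family_needs
    }
    if len(subjects) > 1:
        raise RuleMatrixError(f"cannot merge candidates of different subjects: {sorted(subjects)}")
    buckets: dict[tuple[str, str], dict] = {}
    for cand in list(individual_needs) + list(family_needs):
        key = cand.item.dedup_key
        trig: Trigger = (cand.source_kind, cand.trigger_indicator, cand.trigger_score)
        bucket = buckets.setdefault(key, {"item": cand.item, "triggers": set()})
        if cand.item.intensity_grade > bucket["item"].intensity_grade:
            bucket["item"] = cand.item
        bucket["triggers"].add(trig)
    subject_id = next(iter(subjects)) if subjects else ""
    return [
        MergedCandidate(
            subject_id=subject_id,
            item=bucket["item"],
            triggers=tuple(sorted(bucket["triggers"])),
        )
        for key, bucket in sorted(buckets.items())
    ]
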