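"""Digital capability portraits: validated ordinal score vectors.

A portrait is one subject's assessment encoded as a fixed-order integer
vector, A_i = (a_i1, ..., a_i28) for individual functional capability and
B_i = (b_i1, ..., b_i8) for family caregiving capability. Validation is
strict: scores must be integers in 0..4 aligned with the registry order;
out-of-range or missing values are rejected, never coerced or imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Integral, Real
from typing import Mapping, Optional, Sequence, Union

from .errors import PortraitError
from .registry import FAMILY, INDIVIDUAL, REGISTRY_SIZES, SCALE_MAX, SCALE_MIN, IndicatorRegistry

#: demographic keys accepted as contextual (never scored) information
DEMOGRAPHIC_FIELDS = ("age", "gender", "living_arrangement", "health_status")


@dataclass(frozen=True)
class IndividualPortrait:
    """Length-28 vector of individual functional capability scores."""

    subject_id: str
    scores: tuple[int, ...]
    kind: str = field(default=INDIVIDUAL, init=False)

    def __post_init__(self) -> None:
        _check_scores(self.scores, REGISTRY_SIZES[INDIVIDUAL], self.subject_id)


@dataclass(frozen=True)
class FamilyPortrait:
    """Length-8 vector of family caregiving capability scores."""

    subject_id: str
    scores: tuple[int, ...]
    kind: str = field(default=FAMILY, init=False)

    def __post_init__(self) -> None:
        _check_scores(self.scores, REGISTRY_SIZES[FAMILY], self.subject_id)


Portrait = Union[IndividualPortrait, FamilyPortrait]


@dataclass(frozen=True)
class DualPortrait:
    """One subject's individual and family portraits, plus optional context."""

    individual: IndividualPortrait
    family: FamilyPortrait
    demographics: Optional[Mapping[str, object]] = None

    def __post_init__(self) -> None:
        if self.individual.subject_id != self.family.subject_id:
            raise PortraitError(
                f"dual portrait mixes subjects {self.individual.subject_id!r} "
                f"and {self.family.subject_id!r}"
            )

    @property
    def subject_id(self) -> str:
        return self.individual.subject_id


def _check_scores(scores: Sequence[int], expected_len: int, subject_id: str) -> None:
    if len(scores) != expected_len:
        raise PortraitError(
            f"subject {subject_id!r}: expected {expected_len} scores, got {len(scores)}"
        )
    for j, value in enumerate(scores):
        if not isinstance(value, Integral):
            raise PortraitError(
                f"subject {subject_id!r}: score at position {j} is not an integer ({value!r})"
            )
        if not SCALE_MIN <= int(value) <= SCALE_MAX:
            raise PortraitError(
                f"subject {subject_id!r}: score {int(value)} at position {j} "
                f"outside {SCALE_MIN}..{SCALE_MAX}"
            )


def _as_int(value: object, position: int, subject_id: str) -> int:
    """Accept ints and integral floats (CSV round-trips); reject anything else."""
    if isinstance(value, bool):
        raise PortraitError(f"subject {subject_id!r}: boolean score at position {position}")
    if isinstance(value, Integral):
        return int(value)
    if isinstance(value, Real) and float(value).is_integer():
        return int(value)
    if isinstance(value, str):
        stripped = value.strip()
        if stripped.lstrip("+-").isdigit():
            return int(stripped)
    raise PortraitError(
        f"subject {subject_id!r}: non-integer score {value!r} at position {position}"
    )


def validate_portrait(
    registry: IndicatorRegistry, subject_id: str, raw_scores: Sequence[object]
) -> Portrait:
    """Validate raw scores against a registry and return a typed portrait.

    ``raw_scores`` must be aligned with the registry's indicator order.
    Raises :class:`PortraitError` on length mismatch, non-integer values,
    missing values (None/NaN) or scores outside 0..4.
    """
    if len(raw_scores) != len(registry):
        raise PortraitError(
            f"subject {subject_id!r}: {registry.kind} portrait needs "
            f"{len(registry)} scores, got {len(raw_scores)}"
        )
    values = []
    for j, value in enumerate(raw_scores):
        if value is None or (isinstance(value, float) and value != value):
            raise PortraitError(
                f"subject {subject_id!r}: missing score for indicator "
                f"{registry.ids[j]!r} (position {j})"
            )
        values.append(_as_int(value, j, subject_id))
    cls = IndividualPortrait if registry.kind == INDIVIDUAL else FamilyPortrait
    return cls(subject_id=str(subject_id), scores=tuple(values))
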