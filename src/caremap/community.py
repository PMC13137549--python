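"""Community-level capability matrices and summaries.

Stacking all N portraits of one kind row-wise gives the community capability
matrix (N x 28 for individual functional capability, N x 8 for family
caregiving capability). The matrix supports distribution/heterogeneity
profiling per indicator and simple threshold policies for flagging
potentially high-risk subjects.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CaremapError, ConfigError
from .portraits import FamilyPortrait, IndividualPortrait, Portrait
from .registry import FAMILY, INDIVIDUAL, REGISTRY_SIZES, SCALE_MAX, SCALE_MIN, IndicatorRegistry


@dataclass(frozen=True)
class CommunityMatrix:
    """Row-wise aggregation of same-kind portraits, order preserving."""

    kind: str
    subject_ids: tuple[str, ...]
    scores: np.ndarray  # shape (N, 28) or (N, 8), dtype int

    def __post_init__(self) -> None:
        width = REGISTRY_SIZES[self.kind]
        if self.scores.ndim != 2 or self.scores.shape != (len(self.subject_ids), width):
            raise CaremapError(
                f"{self.kind} community matrix must be "
                f"{len(self.subject_ids)}x{width}, got {self.scores.shape}"
            )

    def __len__(self) -> int:
        return len(self.subject_ids)

    def row(self, i: int) -> Portrait:
        """Recover subject i's portrait exactly (lossless aggregation)."""
        cls = IndividualPortrait if self.kind == INDIVIDUAL else FamilyPortrait
        return cls(subject_id=self.subject_ids[i], scores=tuple(int(v) for v in self.scores[i]))


def assemble_community_matrix(portraits: Sequence[Portrait]) -> CommunityMatrix:
    """Stack same-kind portraits into a community matrix, in input order."""
    if not portraits:
        raise CaremapError("cannot assemble a community matrix from zero portraits")
    kinds = {p.kind for p in portraits}
    if len(kinds) > 1:
        raise CaremapError(f"mixed portrait kinds: {sorted(kinds)}")
    ids = [p.subject_id for p in portraits]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CaremapError(f"duplicate subject_ids: {dupes}")
    scores = np.array([p.scores for p in portraits], dtype=int)
    return CommunityMatrix(kind=portraits[0].kind, subject_ids=tuple(ids), scores=scores)


def community_profile(
    matrix: CommunityMatrix, registry: Optional[IndicatorRegistry] = None
) -> pd.DataFrame:
    """Per-indicator score distribution across the community.

    Returns a DataFrame with one row per indicator and columns
    ``count_0 .. count_4`` (summing to N), ``mean`` and ``share_le_1``
    (share of subjects scoring at most 1, the heavier-need end).
    """
    if registry is not None and registry.kind != matrix.kind:
        raise CaremapError(
            f"registry kind {registry.kind!r} does not match matrix kind {matrix.kind!r}"
        )
    levels = range(SCALE_MIN, SCALE_MAX + 1)
    counts = {
        f"count_{lvl}": (matrix.scores == lvl).sum(axis=0).astype(int) for lvl in levels
    }
    frame = pd.DataFrame(counts)
    frame["mean"] = matrix.scores.mean(axis=0)
    frame["share_le_1"] = (matrix.scores <= 1).mean(axis=0)
    frame.index = (
        list(registry.ids)
        if registry is not None
        else [f"indicator_{j}" for j in range(matrix.scores.shape[1])]
    )
    frame.index.name = "indicator"
    return frame


@dataclass(frozen=True)
class HighRiskPolicy:
    """Flag subjects with at least ``min_indicators`` scores <= ``max_score``."""

    min_indicators: int = 3
    max_score: int = 1

    def __post_init__(self) -> None:
        if self.min_indicators < 1:
            raise ConfigError("high-risk policy requires min_indicators >= 1")
        if not SCALE_MIN <= self.max_score <= SCALE_MAX:
            raise ConfigError(
                f"high-risk policy max_score must be in {SCALE_MIN}..{SCALE_MAX}"
            )


def flag_high_risk(
    matrix: CommunityMatrix, policy: HighRiskPolicy | None = None
) -> list[str]:
    """Subjects meeting the low-capability threshold policy, in matrix order."""
    policy = policy or HighRiskPolicy()
    low = (matrix.scores <= policy.max_score).sum(axis=1)
    return [sid for sid, n in zip(matrix.subject_ids, low) if n >= policy.min_indicators]
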