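"""Two-stage hybrid service-need recommendation.

Stage 1 (rule-based, in :mod:`caremap.rules`) decides *which* services are
candidates; stage 2 re-prioritizes them and never adds or removes any. The
priority of a candidate is a convex combination of three components in
[0, 1]:

``total = w_severity * severity + w_family * family_deficit + w_support * support``

* **severity** — how impaired the triggering capability is,
  (4 - trigger score)/4, using the most severe trigger after merging;
* **family_deficit** — the caregiving-environment moderator: for
  individually-triggered candidates, (4 - mean family score)/4 (a weaker
  household raises the priority of external services); for family-triggered
  candidates, the severity of the triggering family indicator;
* **support** — user-based collaborative filtering: the similarity-weighted
  share of the subject's k nearest neighbors (by cosine similarity over the
  concatenated, 0-1 scaled 36-dimensional dual portrait vector) whose own
  stage-1 candidate set contains the same service.

Totals are stratified into high / medium / low priority levels with closed
lower bounds (defaults 2/3 and 1/3). All tie-breaks are deterministic.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError
from .portraits import DualPortrait
from .registry import SCALE_MAX
from .rules import (
    CandidateNeed,
    MappingMatrix,
    MergedCandidate,
    ServiceItem,
    category_rank,
    map_portrait,
    merge_candidates,
)

COSINE = "cosine"
INVERSE_EUCLIDEAN = "inverse_euclidean"
METRICS = (COSINE, INVERSE_EUCLIDEAN)

DUAL_VECTOR_LENGTH = 36


@dataclass(frozen=True)
class SimilarityConfig:
    """Parameters of the collaborative-filtering stage and score fusion."""

    metric: str = COSINE
    k_neighbors: int = 5
    min_similarity: float = 0.0
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2)  # severity, family, support
    seed: Optional[int] = None  # reserved; default tie-breaks are deterministic

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigError(f"unknown similarity metric {self.metric!r}")
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ConfigError("min_similarity must be in [0, 1]")
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ConfigError("weights must be three nonnegative numbers")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1, got {sum(self.weights)}")


@dataclass(frozen=True)
class StratificationThresholds:
    """Closed lower bounds of the high and medium priority strata."""

    high: float = 2.0 / 3.0
    medium: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.medium < self.high < 1.0:
            raise ConfigError(
                f"thresholds must satisfy 0 < medium < high < 1, got "
                f"medium={self.medium}, high={self.high}"
            )

    def level(self, total: float) -> str:
        if total >= self.high:
            return "high"
        if total >= self.medium:
            return "medium"
        return "low"


@dataclass(frozen=True)
class PriorityScore:
    severity_component: float
    family_deficit_component: float
    support_component: float
    total: float


@dataclass(frozen=True)
class Recommendation:
    item: ServiceItem
    priority_level: Optional[str]
    intensity_grade: int
    score: PriorityScore
    triggers: tuple[tuple[str, str, int], ...]


@dataclass(frozen=True)
class RecommendationList:
    """Ordered recommendations (descending total) for one subject."""

    subject_id: str
    recommendations: tuple[Recommendation, ...]
    config: SimilarityConfig = field(default_factory=SimilarityConfig)
    thresholds: StratificationThresholds = field(default_factory=StratificationThresholds)
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.recommendations)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "config": dataclasses.asdict(self.config),
            "thresholds": dataclasses.asdict(self.thresholds),
            "provenance": dict(self.provenance),
            "recommendations": [
                {
                    "label": rec.item.label,
                    "category": rec.item.category,
                    "intensity_grade": rec.intensity_grade,
                    "priority_level": rec.priority_level,
                    "score": {
                        "severity": rec.score.severity_component,
                        "family_deficit": rec.score.family_deficit_component,
                        "support": rec.score.support_component,
                        "total": rec.score.total,
                    },
                    "triggers": [list(t) for t in rec.triggers],
                }
                for rec in self.recommendations
            ],
        }


def dual_vector(dual: DualPortrait) -> np.ndarray:
    """Concatenated (individual then family) scores scaled into [0, 1]."""
    raw = np.array(dual.individual.scores + dual.family.scores, dtype=float)
    return raw / SCALE_MAX


def similarity(u: np.ndarray, v: np.ndarray, config: SimilarityConfig | None = None) -> float:
    """Similarity in [0, 1] between two equal-length capability vectors.

    Cosine similarity with the convention that any comparison involving a
    zero vector is 0; or inverse Euclidean 1/(1 + ||u - v||). Symmetric,
    and 1 exactly for identical nonzero vectors.
    """
    config = config or SimilarityConfig()
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ConfigError(f"vector length mismatch: {u.shape} vs {v.shape}")
    if config.metric == COSINE:
        nu = float(np.linalg.norm(u))
        nv = float(np.linalg.norm(v))
        if nu == 0.0 or nv == 0.0:
            return 0.0
        return float(np.dot(u, v) / (nu * nv))
    return float(1.0 / (1.0 + np.linalg.norm(u - v)))


@dataclass(frozen=True)
class Neighbor:
    dual: DualPortrait
    similarity: float

    @property
    def subject_id(self) -> str:
        return self.dual.subject_id


def neighbors(
    target: DualPortrait,
    population: Sequence[DualPortrait],
    config: SimilarityConfig | None = None,
) -> list[Neighbor]:
    """Top-k most similar subjects, deterministic.

    The target itself is excluded by subject_id; candidates below
    ``min_similarity`` are dropped; ties are broken by lexicographically
    smaller subject_id. May return fewer than k (including zero).
    """
    config = config or SimilarityConfig()
    tv = dual_vector(target)
    scored = [
        Neighbor(dual=other, similarity=similarity(tv, dual_vector(other), config))
        for other in population
        if other.subject_id != target.subject_id
    ]
    eligible = [n for n in scored if n.similarity >= config.min_similarity]
    eligible.sort(key=lambda n: (-n.similarity, n.subject_id))
    return eligible[: config.k_neighbors]


def neighbor_support(
    candidate: MergedCandidate | CandidateNeed,
    neighbor_set: Sequence[Neighbor],
    neighbor_candidates: Mapping[str, frozenset | set],
) -> float:
    """Similarity-weighted share of neighbors whose stage-1 set has the item.

    sum_j sim_j * 1[key in set_j] / sum_j sim_j, and 0 for an empty (or
    zero-similarity) neighbor set. ``neighbor_candidates`` maps neighbor
    subject_id to the set of dedup keys of its stage-1 candidates.
    """
    if not neighbor_set:
        return 0.0
    key = candidate.item.dedup_key
    total_sim = sum(n.similarity for n in neighbor_set)
    if total_sim == 0.0:
        return 0.0
    hit = sum(
        n.similarity
        for n in neighbor_set
        if key in neighbor_candidates.get(n.subject_id, frozenset())
    )
    return hit / total_sim


def base_priority(candidate: MergedCandidate, dual: DualPortrait) -> tuple[float, float]:
    """(severity, family_deficit) components in [0, 1] for one candidate.

    Severity comes from the most severe (lowest-score) trigger. The family
    deficit of a candidate with any family trigger is that trigger's own
    severity; a purely individually-triggered candidate inherits the
    household-level deficit (4 - mean family score)/4, so weaker family
    caregiving capability uniformly raises the urgency of external services.
    """
    min_score = min(score for _, _, score in candidate.triggers)
    severity = (SCALE_MAX - min_score) / SCALE_MAX
    family_scores = [s for kind, _, s in candidate.triggers if kind == "family"]
    if family_scores:
        family_deficit = (SCALE_MAX - min(family_scores)) / SCALE_MAX
    else:
        mean_family = float(np.mean(dual.family.scores))
        family_deficit = (SCALE_MAX - mean_family) / SCALE_MAX
    return severity, family_deficit


def hybrid_rank(
    candidates: Sequence[MergedCandidate],
    dual: DualPortrait,
    supports: Mapping[tuple[str, str], float],
    config: SimilarityConfig | None = None,
    provenance: Optional[Mapping[str, str]] = None,
) -> RecommendationList:
    """Fuse the three components and sort candidates by descending total.

    ``supports`` maps each candidate's dedup key to its neighbor-support
    value. Ties in total break by higher intensity grade, then canonical
    category order, then label. The output is a permutation of the input.
    """
    config = config or SimilarityConfig()
    w_sev, w_fam, w_sup = config.weights
    recs = []
    for cand in candidates:
        severity, family_deficit = base_priority(cand, dual)
        support = supports.get(cand.dedup_key, 0.0)
        total = w_sev * severity + w_fam * family_deficit + w_sup * support
        recs.append(
            Recommendation(
                item=cand.item,
                priority_level=None,
                intensity_grade=cand.item.intensity_grade,
                score=PriorityScore(severity, family_deficit, support, total),
                triggers=cand.triggers,
            )
        )
    recs.sort(
        key=lambda r: (
            -r.score.total,
            -r.intensity_grade,
            category_rank(r.item.category),
            r.item.label,
        )
    )
    return RecommendationList(
        subject_id=dual.subject_id,
        recommendations=tuple(recs),
        config=config,
        provenance=dict(provenance or {}),
    )


def stratify(
    reclist: RecommendationList,
    thresholds: StratificationThresholds | None = None,
) -> RecommendationList:
    """Assign high/medium/low priority levels from totals alone."""
    thresholds = thresholds or StratificationThresholds()
    recs = tuple(
        dataclasses.replace(rec, priority_level=thresholds.level(rec.score.total))
        for rec in reclist.recommendations
    )
    return dataclasses.replace(reclist, recommendations=recs, thresholds=thresholds)


def stage1_candidates(
    dual: DualPortrait,
    individual_matrix: MappingMatrix,
    family_matrix: MappingMatrix,
) -> list[MergedCandidate]:
    """Rule-based stage 1: map both portraits and merge the candidate lists."""
    return merge_candidates(
        map_portrait(dual.individual, individual_matrix),
        map_portrait(dual.family, family_matrix),
    )


def recommend(
    dual: DualPortrait,
    population: Sequence[DualPortrait],
    individual_matrix: MappingMatrix,
    family_matrix: MappingMatrix,
    config: SimilarityConfig | None = None,
    thresholds: StratificationThresholds | None = None,
) -> RecommendationList:
    """Full two-stage pipeline for one subject; deterministic end to end.

    Stage 1 maps both portraits through their total matrices and merges the
    candidate lists. Stage 2 finds the k most similar subjects in
    ``population`` (the target is excluded if present), computes each
    candidate's neighbor support from the neighbors' own stage-1 sets, fuses
    severity, family deficit and support into a total, sorts, and stratifies
    into priority levels. An empty population yields a rule-only ranking
    (all support components 0).
    """
    config = config or SimilarityConfig()
    thresholds = thresholds or StratificationThresholds()
    candidates = stage1_candidates(dual, individual_matrix, family_matrix)
    neighbor_set = neighbors(dual, population, config)
    neighbor_keys = {
        n.subject_id: frozenset(
            c.dedup_key for c in stage1_candidates(n.dual, individual_matrix, family_matrix)
        )
        for n in neighbor_set
    }
    supports = {
        cand.dedup_key: neighbor_support(cand, neighbor_set, neighbor_keys)
        for cand in candidates
    }
    provenance = {
        "individual_matrix": individual_matrix.name,
        "family_matrix": family_matrix.name,
        "population_size": str(
            sum(1 for p in population if p.subject_id != dual.subject_id)
        ),
    }
    ranked = hybrid_rank(candidates, dual, supports, config, provenance)
    return stratify(ranked, thresholds)
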