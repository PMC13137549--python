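"""Synthetic communities of correlated ordinal capability portraits.

No public dataset of dual capability assessments exists, so testing and
demonstration use a latent-Gaussian threshold generator: each subject draws
a 36-dimensional latent normal vector with an exchangeable within-portrait
correlation (individual block of 28, family block of 8) and a cross-block
correlation, and each coordinate is cut into the ordinal scores 0..4.

Cut points are the normal quantiles of the cumulative Binomial(4, m/4)
distribution, where m is the target mean score, so the marginal score
distribution of an unshifted subject is exactly Binomial(4, m/4) — mean m by
construction, unimodal and symmetric-ish around it, which is what routine
community assessments tend to look like. Optional mixture clusters shift the
latent mean to emulate subpopulations (e.g. a frailer group).

The module also exposes the published worked-example vectors (two community
members and the end-to-end demonstration subject "Mr. Zhang") as validated
fixtures.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError
from .portraits import DualPortrait, FamilyPortrait, IndividualPortrait, Portrait
from .registry import FAMILY, INDIVIDUAL, REGISTRY_SIZES, SCALE_MAX, IndicatorRegistry
from .rules import MappingMatrix, MappingRule, ServiceItem

N_INDIVIDUAL = REGISTRY_SIZES[INDIVIDUAL]
N_FAMILY = REGISTRY_SIZES[FAMILY]
N_TOTAL = N_INDIVIDUAL + N_FAMILY


@dataclass(frozen=True)
class GeneratorProfile:
    """Population parameters of the latent-Gaussian threshold generator.

    ``mean_capability`` is the target marginal mean score (0..4);
    ``domain_correlation`` is the exchangeable latent correlation within each
    portrait block; ``cross_correlation`` couples the individual and family
    blocks; ``cluster_spec`` optionally lists (weight, latent mean shift)
    mixture components, weights summing to 1.
    """

    n: int
    seed: int = 0
    mean_capability: float = 2.5
    domain_correlation: float = 0.6
    cross_correlation: float = 0.3
    cluster_spec: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("population size must be nonnegative")
        if not 0.0 < self.mean_capability < float(SCALE_MAX):
            raise ConfigError("mean_capability must lie strictly inside (0, 4)")
        if not 0.0 <= self.domain_correlation < 1.0:
            raise ConfigError("domain_correlation must be in [0, 1)")
        if self.cluster_spec is not None:
            weights = [w for w, _ in self.cluster_spec]
            if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigError("cluster weights must be nonnegative and sum to 1")
        # infeasible correlation structures are rejected eagerly
        correlation_matrix(self)


def correlation_matrix(profile: GeneratorProfile) -> np.ndarray:
    """36x36 latent correlation implied by the profile; must be PSD."""
    rho_w, rho_c = profile.domain_correlation, profile.cross_correlation
    corr = np.full((N_TOTAL, N_TOTAL), rho_c)
    corr[:N_INDIVIDUAL, :N_INDIVIDUAL] = rho_w
    corr[N_INDIVIDUAL:, N_INDIVIDUAL:] = rho_w
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() < -1e-9:
        raise ConfigError(
            f"infeasible correlation structure (within={rho_w}, cross={rho_c}): "
            "latent correlation matrix is not positive semidefinite"
        )
    return corr


def cut_points(mean_capability: float) -> np.ndarray:
    """Latent thresholds mapping N(0,1) to a Binomial(4, m/4) score marginal."""
    p = mean_capability / SCALE_MAX
    pmf = stats.binom.pmf(np.arange(SCALE_MAX + 1), SCALE_MAX, p)
    cum = np.cumsum(pmf)[:-1]
    return stats.norm.ppf(cum)


def generate_population(
    profile: GeneratorProfile, return_clusters: bool = False
) -> list[DualPortrait] | tuple[list[DualPortrait], np.ndarray]:
    """Draw a synthetic community, deterministic given the profile seed.

    Subject ids are "S0001", "S0002", ... in draw order. With
    ``return_clusters=True`` also returns the generating mixture component
    of each subject (all zeros when no ``cluster_spec`` is given).
    """
    rng = np.random.default_rng(profile.seed)
    if profile.n == 0:
        return ([], np.zeros(0, dtype=int)) if return_clusters else []
    corr = correlation_matrix(profile)
    # eigendecomposition root: robust to the PSD-but-singular boundary cases
    vals, vecs = np.linalg.eigh(corr)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    latent = rng.standard_normal((profile.n, N_TOTAL)) @ root.T

    if profile.cluster_spec:
        weights = np.array([w for w, _ in profile.cluster_spec])
        shifts = np.array([s for _, s in profile.cluster_spec])
        labels = rng.choice(len(weights), size=profile.n, p=weights / weights.sum())
        latent = latent + shifts[labels][:, None]
    else:
        labels = np.zeros(profile.n, dtype=int)

    cuts = cut_points(profile.mean_capability)
    scores = (latent[:, :, None] > cuts[None, None, :]).sum(axis=2)

    width = len(str(max(profile.n, 1)))
    width = max(width, 4)
    population = []
    for i in range(profile.n):
        sid = f"S{i + 1:0{width}d}"
        population.append(
            DualPortrait(
                individual=IndividualPortrait(sid, tuple(int(v) for v in scores[i, :N_INDIVIDUAL])),
                family=FamilyPortrait(sid, tuple(int(v) for v in scores[i, N_INDIVIDUAL:])),
            )
        )
    return (population, labels) if return_clusters else population


# -- published worked-example vectors ---------------------------------------

_A_1 = (1, 2, 1, 1, 1, 2, 2, 2, 1, 1, 2, 1, 2, 2, 3, 2, 2, 2, 1, 2, 1, 2, 2, 2, 1, 2, 3, 2)
_A_100 = (2, 1, 3, 1, 2, 1, 1, 1, 3, 2, 1, 3, 0, 4, 1, 0, 2, 1, 1, 2, 1, 1, 3, 1, 1, 1, 1, 1)
_B_1 = (2, 3, 1, 1, 3, 1, 2, 2)
_B_100 = (3, 2, 1, 2, 2, 2, 1, 2)
_ZHANG_A = (1, 1, 1, 1, 2, 2, 1, 1, 1, 2, 1, 2, 3, 3, 1, 1, 1, 1, 2, 1, 1, 3, 2, 1, 2, 1, 1, 1)
_ZHANG_B = (0, 2, 1, 1, 1, 1, 1, 2)


def example_portraits() -> dict[str, Portrait]:
    """The published worked-example capability vectors, as typed portraits.

    A_1/B_1 and A_100/B_100 are the two community members used to illustrate
    the portrait notation; zhang_individual/zhang_family is the end-to-end
    demonstration subject.
    """
    return {
        "A_1": IndividualPortrait("subject_001", _A_1),
        "A_100": IndividualPortrait("subject_100", _A_100),
        "B_1": FamilyPortrait("subject_001", _B_1),
        "B_100": FamilyPortrait("subject_100", _B_100),
        "zhang_individual": IndividualPortrait("zhang", _ZHANG_A),
        "zhang_family": FamilyPortrait("zhang", _ZHANG_B),
    }


def example_duals() -> dict[str, DualPortrait]:
    """The worked-example subjects paired into dual portraits."""
    p = example_portraits()
    return {
        "subject_001": DualPortrait(p["A_1"], p["B_1"]),
        "subject_100": DualPortrait(p["A_100"], p["B_100"]),
        "zhang": DualPortrait(p["zhang_individual"], p["zhang_family"]),
    }


_FIXTURE_CATEGORIES = (
    "daily living assistance",
    "nursing",
    "rehabilitation",
    "safety/home modification",
    "psychological support",
)


def generate_rule_fixture(registry: IndicatorRegistry, seed: int = 0) -> MappingMatrix:
    """Random but deterministic total mapping matrix for tests and demos.

    One to three pseudo-random items per (indicator, level) cell, with
    intensity grade 5 - level as in the shipped fixtures.
    """
    rng = np.random.default_rng(seed)
    rules = {}
    for indicator_id in registry.ids:
        for level in range(SCALE_MAX + 1):
            n_items = int(rng.integers(1, 4))
            items = tuple(
                ServiceItem(
                    label=f"{indicator_id} service {level}.{j} #{int(rng.integers(0, 10_000)):04d}",
                    category=_FIXTURE_CATEGORIES[int(rng.integers(0, len(_FIXTURE_CATEGORIES)))],
                    intensity_grade=5 - level,
                )
                for j in range(n_items)
            )
            rules[(indicator_id, level)] = MappingRule(
                portrait_kind=registry.kind,
                indicator_id=indicator_id,
                score_level=level,
                items=items,
            )
    return MappingMatrix(
        kind=registry.kind, registry=registry, rules=rules, name=f"synthetic_seed{seed}"
    )
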