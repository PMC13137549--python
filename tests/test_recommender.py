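"""Similarity, neighbor support, score fusion and the full two-stage pipeline."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics.pairwise import cosine_similarity as sk_cosine

from caremap import (
    ConfigError,
    DualPortrait,
    FamilyPortrait,
    IndividualPortrait,
    MergedCandidate,
    Neighbor,
    ServiceItem,
    SimilarityConfig,
    StratificationThresholds,
    base_priority,
    dual_vector,
    hybrid_rank,
    neighbor_support,
    neighbors,
    recommend,
    recommendations_to_json,
    similarity,
    stage1_candidates,
    stratify,
)

score_vec36 = st.lists(st.integers(0, 4), min_size=36, max_size=36)


def mk_dual(sid, ind=1, fam=1):
    ind_scores = (ind,) * 28 if isinstance(ind, int) else tuple(ind)
    fam_scores = (fam,) * 8 if isinstance(fam, int) else tuple(fam)
    return DualPortrait(IndividualPortrait(sid, ind_scores), FamilyPortrait(sid, fam_scores))


class TestDualVector:
    def test_extremes(self):
        assert np.array_equal(dual_vector(mk_dual("z", 0, 0)), np.zeros(36))
        assert np.array_equal(dual_vector(mk_dual("o", 4, 4)), np.ones(36))

    def test_zhang_entries(self, duals):
        v = dual_vector(duals["zhang"])
        assert v[0] == pytest.approx(0.25)   # first individual score 1
        assert v[28] == pytest.approx(0.0)   # first family score 0


class TestSimilarity:
    def test_self_similarity_is_one(self, duals):
        v = dual_vector(duals["zhang"])
        assert similarity(v, v) == pytest.approx(1.0)

    def test_zero_vector_convention(self):
        assert similarity(np.zeros(36), np.ones(36)) == 0.0
        assert similarity(np.zeros(36), np.zeros(36)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            similarity(np.ones(36), np.ones(8))

    def test_worked_example_pair_matches_oracle(self, duals):
        u = dual_vector(duals["subject_001"])
        v = dual_vector(duals["subject_100"])
        expected = sk_cosine(u.reshape(1, -1), v.reshape(1, -1))[0, 0]
        assert similarity(u, v) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(a=score_vec36, b=score_vec36)
    def test_cosine_matches_direct_formula(self, a, b):
        u = np.array(a) / 4.0
        v = np.array(b) / 4.0
        got = similarity(u, v)
        nu = math.sqrt(math.fsum(x * x for x in u))
        nv = math.sqrt(math.fsum(x * x for x in v))
        expected = 0.0 if nu == 0 or nv == 0 else math.fsum(
            x * y for x, y in zip(u, v)
        ) / (nu * nv)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(similarity(v, u), abs=1e-15)
        assert -1e-12 <= got <= 1 + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(a=score_vec36, b=score_vec36)
    def test_inverse_euclidean_matches_formula(self, a, b):
        cfg = SimilarityConfig(metric="inverse_euclidean")
        u, v = np.array(a) / 4.0, np.array(b) / 4.0
        expected = 1.0 / (1.0 + math.sqrt(math.fsum((x - y) ** 2 for x, y in zip(u, v))))
        assert similarity(u, v, cfg) == pytest.approx(expected, abs=1e-12)
        assert 0 < similarity(u, v, cfg) <= 1


class TestNeighbors:
    def test_single_other_subject(self, duals):
        got = neighbors(duals["zhang"], [duals["subject_001"]])
        assert [n.subject_id for n in got] == ["subject_001"]

    def test_target_excluded_and_empty_population_ok(self, duals):
        assert neighbors(duals["zhang"], [duals["zhang"]]) == []
        assert neighbors(duals["zhang"], []) == []

    def test_equidistant_ties_break_lexicographically(self):
        target = mk_dual("t", 2, 2)
        pop = [mk_dual(sid, 3, 3) for sid in ("s_c", "s_a", "s_b")]
        got = neighbors(target, pop, SimilarityConfig(k_neighbors=2))
        assert [n.subject_id for n in got] == ["s_a", "s_b"]

    def test_min_similarity_filters(self, duals):
        cfg = SimilarityConfig(min_similarity=0.999999)
        got = neighbors(duals["zhang"], [duals["subject_001"], duals["subject_100"]], cfg)
        assert got == []


class TestNeighborSupport:
    def _cand(self, label="Respite care"):
        return MergedCandidate(
            "t", ServiceItem(label, "nursing", 3), (("individual", "eating", 1),)
        )

    def test_empty_neighbor_set_gives_zero(self):
        assert neighbor_support(self._cand(), [], {}) == 0.0

    def test_all_neighbors_carry_gives_one(self):
        cand = self._cand()
        ns = [Neighbor(mk_dual("a"), 0.4), Neighbor(mk_dual("b"), 0.9)]
        sets = {"a": {cand.dedup_key}, "b": {cand.dedup_key}}
        assert neighbor_support(cand, ns, sets) == pytest.approx(1.0)

    def test_weighted_fraction_formula(self):
        cand = self._cand()
        ns = [Neighbor(mk_dual("a"), 0.8), Neighbor(mk_dual("b"), 0.2)]
        sets = {"a": {cand.dedup_key}, "b": frozenset()}
        assert neighbor_support(cand, ns, sets) == pytest.approx(0.8)


class TestBasePriority:
    @pytest.mark.parametrize("score,expected", [(4, 0.0), (0, 1.0), (1, 0.75)])
    def test_severity_from_trigger_score(self, duals, score, expected):
        cand = MergedCandidate(
            "zhang", ServiceItem("x", "nursing", 3), (("individual", "eating", score),)
        )
        severity, _ = base_priority(cand, duals["zhang"])
        assert severity == pytest.approx(expected)

    def test_zhang_family_mean_deficit(self, duals):
        """Mean family score (0+2+1+1+1+1+1+2)/8 = 1.125 => deficit 0.71875."""
        cand = MergedCandidate(
            "zhang", ServiceItem("x", "nursing", 3), (("individual", "eating", 1),)
        )
        _, deficit = base_priority(cand, duals["zhang"])
        assert deficit == pytest.approx((4 - 1.125) / 4) == pytest.approx(0.71875)

    def test_family_triggered_uses_own_trigger(self, duals):
        cand = MergedCandidate(
            "zhang",
            ServiceItem("x", "nursing", 5),
            (("family", "financial_resources", 0),),
        )
        severity, deficit = base_priority(cand, duals["zhang"])
        assert severity == 1.0 and deficit == 1.0


class TestHybridRankAndStratify:
    def _two_candidates(self):
        a = MergedCandidate("t", ServiceItem("Svc A", "nursing", 3), (("individual", "eating", 2),))
        b = MergedCandidate("t", ServiceItem("Svc B", "nursing", 3), (("individual", "bathing", 2),))
        return a, b

    def test_support_difference_changes_total_by_its_weight(self, duals):
        a, b = self._two_candidates()
        supports = {a.dedup_key: 1.0, b.dedup_key: 0.0}
        ranked = hybrid_rank([a, b], duals["zhang"], supports)
        by_label = {r.item.label: r.score.total for r in ranked.recommendations}
        assert by_label["Svc A"] - by_label["Svc B"] == pytest.approx(0.2)

    def test_output_is_permutation_of_input(self, duals, ind_matrix, fam_matrix):
        cands = stage1_candidates(duals["zhang"], ind_matrix, fam_matrix)
        ranked = hybrid_rank(cands, duals["zhang"], {})
        assert sorted(r.item.label for r in ranked.recommendations) == sorted(
            c.item.label for c in cands
        )

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigError):
            SimilarityConfig(weights=(0.5, 0.3, 0.3))
        with pytest.raises(ConfigError):
            SimilarityConfig(weights=(1.2, -0.2, 0.0))

    def test_stratification_boundaries(self):
        thr = StratificationThresholds()
        assert thr.level(1.0) == "high"
        assert thr.level(2.0 / 3.0) == "high"  # closed lower bound
        assert thr.level(0.5) == "medium"
        assert thr.level(1.0 / 3.0) == "medium"
        assert thr.level(0.2) == "low"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            StratificationThresholds(high=0.3, medium=0.6)

    def test_stratify_is_monotone_in_total(self, duals, ind_matrix, fam_matrix):
        reclist = recommend(duals["zhang"], [], ind_matrix, fam_matrix)
        order = {"high": 2, "medium": 1, "low": 0}
        levels = [order[r.priority_level] for r in reclist.recommendations]
        assert levels == sorted(levels, reverse=True)


class TestRecommendPipeline:
    def test_empty_population_is_rule_only(self, duals, ind_matrix, fam_matrix):
        reclist = recommend(duals["zhang"], [], ind_matrix, fam_matrix)
        assert len(reclist) > 0
        assert all(r.score.support_component == 0.0 for r in reclist.recommendations)

    def test_permutation_of_stage1(self, duals, ind_matrix, fam_matrix, population20):
        cands = stage1_candidates(duals["zhang"], ind_matrix, fam_matrix)
        reclist = recommend(duals["zhang"], population20, ind_matrix, fam_matrix)
        assert sorted(r.item.dedup_key for r in reclist.recommendations) == sorted(
            c.dedup_key for c in cands
        )

    def test_population_invariance_when_support_weight_zero(
        self, duals, ind_matrix, fam_matrix, population20
    ):
        cfg = SimilarityConfig(weights=(0.6, 0.4, 0.0))
        a = recommend(duals["zhang"], [], ind_matrix, fam_matrix, cfg)
        b = recommend(duals["zhang"], population20, ind_matrix, fam_matrix, cfg)
        assert [
            (r.item.label, r.score.total, r.priority_level) for r in a.recommendations
        ] == [(r.item.label, r.score.total, r.priority_level) for r in b.recommendations]

    def test_repeated_runs_byte_identical(self, duals, ind_matrix, fam_matrix, population20):
        a = recommend(duals["zhang"], population20, ind_matrix, fam_matrix)
        b = recommend(duals["zhang"], population20, ind_matrix, fam_matrix)
        assert recommendations_to_json(a).encode() == recommendations_to_json(b).encode()

    def test_family_degradation_never_lowers_individually_triggered_totals(
        self, duals, ind_matrix, fam_matrix, population20
    ):
        """Weaker family caregiving raises the priority of external services."""
        zhang = duals["zhang"]
        strong = mk_dual("zhang", zhang.individual.scores, 4)
        weak = mk_dual("zhang", zhang.individual.scores, 0)
        rec_strong = recommend(strong, population20, ind_matrix, fam_matrix)
        rec_weak = recommend(weak, population20, ind_matrix, fam_matrix)

        def individual_totals(reclist):
            return {
                r.item.dedup_key: r.score.total
                for r in reclist.recommendations
                if all(kind == "individual" for kind, _, _ in r.triggers)
            }

        strong_totals = individual_totals(rec_strong)
        weak_totals = individual_totals(rec_weak)
        shared = set(strong_totals) & set(weak_totals)
        assert shared
        for key in shared:
            assert weak_totals[key] >= strong_totals[key] - 1e-12

    @settings(derandomize=True, max_examples=25)
    @given(
        fam_hi=st.lists(st.integers(0, 4), min_size=8, max_size=8),
        drop=st.integers(0, 7),
    )
    def test_pointwise_family_lowering_monotone_without_support(
        self, duals, ind_matrix, fam_matrix, fam_hi, drop
    ):
        """With w_support = 0 any pointwise lowering of family scores is monotone."""
        fam_lo = list(fam_hi)
        fam_lo[drop] = max(0, fam_lo[drop] - 1)
        cfg = SimilarityConfig(weights=(0.6, 0.4, 0.0))
        hi = recommend(mk_dual("z", duals["zhang"].individual.scores, fam_hi), [], ind_matrix, fam_matrix, cfg)
        lo = recommend(mk_dual("z", duals["zhang"].individual.scores, fam_lo), [], ind_matrix, fam_matrix, cfg)

        def ind_totals(reclist):
            return {
                r.item.dedup_key: r.score.total
                for r in reclist.recommendations
                if all(kind == "individual" for kind, _, _ in r.triggers)
            }

        hi_t, lo_t = ind_totals(hi), ind_totals(lo)
        for key in set(hi_t) & set(lo_t):
            assert lo_t[key] >= hi_t[key] - 1e-12
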