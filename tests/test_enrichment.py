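"""Exact hypergeometric statistics against enumeration and library oracles."""

import math
from itertools import combinations

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.enrichment import (
    DiseaseEnrichmentRow,
    EnrichmentConfig,
    benjamini_hochberg,
    enrich_diseases,
    enrich_from_counts,
    hypergeom_pmf,
    hypergeom_upper_tail,
    select_major_diseases,
)
from netpharm.io import DiseaseTargetDB
from netpharm.simulate import reference_fixture


def enumerate_pmf(k, N, K, n):
    """Exhaustive draw enumeration: fraction of n-subsets with k marked."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n) if len(marked & set(draw)) == k)
    return hits / math.comb(N, n)


class TestPointProbability:
    @pytest.mark.parametrize(
        "k,N,K,n,expected",
        [
            (4, 749, 5, 151, 0.006421),
            (1, 749, 1, 151, 151 / 749),
            (2, 749, 5, 151, 0.207201),
            (0, 20, 0, 5, 1.0),
        ],
    )
    def test_published_and_closed_form_values(self, k, N, K, n, expected):
        assert hypergeom_pmf(k, N, K, n) == pytest.approx(expected, abs=5e-7)

    def test_out_of_support_is_zero(self):
        assert hypergeom_pmf(6, 20, 5, 10) == 0.0
        assert hypergeom_pmf(0, 20, 15, 10) == 0.0  # below n+K-N = 5

    def test_inconsistent_arguments_raise(self):
        with pytest.raises(ValueError):
            hypergeom_pmf(1, 10, 11, 5)
        with pytest.raises(ValueError):
            hypergeom_pmf(-1, 10, 5, 5)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in (4, 7, 10, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_pmf(k, N, K, n) == pytest.approx(
                            enumerate_pmf(k, N, K, n), abs=1e-12
                        )

    def test_matches_scipy_at_study_scale(self):
        # independent log-gamma route as a cross-check of the exact rationals
        for k, K in [(48, 176), (77, 370), (15, 52), (1, 4)]:
            assert hypergeom_pmf(k, 749, K, 151) == pytest.approx(
                float(scipy.stats.hypergeom.pmf(k, 749, K, 151)), rel=1e-10
            )


class TestUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 30, 7, 9) == 1.0

    def test_single_element_tail(self):
        assert hypergeom_upper_tail(1, 749, 1, 151) == pytest.approx(151 / 749, abs=1e-15)

    def test_worked_enumeration_example(self):
        assert hypergeom_upper_tail(3, 20, 5, 5) == pytest.approx(1126 / 15504, abs=1e-15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 15), st.data())
    def test_tail_difference_is_pmf_and_tail_dominates(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        for k in range(0, min(K, n) + 1):
            tail_k = hypergeom_upper_tail(k, N, K, n)
            tail_next = hypergeom_upper_tail(k + 1, N, K, n)
            pmf_k = hypergeom_pmf(k, N, K, n)
            assert tail_k - tail_next == pytest.approx(pmf_k, abs=1e-12)
            assert tail_k >= pmf_k - 1e-15

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.data())
    def test_pmf_sums_to_one_and_is_symmetric_in_K_n(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        total = sum(hypergeom_pmf(k, N, K, n) for k in range(min(K, n) + 1))
        assert total == pytest.approx(1.0, abs=1e-10)
        for k in range(min(K, n) + 1):
            assert hypergeom_pmf(k, N, K, n) == hypergeom_pmf(k, N, n, K)


class TestDiseaseRanking:
    def test_published_table_ranks_hepatitis_first(self):
        triples, config = reference_fixture()
        rows = enrich_from_counts(triples, config)
        assert rows[0].disease == "Hepatitis"
        assert rows[0].p_value == pytest.approx(0.002593, abs=5e-7)
        by_name = {r.disease: r for r in rows}
        assert by_name["Reye Syndrome"].p_value == pytest.approx(0.411638, abs=5e-7)
        assert by_name["Reye Syndrome"].match == 1 and by_name["Reye Syndrome"].total == 4

    def test_degenerate_universe_gives_p_one(self):
        db = DiseaseTargetDB(entries={"only": frozenset({"A", "B", "C"})})
        config = EnrichmentConfig(N=3, n=3)
        rows = enrich_diseases(db, {"A", "B", "C"}, config)
        assert rows[0].p_value == pytest.approx(1.0, abs=1e-15)

    def test_zero_match_diseases_are_reported_not_dropped(self):
        db = DiseaseTargetDB(
            entries={"hit": frozenset({"A", "B"}), "miss": frozenset({"C", "D"})}
        )
        rows = enrich_diseases(db, {"A"}, EnrichmentConfig(N=4, n=1))
        assert {r.disease for r in rows} == {"hit", "miss"}
        miss = next(r for r in rows if r.disease == "miss")
        assert miss.match == 0 and miss.p_value == pytest.approx(
            hypergeom_pmf(0, 4, 2, 1)
        )
        tail_rows = enrich_diseases(
            db, {"A"}, EnrichmentConfig(N=4, n=1, variant="upper_tail")
        )
        assert next(r for r in tail_rows if r.disease == "miss").p_value == 1.0

    def test_sorting_ties_break_by_match_then_name(self):
        config = EnrichmentConfig(N=100, n=10)
        rows = enrich_from_counts(
            [("b", 1, 2), ("a", 1, 2), ("big", 5, 50), ("c", 1, 2)], config
        )
        tied = [r.disease for r in rows if (r.match, r.total) == (1, 2)]
        assert tied == sorted(tied)

    def test_size_mismatch_errors_state_both_numbers(self):
        db = DiseaseTargetDB(entries={"d": frozenset({"A", "B"})})
        with pytest.raises(ValueError, match="outside the disease universe"):
            enrich_diseases(db, {"Z"}, EnrichmentConfig(N=2, n=1))
        with pytest.raises(ValueError, match="config.n=2"):
            enrich_diseases(db, {"A"}, EnrichmentConfig(N=2, n=2))
        with pytest.raises(ValueError, match="config.N=5"):
            enrich_diseases(db, {"A"}, EnrichmentConfig(N=5, n=1))


class TestMajorDiseaseFilter:
    def test_published_table_yields_exactly_six(self):
        triples, config = reference_fixture()
        major = select_major_diseases(enrich_from_counts(triples, config), config)
        assert [r.disease for r in major] == [
            "Hepatitis",
            "Liver Failure, Acute",
            "Hypertension, Portal",
            "Hepatitis B",
            "Fatty Liver",
            "Liver Failure",
        ]

    def test_alpha_zero_empty_and_permissive_keeps_all(self):
        triples, config = reference_fixture()
        rows = enrich_from_counts(triples, config)
        assert select_major_diseases(rows, EnrichmentConfig(N=749, n=151, alpha=0.0)) == []
        permissive = EnrichmentConfig(N=749, n=151, alpha=1.0, min_match=0)
        assert len(select_major_diseases(rows, permissive)) == len(rows)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        ps = [0.001, 0.02, 0.02, 0.3, 0.9, 0.04]
        ours = benjamini_hochberg(ps)
        _, theirs, _, _ = multipletests(ps, method="fdr_bh")
        assert ours == pytest.approx(list(theirs), abs=1e-12)

    def test_correction_attached_to_rows(self):
        config = EnrichmentConfig(N=50, n=10, correction="benjamini_hochberg")
        rows = enrich_from_counts([("a", 3, 5), ("b", 0, 10)], config)
        assert all(isinstance(r, DiseaseEnrichmentRow) and r.q_value is not None for r in rows)
        assert all(r.q_value >= r.p_value - 1e-15 for r in rows)
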