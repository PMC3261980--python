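"""Hypergeometric enrichment: tail probabilities, adjustment, translation."""

import math
from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from toxilink import (
    AnnotationSource,
    IdMap,
    Relation,
    SourceKind,
    bonferroni_adjust,
    enrich_diseases,
    hypergeom_upper_tail,
    translate_disease_ids,
)
from tests.conftest import make_mapped


def enumeration_oracle(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-subsets of N items."""
    annotated = set(range(K))
    hits = sum(
        1 for subset in combinations(range(N), n) if len(annotated & set(subset)) >= k
    )
    return hits / math.comb(N, n)


class TestUpperTail:
    def test_small_case_equals_exact_fraction(self):
        # (C(4,2)C(6,1) + C(4,3)) / C(10,3) = 40/120
        assert hypergeom_upper_tail(10, 4, 3, 2) == pytest.approx(1 / 3, abs=1e-15)

    def test_k_zero_is_exactly_one(self):
        assert hypergeom_upper_tail(50, 10, 5, 0) == 1.0

    def test_matches_enumeration_on_a_grid(self):
        for N in (5, 8, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = enumeration_oracle(N, K, n, k)
                        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                            expected, abs=1e-12
                        ), (N, K, n, k)

    def test_matches_scipy_survival_function_at_scale(self):
        for params in [(2387, 13, 29, 1), (10509, 1977, 131, 48), (500, 60, 40, 12)]:
            N, K, n, k = params
            assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), rel=1e-10
            )

    def test_closed_form_for_k_one(self):
        # P(X >= 1) = 1 - C(N-K, n) / C(N, n)
        N, K, n = 2387, 13, 29
        closed = 1.0 - math.comb(N - K, n) / math.comb(N, n)
        assert hypergeom_upper_tail(N, K, n, 1) == pytest.approx(closed, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.data())
    def test_tail_complement_and_monotonicity(self, data):
        N = data.draw(st.integers(1, 300))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        upper = [hypergeom_upper_tail(N, K, n, k) for k in range(min(K, n) + 1)]
        # non-increasing in k
        assert all(a >= b - 1e-12 for a, b in zip(upper, upper[1:]))
        for k in range(1, min(K, n) + 1):
            lower = hypergeom.cdf(k - 1, N, K, n)
            assert upper[k] + lower == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "N, K, n, k, message",
        [
            (10, 12, 5, 1, "K <= N"),
            (10, 5, 12, 1, "n <= N"),
            (10, 3, 5, 4, "k <= min"),
            (10, 3, 5, -1, "0 <= k"),
        ],
    )
    def test_bound_violations_name_the_inequality(self, N, K, n, k, message):
        with pytest.raises(ValueError, match=message):
            hypergeom_upper_tail(N, K, n, k)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni_adjust(0.001, 10) == pytest.approx(0.01)
        assert bonferroni_adjust(0.5, 10) == 1.0

    def test_invalid_family_size(self):
        with pytest.raises(ValueError, match=">= 1"):
            bonferroni_adjust(0.01, 0)


class TestTranslateDiseaseIds:
    def test_one_to_many_fan_out(self):
        src = AnnotationSource(SourceKind.CTD_LIKE, [("P", "M1", Relation.INFERRED)])
        out = translate_disease_ids(src, IdMap([("M1", "O1"), ("M1", "O2")]))
        assert out.annotations == {
            ("P", "O1", Relation.INFERRED),
            ("P", "O2", Relation.INFERRED),
        }

    def test_identity_map_is_identity(self, tiny_annotation_source):
        idmap = IdMap([(d, d) for d in tiny_annotation_source.diseases])
        assert translate_disease_ids(tiny_annotation_source, idmap) == (
            tiny_annotation_source
        )

    def test_unmappable_diseases_retained_and_counted(self, caplog):
        src = AnnotationSource(
            SourceKind.CTD_LIKE,
            [
                ("P1", "M1", Relation.INFERRED),
                ("P2", "M1", Relation.INFERRED),
                ("P3", "M2", Relation.INFERRED),
                ("P4", "MX", Relation.INFERRED),
            ],
        )
        idmap = IdMap([("M1", "O1"), ("M2", "O2")])
        with caplog.at_level("INFO", logger="toxilink"):
            out = translate_disease_ids(src, idmap)
        assert out.diseases == {"O1", "O2", "MX"}
        assert "1 disease(s) had no mapping" in caplog.text


class TestEnrichDiseases:
    def test_hand_fixture_parameters(self, tiny_annotation_source):
        ps = make_mapped("C1", ["G1", "G2", "G9"])  # G9 outside the universe
        results = enrich_diseases(ps, tiny_annotation_source)
        by_disease = {r.disease_id: r for r in results}
        # universe 5, members inside 2; D1 annotated to {G1,G2} -> k=2
        r = by_disease["D1"]
        assert (r.N, r.K, r.n, r.k) == (5, 2, 2, 2)
        assert r.linking_proteins == {"G1", "G2"}
        assert r.p_raw == pytest.approx(1 / math.comb(5, 2))
        # family size = 3 diseases
        assert r.p_adj == pytest.approx(3 * r.p_raw)
        # D2 has zero overlap -> omitted
        assert "D2" not in by_disease

    def test_omim_like_reported_unadjusted(self):
        src = AnnotationSource(
            SourceKind.OMIM_LIKE,
            [("G1", "D1", Relation.DIRECT), ("G2", "D2", Relation.DIRECT)],
        )
        (r,) = enrich_diseases(make_mapped("C1", ["G1"]), src)
        assert r.p_adj == r.p_raw

    def test_single_annotating_disease_is_certain(self):
        src = AnnotationSource(
            SourceKind.CTD_LIKE,
            [(f"G{i}", "D1", Relation.INFERRED) for i in range(6)],
        )
        (r,) = enrich_diseases(make_mapped("C1", ["G0", "G1"]), src)
        assert (r.k, r.K) == (r.n, r.N)
        assert r.p_raw == 1.0

    def test_no_members_in_universe_warns_empty(self, tiny_annotation_source, caplog):
        with caplog.at_level("WARNING", logger="toxilink"):
            results = enrich_diseases(
                make_mapped("C1", ["ZZ"]), tiny_annotation_source
            )
        assert results == []
        assert "no proteins" in caplog.text

    def test_sorted_by_adjusted_p_then_disease(self, tiny_annotation_source):
        ps = make_mapped("C1", ["G1", "G2", "G3", "G4", "G5"])
        results = enrich_diseases(ps, tiny_annotation_source)
        keys = [(r.p_adj, r.disease_id) for r in results]
        assert keys == sorted(keys)

    def test_direct_only_restricts_catalog(self, tiny_annotation_source):
        ps = make_mapped("C1", ["G1", "G4"])
        results = enrich_diseases(ps, tiny_annotation_source, direct_only=True)
        # direct records only: G1-D1 and G4-D2; universe shrinks to {G1,G4}
        assert {r.disease_id for r in results} == {"D1", "D2"}
        assert all(r.N == 2 for r in results)

    def test_bonferroni_family_override(self, tiny_annotation_source):
        ps = make_mapped("C1", ["G1"])
        results = enrich_diseases(ps, tiny_annotation_source, bonferroni_m=100)
        assert all(
            r.p_adj == pytest.approx(min(1.0, 100 * r.p_raw)) for r in results
        )
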