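import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxinfer import (
    FilterLevel,
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    infer_diseases,
    propagate_annotations,
)
from toxinfer.enrichment import report_to_frame
from toxinfer.ontology import AnnotationMap, OntologyGraph


def enum_upper_tail(k, K, n, N):
    """Oracle: enumerate every size-n draw from an N-item population."""
    successes = set(range(K))
    draws = list(combinations(range(N), n))
    hits = sum(1 for d in draws if sum(x in successes for x in d) >= k)
    return hits / len(draws)


def bh_stepup(p):
    """Oracle: the step-up formula applied by hand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestHypergeomUpperTail:
    def test_zero_successes_has_probability_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 4, 5, 10)  # k > K
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 4, 10)  # K > N
        with pytest.raises(ValueError):
            hypergeom_upper_tail(-1, 4, 5, 10)

    def test_all_draws_successful(self):
        # C(5,4)/C(10,4), checked against full enumeration of the 210 draws
        expected = enum_upper_tail(4, 5, 4, 10)
        assert expected == pytest.approx(math.comb(5, 4) / math.comb(10, 4))
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("N", [5, 8, 10])
    def test_matches_enumeration(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                        enum_upper_tail(k, K, n, N), abs=1e-12
                    )


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_example(self):
        # ranks 1..3: 0.01*3/1, 0.02*3/2, 0.03*3/3 -> monotone from the top
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
        seed=st.integers(0, 1000),
    )
    def test_matches_stepup_oracle_and_permutation_invariance(self, p, seed):
        adj = np.asarray(bh_adjust(p))
        assert np.allclose(adj, bh_stepup(p), atol=1e-12)
        assert ((np.asarray(p) - 1e-12 <= adj) & (adj <= 1 + 1e-12)).all()
        perm = np.random.default_rng(seed).permutation(len(p))
        adj_perm = np.asarray(bh_adjust([p[i] for i in perm]))
        assert np.allclose(adj_perm, adj[perm], atol=1e-12)


@pytest.fixture
def flat_annotations():
    """20-gene universe; term T annotates 5 genes, term U annotates 8."""
    genes = [f"g{i}" for i in range(20)]
    direct = {g: {"ROOT"} for g in genes}
    for g in genes[:5]:
        direct[g] = direct[g] | {"T"}
    for g in genes[5:13]:
        direct[g] = direct[g] | {"U"}
    return AnnotationMap(direct=direct, propagated=direct)


class TestEnrich:
    def test_counts_and_single_term_pvalue(self, flat_annotations):
        target = {"g0", "g1", "g2", "g3", "g19"}  # 4 of 5 in T
        results = enrich(target, flat_annotations, alpha=0.05)
        by_term = {r.term: r for r in results}
        t = by_term["T"]
        assert (t.k, t.n, t.K, t.N) == (4, 5, 5, 20)
        assert t.p_value == pytest.approx(enum_upper_tail(4, 5, 5, 20), abs=1e-12)
        assert t.genes == ("g0", "g1", "g2", "g3")
        # ROOT annotates everything: k=n, K=N -> p = 1
        assert by_term["ROOT"].p_value == pytest.approx(1.0)

    def test_target_equal_to_universe_is_never_significant(self, flat_annotations):
        universe = set(flat_annotations.direct)
        results = enrich(universe, flat_annotations, alpha=0.05)
        assert results
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_terms_without_target_hits_not_reported(self, flat_annotations):
        results = enrich({"g15"}, flat_annotations)  # g15 only in ROOT and U... check
        terms = {r.term for r in results}
        assert "T" not in terms

    def test_stray_target_genes_warned_and_dropped(self, flat_annotations):
        with pytest.warns(UserWarning, match="outside"):
            results = enrich({"g0", "mystery"}, flat_annotations)
        assert all(r.n == 1 for r in results)

    def test_empty_target_warns(self, flat_annotations):
        with pytest.warns(UserWarning, match="empty"):
            assert enrich(set(), flat_annotations) == []

    def test_results_sorted_and_deterministic(self, flat_annotations):
        target = {"g0", "g1", "g2", "g5", "g6"}
        a = enrich(target, flat_annotations)
        b = enrich(set(target), flat_annotations)
        assert a == b
        keys = [(r.adjusted_p, r.term) for r in a]
        assert keys == sorted(keys)


class TestInferDiseases:
    def test_level_none_equals_conventional(self, bundle):
        chem, _, tissue = bundle.planted[0]
        conv = infer_diseases(
            chem, bundle.interactions, bundle.annotations, bundle.graph,
            mode="conventional",
        )
        aug = infer_diseases(
            chem, bundle.interactions, bundle.annotations, bundle.graph,
            mode="augmented", dataset=bundle.expression, tissue=tissue,
            level=FilterLevel.NONE,
        )
        assert conv.results == aug.results

    def test_augmented_recovers_planted_term(self, bundle):
        chem, term, tissue = bundle.planted[0]
        aug = infer_diseases(
            chem, bundle.interactions, bundle.annotations, bundle.graph,
            mode="augmented", dataset=bundle.expression, tissue=tissue,
            level=FilterLevel.LOW,
        )
        assert term in aug.enriched_terms

    def test_unknown_chemical_gives_empty_report(self, bundle):
        with pytest.warns(UserWarning):
            report = infer_diseases(
                "CID99999", bundle.interactions, bundle.annotations, bundle.graph
            )
        assert report.enriched == []
        assert report.empty_after_filter

    def test_augmented_requires_tissue_inputs(self, bundle):
        with pytest.raises(ValueError, match="dataset and tissue"):
            infer_diseases(
                bundle.planted[0][0], bundle.interactions, bundle.annotations,
                bundle.graph, mode="augmented",
            )

    def test_report_frame_columns(self, bundle):
        chem, _, _ = bundle.planted[0]
        report = infer_diseases(
            chem, bundle.interactions, bundle.annotations, bundle.graph
        )
        frame = report_to_frame(report)
        assert list(frame.columns) == [
            "term", "name", "gene_ratio", "background_ratio",
            "p_value", "adjusted_p", "genes",
        ]
        assert len(frame) == len(report.enriched)
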