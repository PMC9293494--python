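"""Hypergeometric over-representation, BH adjustment, top-term selection,
and the qPCR fold-change statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from helpers import bh_oracle, hypergeom_tail_exact

from herbnetpharm.enrichment import (
    DdctMeasurement,
    adjust_pvalues,
    ddct_fold_change,
    enrich_gene_set,
    hypergeometric_tail,
    select_top_terms,
)
from herbnetpharm.errors import ValidationError
from herbnetpharm.io import AnnotationCollection
from herbnetpharm.simulate import SimulationConfig, simulate_annotations


def _draw_params(rng, m_max=2000):
    M = int(rng.integers(10, m_max))
    n = int(rng.integers(1, M + 1))
    K = int(rng.integers(1, M + 1))
    k = int(rng.integers(0, min(n, K) + 1))
    return k, n, K, M


class TestHypergeometricTail:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_tail(0, 5, 5, 10) == 1.0

    def test_full_overlap_exact_value(self):
        # drawing all 5 marked elements in 5 draws out of 10: 1 / C(10,5)
        assert hypergeometric_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_big_integer_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(300):
            k, n, K, M = _draw_params(rng)
            exact = float(hypergeom_tail_exact(k, n, K, M))
            ours = hypergeometric_tail(k, n, K, M)
            assert ours == pytest.approx(exact, rel=1e-10, abs=1e-300)

    def test_matches_scipy_survival_function(self):
        rng = np.random.default_rng(67)
        for _ in range(100):
            k, n, K, M = _draw_params(rng)
            expected = stats.hypergeom.sf(k - 1, M, K, n)
            assert hypergeometric_tail(k, n, K, M) == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_monotone_decreasing_in_k(self):
        rng = np.random.default_rng(71)
        for _ in range(50):
            _, n, K, M = _draw_params(rng, m_max=200)
            tails = [hypergeometric_tail(k, n, K, M) for k in range(min(n, K) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    @pytest.mark.parametrize("bad", [(-1, 5, 5, 10), (6, 5, 5, 10), (2, 5, 11, 10), (2, 11, 5, 10)])
    def test_bounds_rejected(self, bad):
        with pytest.raises(ValidationError):
            hypergeometric_tail(*bad)


class TestAdjustPvalues:
    def test_hand_computed_bh(self):
        assert adjust_pvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_hand_computed_bh_mixed(self):
        # ordered p: 0.005, 0.04, 0.1 -> adjusted 0.015, 0.06, 0.1
        assert adjust_pvalues([0.04, 0.005, 0.1]) == pytest.approx([0.06, 0.015, 0.1])

    def test_single_and_none(self):
        assert adjust_pvalues([0.3]) == [0.3]
        assert adjust_pvalues([0.5, 0.01], method="none") == [0.5, 0.01]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=150)
    def test_bh_matches_textbook_oracle_and_is_monotone(self, pvals):
        adj = adjust_pvalues(pvals)
        oracle = bh_oracle(pvals)
        assert adj == pytest.approx(oracle, abs=1e-12)
        assert all(a >= p - 1e-15 and a <= 1.0 for a, p in zip(adj, pvals))
        order = np.argsort(pvals, kind="stable")
        ranked = [adj[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(ranked, ranked[1:]))


class TestEnrichGeneSet:
    @pytest.fixture
    def collection(self):
        terms = {
            "T1": ("apoptosis", {"CASP3", "TP53", "BAX"}),
            "T2": ("lens", {"CRYAB", "CRYAA"}),
            "T3": ("kinase", {"MAPK14", "TP53", "AKT1", "EGFR"}),
        }
        return AnnotationCollection(terms=terms)

    def test_query_disjoint_from_terms_is_empty(self, collection):
        collection.universe = collection.annotated_genes() | {"ESR1", "AKR1B1"}
        res = enrich_gene_set({"ESR1", "AKR1B1"}, collection, universe_mode="explicit")
        assert res == []

    def test_only_overlapping_terms_reported(self, collection):
        assert [r.term_id for r in enrich_gene_set({"CRYAB"}, collection)] == ["T2"]

    def test_counts_and_ratio(self, collection):
        res = {r.term_id: r for r in enrich_gene_set({"CASP3", "TP53"}, collection)}
        r = res["T1"]
        # universe = union of the three term gene sets = 8 unique genes
        assert (r.k, r.n, r.K, r.M) == (2, 2, 3, 8)
        assert r.enrichment_ratio == pytest.approx((2 / 2) / (3 / 8))
        assert r.p_raw == pytest.approx(float(hypergeom_tail_exact(2, 2, 3, 8)), rel=1e-10)

    def test_ease_discounts_one_gene(self, collection):
        plain = {r.term_id: r.p_raw for r in enrich_gene_set({"CRYAB"}, collection)}
        eased = {r.term_id: r.p_raw for r in enrich_gene_set({"CRYAB"}, collection, ease=True)}
        assert eased["T2"] == 1.0  # k=1 -> tail at 0
        assert plain["T2"] < 1.0

    def test_ease_never_smaller_than_plain(self):
        rng = np.random.default_rng(73)
        genes = [f"G{i}" for i in range(60)]
        for _ in range(20):
            terms = {
                f"T{t}": ("d", {str(x) for x in rng.choice(genes, size=rng.integers(3, 20), replace=False)})
                for t in range(6)
            }
            coll = AnnotationCollection(terms=terms)
            query = {str(x) for x in rng.choice(genes, size=10, replace=False)}
            query &= coll.annotated_genes()
            if not query:
                continue
            plain = {r.term_id: r.p_raw for r in enrich_gene_set(query, coll)}
            eased = {r.term_id: r.p_raw for r in enrich_gene_set(query, coll, ease=True)}
            for tid in plain:
                assert eased[tid] >= plain[tid] - 1e-12

    def test_explicit_universe_mode(self, collection):
        collection.universe = {f"X{i}" for i in range(50)} | collection.annotated_genes()
        res = enrich_gene_set({"CASP3", "TP53"}, collection, universe_mode="explicit")
        assert all(r.M == len(collection.universe) for r in res)

    def test_query_outside_universe_rejected(self, collection):
        with pytest.raises(ValidationError):
            enrich_gene_set({"NOT_ANNOTATED"}, collection)

    def test_planted_term_ranks_first(self):
        cfg = SimulationConfig(seed=101)
        rng = np.random.default_rng(101)
        pool = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
        key_genes = {str(x) for x in rng.choice(pool, size=10, replace=False)}
        annotations, planted = simulate_annotations(cfg, key_genes, gene_pool=pool)
        results = enrich_gene_set(key_genes, annotations)
        assert results[0].term_id == planted


class TestSelectTopTerms:
    def _fake(self, tid, p):
        from herbnetpharm.enrichment import EnrichmentResult

        return EnrichmentResult(tid, "", 1, 1, 1, 10, p, p, 1.0)

    def test_truncation(self):
        results = [self._fake(f"T{i:02d}", 0.001 * (i + 1)) for i in range(30)]
        assert len(select_top_terms(results, top_k=20)) == 20

    def test_boundary_alpha_strict(self):
        results = [self._fake("T1", 0.05), self._fake("T2", 0.049)]
        kept = select_top_terms(results, alpha=0.05)
        assert [r.term_id for r in kept] == ["T2"]

    def test_matches_sort_filter_oracle(self):
        rng = np.random.default_rng(79)
        results = [self._fake(f"T{i:03d}", float(rng.uniform(0, 0.2))) for i in range(50)]
        rng.shuffle(results)
        kept = select_top_terms(results, alpha=0.05, top_k=10)
        oracle = sorted(
            [r for r in results if r.p_raw < 0.05], key=lambda r: (r.p_raw, r.term_id)
        )[:10]
        assert [r.term_id for r in kept] == [r.term_id for r in oracle]


class TestFoldChange:
    @pytest.mark.parametrize(
        "measurement,expected",
        [
            (DdctMeasurement(20, 15, 20, 15), 1.0),  # identical dCt
            (DdctMeasurement(21, 15, 20, 15), 0.5),  # one extra cycle
            (DdctMeasurement(18, 15, 20, 15), 4.0),  # ddCt = -2
        ],
    )
    def test_closed_forms(self, measurement, expected):
        assert ddct_fold_change(measurement) == pytest.approx(expected)

    def test_replicates_use_group_means(self):
        m = DdctMeasurement(
            ct_target_treated=[21.0, 21.2, 20.8],
            ct_ref_treated=[15.0, 15.0, 15.0],
            ct_target_control=20.0,
            ct_ref_control=15.0,
        )
        assert ddct_fold_change(m) == pytest.approx(0.5)
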