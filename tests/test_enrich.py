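"""Fisher exact GO overrepresentation and FDR control."""

import numpy as np
import pytest
import scipy.stats

from dgekit.enrich import (
    ContingencyTable2x2,
    bh_fdr,
    fisher_two_tailed,
    go_enrichment,
)
from dgekit.tabio import AnnotationRecord

from oracles import exact_fisher_two_tailed, stepup_fdr


class TestFisher:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((5, 5, 5, 5), 1.0),   # perfectly balanced
            ((3, 0, 0, 3), 0.1),   # enumeration: {1,9,9,1}/20, two tails = 2/20
            ((0, 10, 0, 10), 1.0),  # empty term
        ],
    )
    def test_known_tables(self, cells, expected):
        assert fisher_two_tailed(ContingencyTable2x2(*cells)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(150):
            a, b, c, d = (int(v) for v in rng.integers(0, 60, size=4))
            got = fisher_two_tailed(ContingencyTable2x2(a, b, c, d))
            exact = float(exact_fisher_two_tailed(a, b, c, d))
            assert got == pytest.approx(exact, rel=1e-10), (a, b, c, d)

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 40, size=4))
            got = fisher_two_tailed(ContingencyTable2x2(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(ref, rel=1e-6), (a, b, c, d)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestBhFdr:
    def test_step_up_by_hand(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_equal_stay_equal(self):
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_empty_input(self):
        assert len(bh_fdr([])) == 0

    def test_matches_textbook_definition_and_preserves_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40).tolist()
        assert bh_fdr(p) == pytest.approx(stepup_fdr(p))

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(6)
        p = np.sort(rng.uniform(size=30))
        adj = bh_fdr(p)
        assert np.all(np.diff(adj) >= 0)
        # re-application can only push adjusted values further up
        assert np.all(bh_fdr(adj) >= adj - 1e-15)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        assert np.all(bh_fdr(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _annotated_sets(n_test, n_ref, term_counts_test, term_counts_ref, n_decoys=0,
                    decoy_frac=0.2, seed=0):
    """Build disjoint test/ref contig sets with per-term planted counts."""
    rng = np.random.default_rng(seed)
    test_ids = [f"t{i}" for i in range(n_test)]
    ref_ids = [f"r{i}" for i in range(n_ref)]
    terms_of = {i: set() for i in test_ids + ref_ids}
    for term, k in term_counts_test.items():
        for i in test_ids[:k]:
            terms_of[i].add(term)
    for term, k in term_counts_ref.items():
        for i in ref_ids[:k]:
            terms_of[i].add(term)
    for j in range(n_decoys):
        term = f"GO:{7000000 + j:07d}"
        for i in test_ids + ref_ids:
            if rng.random() < decoy_frac:
                terms_of[i].add(term)
    # every contig carries a filler term so all participate
    ann = [
        AnnotationRecord(i, accession=f"A{i}",
                         go_terms=frozenset(terms_of[i] | {"GO:0999999"}))
        for i in test_ids + ref_ids
    ]
    return set(test_ids), set(ref_ids), ann


class TestGoEnrichment:
    def test_planted_term_reported_and_decoys_silent(self):
        test, ref, ann = _annotated_sets(
            100, 100, {"GO:0008219": 30}, {"GO:0008219": 5}, n_decoys=50
        )
        res = go_enrichment(test, ref, ann, fdr_threshold=0.01)
        by_term = {e.term: e for e in res}
        planted = by_term["GO:0008219"]
        assert planted.reported and planted.fdr < 0.01
        assert planted.overrepresented_in == "test"
        assert planted.table.a == 30 and planted.table.c == 5
        decoys = [e for e in res if e.reported and e.term != "GO:0008219"]
        assert decoys == []

    def test_identical_proportions_report_nothing(self):
        test, ref, ann = _annotated_sets(50, 50, {"GO:0000001": 10},
                                         {"GO:0000001": 10})
        res = go_enrichment(test, ref, ann, fdr_threshold=0.01)
        assert not any(e.reported for e in res)

    def test_fdr_never_below_p(self):
        test, ref, ann = _annotated_sets(60, 60, {"GO:0000001": 20},
                                         {"GO:0000001": 3}, n_decoys=20)
        for e in go_enrichment(test, ref, ann):
            assert e.fdr >= e.p_value - 1e-15

    def test_overlapping_sets_rejected(self):
        ann = [AnnotationRecord("x", "A", go_terms=frozenset({"GO:0000001"}))]
        with pytest.raises(ValueError):
            go_enrichment({"x"}, {"x"}, ann)

    def test_unannotated_sets_yield_empty(self, caplog):
        ann = [AnnotationRecord("x", "A")]  # no GO terms at all
        assert go_enrichment({"x"}, {"y"}, ann) == []

    def test_label_permutation_false_positive_rate(self):
        """Permuting contig labels breaks every term-set association, so
        almost no term should survive the FDR filter (at most about the
        threshold fraction on average)."""
        rng = np.random.default_rng(99)
        n = 60
        ids = [f"g{i}" for i in range(2 * n)]
        ann = []
        for i in ids:  # 50 random terms, no association with any split
            terms = {f"GO:{1 + j:07d}" for j in range(50) if rng.random() < 0.25}
            ann.append(AnnotationRecord(i, accession=f"A{i}",
                                        go_terms=frozenset(terms | {"GO:0999999"})))
        reported_frac = []
        for _ in range(1000):
            perm = rng.permutation(ids)
            res = go_enrichment(set(perm[:n]), set(perm[n:]), ann,
                                fdr_threshold=0.01)
            reported_frac.append(np.mean([e.reported for e in res]))
        assert np.mean(reported_frac) <= 0.01
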