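"""Regulatory windows, peak overlap, pair funnel and network summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pathlinc import GeneLocus, PeakSet, TFlncRNAPair, ValidationError
from pathlinc.network import (
    RegulatoryEdge,
    build_pairs,
    network_summary,
    overlap_edges,
    regulatory_window,
)


class TestRegulatoryWindow:
    def test_plus_strand_clamped_at_chromosome_start(self):
        locus = GeneLocus("L1", "chr1", 10_000, 11_000, "+")
        assert regulatory_window(locus, 10_000, 0) == ("chr1", 0, 11_000)

    def test_minus_strand_mirrors_upstream(self):
        locus = GeneLocus("L1", "chr1", 10_000, 11_000, "-")
        assert regulatory_window(locus, 10_000, 0) == ("chr1", 10_000, 21_000)

    def test_zero_extents_return_gene_body(self):
        locus = GeneLocus("L1", "chr1", 500, 900, "+")
        assert regulatory_window(locus, 0, 0) == ("chr1", 500, 900)

    def test_negative_extent_rejected(self):
        locus = GeneLocus("L1", "chr1", 500, 900, "+")
        with pytest.raises(ValidationError):
            regulatory_window(locus, -1, 0)


class TestOverlapEdges:
    def test_partial_overlap_counts_one_peak(self):
        peaks = [PeakSet("TFA", [("chr1", 100, 200)])]
        loci = [GeneLocus("L1", "chr1", 150, 300, "+")]
        edges = overlap_edges(peaks, loci, upstream=0, downstream=0)
        assert edges == [RegulatoryEdge("TFA", "L1", 1)]

    def test_half_open_abutment_is_no_overlap(self):
        peaks = [PeakSet("TFA", [("chr1", 100, 150)])]
        loci = [GeneLocus("L1", "chr1", 150, 300, "+")]
        assert overlap_edges(peaks, loci, upstream=0, downstream=0) == []

    def test_peak_chromosome_without_loci_is_silent(self):
        peaks = [PeakSet("TFA", [("chrZ", 0, 10)])]
        loci = [GeneLocus("L1", "chr1", 0, 10, "+")]
        assert overlap_edges(peaks, loci) == []

    def test_matches_all_pairs_brute_force(self, oracles):
        rng = np.random.default_rng(31)
        loci = [
            GeneLocus(f"L{i}", "chr1", int(s), int(s) + int(rng.integers(200, 2000)),
                      "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(5_000, 200_000, 10))
        ]
        peak_sets = [
            PeakSet(f"TF{t}", [
                (("chr1" if rng.random() < 0.9 else "chr2"),) + tuple(sorted((
                    int(rng.integers(0, 210_000)),
                    int(rng.integers(0, 210_000)) + 1,
                )))
                for _ in range(50)
            ])
            for t in range(3)
        ]
        up, down = 3_000, 500
        windows = {l.gene_id: regulatory_window(l, up, down) for l in loci}
        expected = oracles["all_pairs_overlap"](peak_sets, windows)
        got = {(e.tf_id, e.lncrna_id): e.peak_count
               for e in overlap_edges(peak_sets, loci, up, down)}
        assert got == expected

    @given(extra=st.integers(0, 20_000))
    def test_widening_window_never_removes_edges(self, extra):
        rng = np.random.default_rng(77)
        loci = [GeneLocus(f"L{i}", "chr1", int(s), int(s) + 800, "+")
                for i, s in enumerate(rng.integers(2_000, 80_000, 6))]
        peaks = [PeakSet("TFA", [
            tuple(["chr1"]) + tuple(sorted((int(a), int(a) + 300)))
            for a in rng.integers(0, 90_000, 25)
        ])]
        narrow = {(e.tf_id, e.lncrna_id)
                  for e in overlap_edges(peaks, loci, 2_000, 0)}
        wide = {(e.tf_id, e.lncrna_id)
                for e in overlap_edges(peaks, loci, 2_000 + extra, 0)}
        assert narrow <= wide


def _enr(rows):
    df = pd.DataFrame(rows, columns=["regulator", "regulator_class",
                                     "pathway", "significant"])
    df["es"], df["p_perm"], df["res"], df["q"] = 0.9, 0.001, 0.998, 0.01
    return df


def _de(passing, failing=()):
    rows = [(g, 2.0, 1e-4, 1e-3, True) for g in passing]
    rows += [(g, 0.2, 0.5, 0.8, False) for g in failing]
    return pd.DataFrame(rows, columns=["gene", "log2fc", "p", "adj_p",
                                       "passes"])


class TestBuildPairs:
    def test_simple_intersection(self):
        out = build_pairs(
            _enr([("A", "TF", "WNT", True)]),
            _enr([("L1", "lncRNA", "WNT", True),
                  ("L2", "lncRNA", "SHH", True)]),
            [RegulatoryEdge("A", "L1", 1)],
            _de(["A", "L1"]),
        )
        assert [(p.tf_id, p.lncrna_id) for p in out.pairs] == [("A", "L1")]
        assert out.pairs[0].pathways == frozenset({"WNT"})
        assert out.n_candidates == 1

    def test_de_failure_empties_final_but_keeps_candidate(self):
        out = build_pairs(
            _enr([("A", "TF", "WNT", True)]),
            _enr([("L1", "lncRNA", "WNT", True)]),
            [RegulatoryEdge("A", "L1", 1)],
            _de(["A"], failing=["L1"]),
        )
        assert out.n_candidates == 1 and out.pairs == []

    def test_either_mode_relaxes_de_requirement(self):
        out = build_pairs(
            _enr([("A", "TF", "WNT", True)]),
            _enr([("L1", "lncRNA", "WNT", True)]),
            [RegulatoryEdge("A", "L1", 1)],
            _de(["A"], failing=["L1"]),
            de_mode="either",
        )
        assert len(out.pairs) == 1

    def test_pathways_are_union_of_member_pathways(self):
        out = build_pairs(
            _enr([("A", "TF", "WNT", True), ("A", "TF", "SHH", True)]),
            _enr([("L1", "lncRNA", "ERBB2", True)]),
            [RegulatoryEdge("A", "L1", 2)],
            _de(["A", "L1"]),
        )
        assert out.pairs[0].pathways == frozenset({"WNT", "SHH", "ERBB2"})
        assert out.pairs[0].peak_count == 2

    def test_annotation_uses_lncrna_de_record(self):
        de = pd.DataFrame(
            [("A", 5.0, 1e-6, 1e-5, True), ("L1", -1.7, 1e-3, 0.02, True)],
            columns=["gene", "log2fc", "p", "adj_p", "passes"])
        out = build_pairs(
            _enr([("A", "TF", "WNT", True)]),
            _enr([("L1", "lncRNA", "WNT", True)]),
            [RegulatoryEdge("A", "L1", 1)], de)
        assert out.pairs[0].lncrna_log2fc == pytest.approx(-1.7)
        assert out.pairs[0].lncrna_adj_p == pytest.approx(0.02)

    def test_pipeline_containment_chain(self, fitted_results):
        results, _ = fitted_results
        edges = {(e.tf_id, e.lncrna_id) for e in results.edges}
        candidates = {(p.tf_id, p.lncrna_id) for p in results.candidate_pairs}
        finals = {(p.tf_id, p.lncrna_id) for p in results.pairs}
        assert finals <= candidates <= edges
        sig = results.significant()
        sig_pathways = {
            (r, pw) for r, pw in zip(sig.regulator, sig.pathway)}
        for pair in results.pairs:
            assert any((pair.tf_id, pw) in sig_pathways
                       or (pair.lncrna_id, pw) in sig_pathways
                       for pw in pair.pathways)


class TestNetworkSummary:
    def _pair(self, tf, lnc):
        return TFlncRNAPair(tf, lnc, frozenset({"WNT"}), 2.0, 0.01, 1)

    def test_degree_counting(self):
        s = network_summary([self._pair("A", "L1"), self._pair("A", "L2")])
        assert s["tf_degree"]["A"] == 2
        assert s["n_pairs"] == 2

    def test_empty_summary_is_all_zero(self):
        s = network_summary([])
        assert s == {"n_pairs": 0, "tf_degree": {}, "lncrna_degree": {},
                     "pathway_pair_counts": {}}

    def test_random_fixture_matches_brute_counting(self):
        rng = np.random.default_rng(9)
        pairs = [self._pair(f"TF{rng.integers(4)}", f"L{i}")
                 for i in range(20)]
        s = network_summary(pairs)
        for tf in {p.tf_id for p in pairs}:
            assert s["tf_degree"][tf] == sum(p.tf_id == tf for p in pairs)
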