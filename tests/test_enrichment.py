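"""Enrichment score, permutation p, RES transform, FDR, ssGSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pathlinc import SimulationConfig, generate_dataset
from pathlinc.enrichment import (
    _p_from_null,
    bh_fdr,
    call_significant,
    enrichment_score,
    permutation_pvalue,
    res_passes,
    res_transform,
    ssgsea_activity,
)
from pathlinc.exceptions import NoOverlapError, ValidationError
from pathlinc.io import ExpressionMatrix, GeneSetCollection
from pathlinc.ranking import RankedGeneList, build_ranked_list


def _ranked(genes, rs):
    records = pd.DataFrame({
        "gene": genes,
        "r": np.sign(rs) * 0.5,
        "p": np.full(len(genes), 0.1),
        "rs": np.asarray(rs, dtype=float),
    })
    return RankedGeneList(regulator_id="REG", records=records)


class TestEnrichmentScore:
    def test_single_top_hit_scores_plus_one(self):
        ranked = _ranked(["g1", "g2", "g3", "g4"], [4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(ranked, {"g1"}) == pytest.approx(1.0)

    def test_single_bottom_hit_scores_minus_one(self):
        ranked = _ranked(["g1", "g2", "g3", "g4"], [1.0, 1.0, 1.0, 1.0])
        assert enrichment_score(ranked, {"g4"}) == pytest.approx(-1.0)

    def test_hand_enumerated_two_hit_example(self):
        # steps +4/6, -1/2, +2/6, -1/2 -> extreme 2/3 after the first hit
        ranked = _ranked(["g1", "g2", "g3", "g4"], [4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(ranked, {"g1", "g3"}) == pytest.approx(2 / 3)

    def test_absent_members_ignored_and_no_overlap_raises(self):
        ranked = _ranked(["g1", "g2", "g3"], [3.0, 2.0, 1.0])
        assert enrichment_score(ranked, {"g1", "zzz"}) == \
            enrichment_score(ranked, {"g1"})
        with pytest.raises(NoOverlapError):
            enrichment_score(ranked, {"zzz"})

    def test_matches_brute_force_on_random_instances(self, oracles):
        brute = oracles["brute_force_es"]
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(10, 120))
            m = int(rng.integers(1, min(n, 15)))
            rs = np.sort(rng.normal(0, 2, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            members = set(rng.choice(genes, size=m, replace=False))
            is_member = np.array([g in members for g in genes])
            ranked = _ranked(genes, rs)
            assert enrichment_score(ranked, members) == pytest.approx(
                brute(rs, is_member), abs=1e-12)


class TestPermutationPvalue:
    def test_observed_beating_all_nulls_gives_floor(self):
        n = 60
        genes = [f"g{i}" for i in range(n)]
        rs = np.linspace(8, 0.1, n)
        ranked = _ranked(genes, rs)
        p = permutation_pvalue(ranked, {"g0", "g1", "g2"}, n_perm=99, seed=5)
        assert p == pytest.approx(1 / 100)

    def test_zero_observed_es_gives_p_one(self):
        assert _p_from_null(0.0, np.array([0.5, -0.5])) == 1.0

    def test_deterministic_given_seed(self):
        ranked = _ranked([f"g{i}" for i in range(40)],
                         np.linspace(3, -3, 40))
        members = {"g3", "g17", "g30"}
        p1 = permutation_pvalue(ranked, members, n_perm=199, seed=9)
        p2 = permutation_pvalue(ranked, members, n_perm=199, seed=9)
        assert p1 == p2

    def test_planted_regulator_reaches_small_p(self):
        cfg = SimulationConfig(seed=17, regulator_loading=0.8,
                               genes_per_pathway=20)
        expr, sets, _, _, truth = generate_dataset(cfg)
        reg, pathway = sorted(truth.regulator_pathway)[0]
        ranked = build_ranked_list(expr, reg)
        p = permutation_pvalue(ranked, sets.sets[pathway], n_perm=999,
                               seed=23)
        assert p <= 0.005


class TestResTransform:
    @pytest.mark.parametrize("es,p,expected", [
        (0.4, 0.05, 0.9),
        (-0.4, 0.05, -0.9),
        (0.7, 0.5, 0.0),
        (0.0, 0.2, 0.0),
    ])
    def test_piecewise_values(self, es, p, expected):
        assert res_transform(es, p) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            res_transform(0.5, 0.0)
        with pytest.raises(ValidationError):
            res_transform(1.5, 0.5)

    @given(es=st.floats(-1, 1), p=st.floats(1e-12, 1.0))
    def test_bounded_and_sign_consistent(self, es, p):
        res = res_transform(es, p)
        assert -1.0 <= res <= 1.0
        if es != 0 and p < 0.5:
            assert np.sign(res) == np.sign(es)

    @given(es=st.sampled_from([0.3, -0.3]),
           p1=st.floats(1e-9, 1.0), p2=st.floats(1e-9, 1.0))
    def test_monotone_in_p_per_branch(self, es, p1, p2):
        # smaller p always moves res toward the sign of es
        lo, hi = sorted((p1, p2))
        a, b = res_transform(es, lo), res_transform(es, hi)
        assert a >= b if es > 0 else a <= b


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_worked_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.001, 0.5]), [0.002, 0.5])

    def test_empty_input_gives_empty_output(self):
        assert len(bh_fdr([])) == 0

    def test_matches_textbook_step_up_oracle(self, oracles):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), oracles["bh_step_up"](p),
                                       atol=1e-12)


class TestCallSignificant:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["regulator", "regulator_class",
                                           "pathway", "es", "p_perm", "res"])

    def test_published_style_tf_row_passes(self):
        # strong positive TF RES with a tiny permutation p
        df = self._frame([("KLF5", "TF", "WNT", 0.9, 0.001, 0.997719498)])
        out = call_significant(df)
        assert bool(out.significant[0])

    def test_threshold_boundaries_are_strict(self):
        df = self._frame([
            ("TFX", "TF", "WNT", 0.9, 0.005, 0.990),       # exactly at cut
            ("LNCX", "lncRNA", "WNT", 0.9, 0.00255, 0.9949),
        ])
        out = call_significant(df)
        assert not out.significant.any()

    def test_negative_res_tf_retained_by_absolute_rule(self):
        df = self._frame([("ESR1", "TF", "ERK", -0.9, 0.001, -0.991404011)])
        assert bool(call_significant(df).significant[0])

    def test_fdr_gate_blocks_isolated_weak_p(self):
        rows = [("L%d" % i, "lncRNA", "WNT", 0.9, 0.4, 0.2)
                for i in range(20)]
        rows.append(("LTOP", "lncRNA", "WNT", 0.9, 0.02, 0.996))
        out = call_significant(self._frame(rows))
        top = out[out.regulator == "LTOP"].iloc[0]
        assert abs(top.res) > 0.995 and top.q >= 0.05
        assert not top.significant

    def test_res_passes_uses_class_specific_cuts(self):
        assert res_passes(0.992, "TF")
        assert not res_passes(0.992, "lncRNA")


class TestSsgsea:
    def _expr(self, values, classes=None):
        genes = list(values.index)
        classes = classes or ["mRNA"] * len(genes)
        return ExpressionMatrix(
            values=values,
            gene_classes=pd.Series(classes, index=genes),
            sample_groups=pd.Series(
                ["tumor"] * (values.shape[1] - 1) + ["control"],
                index=values.columns),
        )

    def test_top_genes_set_scores_positive(self):
        values = pd.DataFrame(
            {"S1": [9.0, 8.0, 3.0, 2.0, 1.0], "S2": [1.0, 2.0, 3.0, 4.0, 5.0]},
            index=["g1", "g2", "g3", "g4", "g5"])
        expr = self._expr(values)
        sets = GeneSetCollection({"TOP": frozenset({"g1", "g2"})})
        df = ssgsea_activity(expr, sets, rescale=False)
        s1 = df[(df["sample"] == "S1")]["activity"].iloc[0]
        s2 = df[(df["sample"] == "S2")]["activity"].iloc[0]
        assert s1 > 0 and s1 > s2

    def test_identical_columns_get_identical_activity(self):
        col = [5.0, 4.0, 3.0, 2.0, 1.0]
        values = pd.DataFrame({"S1": col, "S2": col, "S3": col[::-1]},
                              index=[f"g{i}" for i in range(5)])
        expr = self._expr(values)
        sets = GeneSetCollection({"A": frozenset({"g0", "g1"})})
        df = ssgsea_activity(expr, sets).set_index("sample")
        assert df.loc["S1", "activity"] == df.loc["S2", "activity"]

    def test_matches_hand_enumeration_on_five_gene_toy(self):
        values = pd.DataFrame({"S1": [7.0, 5.0, 6.0, 2.0, 1.0]},
                              index=["g1", "g2", "g3", "g4", "g5"])
        expr = self._expr(values)
        sets = GeneSetCollection({"A": frozenset({"g1", "g2"})})
        # order by S1 desc: g1(7,rank5), g3(6,rank4), g2(5,rank3), g4, g5
        # hit weights: g1->5, g2->3 (sum 8); miss step 1/3
        hit_cdf = np.array([5 / 8, 5 / 8, 1.0, 1.0, 1.0])
        miss_cdf = np.array([0, 1 / 3, 1 / 3, 2 / 3, 1.0])
        expected = float(np.sum(hit_cdf - miss_cdf))
        df = ssgsea_activity(expr, sets, rescale=False)
        assert df["activity"].iloc[0] == pytest.approx(expected)

    def test_invariant_to_gene_row_order(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(5, 2, (8, 3)),
                              index=[f"g{i}" for i in range(8)],
                              columns=["S1", "S2", "S3"])
        expr = self._expr(values)
        sets = GeneSetCollection({"A": frozenset({"g1", "g5", "g7"})})
        a = ssgsea_activity(expr, sets)
        shuffled = values.iloc[[5, 2, 7, 0, 3, 6, 1, 4]]
        expr2 = self._expr(shuffled)
        b = ssgsea_activity(expr2, sets)
        merged = a.merge(b, on=["sample", "pathway"])
        np.testing.assert_allclose(merged["activity_x"],
                                   merged["activity_y"], atol=1e-12)

    def test_no_overlap_raises(self):
        values = pd.DataFrame({"S1": [1.0, 2.0], "S2": [2.0, 1.0]},
                              index=["g1", "g2"])
        expr = self._expr(values)
        with pytest.raises(NoOverlapError):
            ssgsea_activity(expr, GeneSetCollection({"A": frozenset({"zz"})}))
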