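import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import hccpipe as h
from conftest import brute_force_bh


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            h.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert h.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(h.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            h.bh_adjust([0.5, 1.5])

    def test_matches_step_up_definition_on_permutations(self):
        base = [0.001, 0.02, 0.3, 0.04, 0.9, 0.11]
        for n in range(1, 7):
            for perm in itertools.permutations(base[:n]):
                np.testing.assert_allclose(
                    h.bh_adjust(perm), brute_force_bh(perm), atol=1e-12
                )


class TestAnovaPerGene:
    def test_hand_sums_of_squares(self, expr_from_groups):
        e, ann = expr_from_groups(T1=[1, 2, 3], T2=[2, 3, 4], T3=[3, 4, 5])
        t = h.anova_per_gene(e, ann)
        assert t.data.loc["G1", "statistic"] == pytest.approx(3.0)
        assert t.data.loc["G1", "effect"] == pytest.approx(0.0)  # log2 var([2,3,4])
        assert t.data.loc["G1", "p_value"] == pytest.approx(st.f.sf(3.0, 2, 6))

    def test_equal_means_give_f_zero_p_one(self, expr_from_groups):
        e, ann = expr_from_groups(T1=[1, 3], T2=[1, 3], T3=[1, 3])
        t = h.anova_per_gene(e, ann)
        assert t.data.loc["G1", "statistic"] == 0.0
        assert t.data.loc["G1", "p_value"] == 1.0
        assert t.data.loc["G1", "effect"] == -np.inf

    def test_small_group_named_in_error(self, expr_from_groups):
        e, ann = expr_from_groups(T1=[1, 2], T2=[3], T3=[4, 5])
        with pytest.raises(ValueError, match="T2"):
            h.anova_per_gene(e, ann)

    def test_cirrhosis_excluded_unless_passed(self, expr_from_groups):
        e, ann = expr_from_groups(
            cirrhosis=[100.0, 101.0], T1=[1, 2], T2=[2, 3], T3=[3, 4]
        )
        t = h.anova_per_gene(e, ann)  # huge cirrhosis values must not leak in
        # SSB = 2*(1+0+1) = 4, df1 = 2; SSW = 3*0.5 = 1.5, df2 = 3 -> F = 4
        assert t.data.loc["G1", "statistic"] == pytest.approx(4.0)
        t4 = h.anova_per_gene(e, ann, groups=("cirrhosis", "T1", "T2", "T3"))
        assert t4.data.loc["G1", "statistic"] > 1000

    def test_matches_closed_form_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            sizes = rng.integers(2, 6, size=rng.integers(2, 5))
            groups = [rng.normal(size=n) for n in sizes]
            values = np.concatenate(groups)
            sample_ids, rows = [], []
            stages = ["T1", "T2", "T3", "T1"]  # reuse tokens for >3 groups
            labels = []
            # build an annotation with one stage per group (max 3 groups here)
            sizes = sizes[:3]
            groups = groups[:3]
            if len(groups) < 2:
                continue
            e_dict = {}
            for gi, vals in enumerate(groups):
                for j, v in enumerate(vals):
                    sid = f"g{gi}s{j}"
                    sample_ids.append(sid)
                    e_dict[sid] = v
                    rows.append((sid, "tumor", f"T{gi + 1}", "unknown", "t"))
            e = h.ExpressionMatrix(
                pd.DataFrame([list(e_dict.values())], index=["G1"],
                             columns=list(e_dict.keys()))
            )
            ann = h.SampleAnnotation(
                pd.DataFrame(rows, columns=["sample_id", "tissue_class", "stage",
                                            "phenotype", "cohort"]).set_index("sample_id")
            )
            t = h.anova_per_gene(e, ann, groups=tuple(f"T{i+1}" for i in range(len(groups))))
            f_ref, p_ref = st.f_oneway(*groups)
            assert t.data.loc["G1", "statistic"] == pytest.approx(f_ref, abs=1e-10)
            assert t.data.loc["G1", "p_value"] == pytest.approx(p_ref, abs=1e-10)


class TestSelectStageGenes:
    def _table(self, fdr, effect):
        return h.GeneStatTable(
            pd.DataFrame({"statistic": [1.0], "p_value": [0.01],
                          "fdr": [fdr], "effect": [effect]}, index=["G1"])
        )

    def test_passing_gene_selected(self):
        assert h.select_stage_genes(self._table(0.20, 0.0)) == ["G1"]

    def test_fdr_boundary_strict(self):
        assert h.select_stage_genes(self._table(0.25, 0.0)) == []

    def test_neg_inf_effect_excluded(self):
        assert h.select_stage_genes(self._table(0.01, -np.inf)) == []


class TestClusterGenes:
    def test_perfect_blocks_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        rows, genes = [], []
        for i in range(4):
            rows.append(base * (1 + 0.1 * i) + i)  # corr +1 block
            genes.append(f"A{i}")
        for i in range(3):
            rows.append(-base * (1 + 0.1 * i))  # corr -1 with block A
            genes.append(f"B{i}")
        e = h.ExpressionMatrix(pd.DataFrame(rows, index=genes,
                                            columns=[f"s{j}" for j in range(12)]))
        cl = h.cluster_genes(e, genes, 2)
        assert sorted(cl.clusters[1]) == ["A0", "A1", "A2", "A3"]
        assert sorted(cl.clusters[2]) == ["B0", "B1", "B2"]

    def test_k_one_and_singletons(self):
        rng = np.random.default_rng(1)
        e = h.ExpressionMatrix(pd.DataFrame(rng.normal(size=(4, 6)),
                                            index=list("ABCD"),
                                            columns=[f"s{j}" for j in range(6)]))
        assert h.cluster_genes(e, list("ABCD"), 1).clusters == {
            1: list("ABCD")
        } or set(h.cluster_genes(e, list("ABCD"), 1).clusters[1]) == set("ABCD")
        singles = h.cluster_genes(e, list("ABCD"), 4).clusters
        assert sorted(len(v) for v in singles.values()) == [1, 1, 1, 1]

    def test_zero_variance_gene_named(self):
        e = h.ExpressionMatrix(pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]],
                                            index=["FLAT", "OK"],
                                            columns=["s1", "s2", "s3"]))
        with pytest.raises(ValueError, match="FLAT"):
            h.cluster_genes(e, ["FLAT", "OK"], 2)


class TestClusterSamples:
    def test_separated_groups_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(5, 4))
        b = rng.normal(100, 0.1, size=(5, 4))
        e = h.ExpressionMatrix(pd.DataFrame(
            np.hstack([a, b]), index=list("ABCDE"),
            columns=[f"a{j}" for j in range(4)] + [f"b{j}" for j in range(4)]))
        labels = h.cluster_samples(e, 2)
        assert len(set(labels[[f"a{j}" for j in range(4)]])) == 1
        assert len(set(labels[[f"b{j}" for j in range(4)]])) == 1
        assert labels["a0"] != labels["b0"]

    def test_duplicate_samples_co_cluster(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=5)
        cols = {f"s{j}": col + (j // 2) * 10 for j in range(6)}  # s0==s1 etc.
        e = h.ExpressionMatrix(pd.DataFrame(cols, index=list("ABCDE")))
        for k in (2, 3):
            labels = h.cluster_samples(e, k)
            assert labels["s0"] == labels["s1"]


class TestSignatureScore:
    def test_single_gene_equals_z(self):
        e = h.ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"],
                                            columns=["s1", "s2", "s3"]))
        s = h.signature_score(e, ["G1"])
        np.testing.assert_allclose(s.scores.values, [-1.0, 0.0, 1.0])

    def test_opposite_genes_cancel(self):
        e = h.ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                                            index=["G1", "G2"],
                                            columns=["s1", "s2", "s3"]))
        np.testing.assert_allclose(h.signature_score(e, ["G1", "G2"]).scores.values,
                                   0.0, atol=1e-12)

    def test_scores_mean_zero(self):
        rng = np.random.default_rng(4)
        e = h.ExpressionMatrix(pd.DataFrame(rng.normal(size=(6, 9)),
                                            index=list("ABCDEF"),
                                            columns=[f"s{j}" for j in range(9)]))
        s = h.signature_score(e, list("ABC"))
        assert abs(s.scores.mean()) < 1e-9


class TestTeffSignature:
    def _matrix(self, genes):
        rng = np.random.default_rng(5)
        return h.ExpressionMatrix(pd.DataFrame(rng.normal(size=(len(genes), 6)),
                                               index=genes,
                                               columns=[f"s{j}" for j in range(6)]))

    def test_five_gene_default(self):
        e = self._matrix(list(h.TEFF_GENES) + ["OTHER"])
        s = h.teff_signature(e)
        assert set(s.genes) == set(h.TEFF_GENES)

    def test_missing_gene_named(self):
        e = self._matrix(["GZMA", "GZMB", "PRF1", "CD8A"])
        with pytest.raises(KeyError, match="EOMES"):
            h.teff_signature(e)

    def test_custom_single_gene(self):
        e = self._matrix(["X"])
        s = h.teff_signature(e, genes=("X",))
        np.testing.assert_allclose(s.scores.values,
                                   h.signature_score(e, ["X"]).scores.values)


class TestTrendSummary:
    def _score(self, values, ann):
        return h.SignatureScore(pd.Series(values, index=ann.sample_ids))

    @pytest.mark.parametrize(
        "group_means,verdict",
        [([2, 1, 0, -1], "decreasing"),
         ([0, 1, 0.5, 0.2], "up_then_down"),
         ([-1, 0, 1, 2], "increasing"),
         ([0, 0, 0, 0], "none")],
    )
    def test_verdicts(self, stage_annotation, group_means, verdict):
        values = np.repeat(group_means, 3).astype(float)
        score = self._score(values, stage_annotation)
        means, v = h.trend_summary(score, stage_annotation,
                                   ("cirrhosis", "T1", "T2", "T3"))
        assert v == verdict
        np.testing.assert_allclose(means.values, group_means)

    def test_empty_group_rejected(self, stage_annotation):
        score = self._score(np.zeros(12), stage_annotation)
        with pytest.raises(ValueError, match="TX"):
            h.trend_summary(score, stage_annotation, ("T1", "TX"))
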