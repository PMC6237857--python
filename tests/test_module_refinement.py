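import numpy as np
import pandas as pd
import pytest

import hccpipe as h


def _expr(rows, genes=None, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"G{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return h.ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))


class TestCorrelationMatrix:
    def test_duplicated_gene_perfect_correlation(self):
        e = _expr([[1, 2, 3], [1, 2, 3]], genes=["A", "B"])
        c = h.correlation_matrix(e, ["A", "B"])
        assert c.data.loc["A", "B"] == pytest.approx(1.0)

    def test_negated_gene(self):
        e = _expr([[1, 2, 3], [-1, -2, -3]], genes=["A", "B"])
        assert h.correlation_matrix(e, ["A", "B"]).data.loc["A", "B"] == pytest.approx(-1.0)

    def test_hand_pearson(self):
        e = _expr([[1, 2, 3], [1, 2, 4]], genes=["A", "B"])
        r = h.correlation_matrix(e, ["A", "B"]).data.loc["A", "B"]
        assert r == pytest.approx(1.5 / np.sqrt(7 / 3), abs=1e-12)  # 0.98198...

    def test_zero_variance_named(self):
        e = _expr([[1, 1, 1], [1, 2, 3]], genes=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            h.correlation_matrix(e, ["FLAT", "OK"])


class TestMinReferenceMatrix:
    def _mat(self, off, genes=("A", "B")):
        df = pd.DataFrame([[1.0, off], [off, 1.0]], index=genes, columns=genes)
        return h.CorrelationMatrix(df)

    def test_single_input_identity(self):
        m = self._mat(0.4)
        ref = h.min_reference_matrix([m])
        np.testing.assert_allclose(ref.data.values, m.data.values)

    def test_cellwise_minimum(self):
        ref = h.min_reference_matrix([self._mat(0.9), self._mat(0.2)])
        assert ref.data.loc["A", "B"] == pytest.approx(0.2)
        assert np.allclose(np.diag(ref.data.values), 1.0)

    def test_result_below_every_input(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(4):
            x = rng.normal(size=(5, 30))
            mats.append(h.correlation_matrix(_expr(x, genes=list("ABCDE")),
                                             list("ABCDE")))
        ref = h.min_reference_matrix(mats)
        for m in mats:
            assert (ref.data.values <= m.data.values + 1e-12).all()

    def test_missing_genes_dropped_with_warning(self, caplog):
        a = self._mat(0.5, genes=("A", "B"))
        v = np.full((3, 3), 0.3)
        np.fill_diagonal(v, 1.0)
        b = h.CorrelationMatrix(pd.DataFrame(v, index=list("ABC"), columns=list("ABC")))
        with caplog.at_level("WARNING", logger="hccpipe"):
            ref = h.min_reference_matrix([a, b])
        assert ref.gene_ids == ["A", "B"]
        assert ref.data.loc["A", "B"] == pytest.approx(0.3)


class TestExtractModules:
    def _planted_reference(self, block=5, total=15, inside=0.7, outside=0.0):
        genes = [f"G{i:02d}" for i in range(total)]
        v = np.full((total, total), outside)
        v[:block, :block] = inside
        np.fill_diagonal(v, 1.0)
        return h.ReferenceCorrelationMatrix(
            pd.DataFrame(v, index=genes, columns=genes)
        ), genes[:block]

    def test_planted_block_is_module1(self):
        ref, block = self._planted_reference()
        a = h.extract_modules(ref, 2)
        assert sorted(a.genes("module1")) == block
        assert a.internal_medians["module1"] >= a.internal_medians["module2"]

    def test_equal_internal_medians_tie_break_warns(self, caplog):
        # two 2-gene blocks with identical internal correlation -> tied medians
        genes = list("ABCD")
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 0.5
        v[2, 3] = v[3, 2] = 0.5
        np.fill_diagonal(v, 1.0)
        ref = h.ReferenceCorrelationMatrix(pd.DataFrame(v, index=genes, columns=genes))
        with caplog.at_level("WARNING", logger="hccpipe"):
            a = h.extract_modules(ref, 2)
        assert any("tie" in r.message for r in caplog.records)
        # smallest member id wins the tie: the block containing "A"
        assert sorted(a.genes("module1")) == ["A", "B"]

    def test_fully_degenerate_matrix_does_not_crash(self):
        genes = list("ABCD")
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        ref = h.ReferenceCorrelationMatrix(pd.DataFrame(v, index=genes, columns=genes))
        a = h.extract_modules(ref, 2)
        assert set(a.labels.index) == set(genes)

    def test_singleton_median_never_preferred(self):
        ref, block = self._planted_reference(block=4, total=6, inside=0.8)
        a = h.extract_modules(ref, k=3)  # background may split into singletons
        assert sorted(a.genes("module1")) == block


class TestMedianPairwiseCorrelation:
    def test_median_of_three_pairs(self):
        # construct genes with known pairwise correlations via small vectors
        e = _expr([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], genes=["A", "B", "C"])
        # pairs: AB=1, AC=-1, BC=-1 -> median -1
        assert h.median_pairwise_correlation(e, ["A", "B", "C"]) == pytest.approx(-1.0)

    def test_duplicated_pair(self):
        e = _expr([[1, 2, 3], [1, 2, 3]], genes=["A", "B"])
        assert h.median_pairwise_correlation(e, ["A", "B"]) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        e = _expr(rng.normal(size=(6, 1000)), genes=list("ABCDEF"))
        assert abs(h.median_pairwise_correlation(e, list("ABCDEF"))) < 0.1

    def test_needs_two_genes(self):
        e = _expr([[1, 2, 3]], genes=["A"])
        with pytest.raises(ValueError):
            h.median_pairwise_correlation(e, ["A"])


class TestSubtypeDiscrimination:
    def test_shifted_subtype_has_highest_scores(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 40))
        x[:, :10] += 2.0  # subtype "emt" carries the module up-shift
        e = _expr(x, genes=list("ABCDE"),
                  samples=[f"s{j}" for j in range(40)])
        labels = pd.Series(["emt"] * 10 + ["other"] * 30, index=e.sample_ids)
        table, p = h.subtype_discrimination(e, list("ABCDE"), labels, "emt")
        assert table[table.subtype == "emt"].score.mean() > \
            table[table.subtype == "other"].score.mean()
        assert p < 1e-4

    def test_single_sample_groups_exact_p_one(self):
        e = _expr([[1.0, 2.0], [2.0, 1.0], [1.5, 2.5]], genes=list("ABC"),
                  samples=["s1", "s2"])
        labels = pd.Series(["x", "y"], index=["s1", "s2"])
        _, p = h.subtype_discrimination(e, list("ABC"), labels, "x")
        assert p == pytest.approx(1.0)

    def test_missing_subtype_rejected(self):
        e = _expr(np.random.default_rng(3).normal(size=(3, 6)), genes=list("ABC"))
        labels = pd.Series(["a"] * 6, index=e.sample_ids)
        with pytest.raises(ValueError):
            h.subtype_discrimination(e, list("ABC"), labels, "zzz")


class TestOnSimulatedIndications:
    def test_shared_module_recovered_specific_module_rejected(self):
        datasets, truth = h.simulate_indications(
            n_datasets=5, n_candidate_genes=60, shared_module_size=15,
            lambda_shared=0.85, specific_module_size=10, lambda_specific=0.85,
            n_samples=150, seed=21,
        )
        mats = [h.correlation_matrix(d, d.gene_ids) for d in datasets]
        ref = h.min_reference_matrix(mats)
        a = h.extract_modules(ref, 2)
        assert set(a.genes("module1")) == set(truth.shared_genes)
        # the dataset-specific module collapses to background in the minimum
        assert set(truth.specific_genes) <= set(a.genes("module2"))

    def test_within_module_correlation_approaches_lambda_squared(self):
        datasets, truth = h.simulate_indications(
            n_datasets=1, n_candidate_genes=30, shared_module_size=10,
            lambda_shared=0.8, specific_module_size=0, n_samples=800, seed=22,
        )
        med = h.median_pairwise_correlation(datasets[0], list(truth.shared_genes))
        assert med == pytest.approx(0.64, abs=0.05)
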