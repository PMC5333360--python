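"""Normalization, the simplified NB test, BH adjustment, Wilcoxon and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import wilcoxon_exact_oracle
from dsxtargets.diffexpr import (
    bh_adjust,
    fpkm,
    nb_test,
    replicate_qc,
    run_contrast,
    size_factors,
    wilcoxon_ranksum,
)


class TestSizeFactors:
    def test_doubled_sample(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = size_factors(counts)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_matches_direct_formula_on_random_matrix(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(500, 6)), columns=[f"s{i}" for i in range(6)]
        )
        f = size_factors(counts)
        mat = counts.to_numpy(dtype=float)
        keep = np.all(mat > 0, axis=1)
        geo = np.exp(np.mean(np.log(mat[keep]), axis=1))
        expected = np.median(mat[keep] / geo[:, None], axis=0)
        assert np.allclose(f.to_numpy(), expected)

    def test_no_all_positive_gene_is_an_error(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [2, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors(counts)


class TestFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s": [100, 10 ** 6 - 100]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 5000})
        assert fpkm(counts, lengths).loc["g1", "s"] == pytest.approx(100.0)

    def test_depth_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({"s": rng.poisson(100, 50)})
        lengths = pd.Series(rng.integers(500, 5000, 50), index=counts.index)
        doubled = counts * 2
        assert np.allclose(fpkm(counts, lengths), fpkm(doubled, lengths))

    def test_matches_hand_formula(self):
        counts = pd.DataFrame({"a": [10, 30], "b": [7, 3]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 2000, "g2": 500})
        out = fpkm(counts, lengths)
        assert out.loc["g1", "a"] == pytest.approx(10 / (2.0 * 40 / 1e6))
        assert out.loc["g2", "b"] == pytest.approx(3 / (0.5 * 10 / 1e6))

    def test_zero_column_sum_rejected(self):
        counts = pd.DataFrame({"a": [0, 0]})
        with pytest.raises(ValueError, match="zero column sum"):
            fpkm(counts, pd.Series([100, 100], index=counts.index))


class TestNbTest:
    def _frame(self, a, b):
        cols = {f"a{i}": a[:, i] for i in range(a.shape[1])}
        cols.update({f"b{i}": b[:, i] for i in range(b.shape[1])})
        return pd.DataFrame(cols)

    def test_identical_groups_null(self):
        a = np.tile([[10, 20, 30]], (5, 1))
        counts = self._frame(a, a)
        res = nb_test(counts, ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                      factors=pd.Series(1.0, index=counts.columns))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p"] >= 0.99).all()

    def test_group_swap_negates_lfc_and_preserves_p(self):
        rng = np.random.default_rng(2)
        a = rng.negative_binomial(10, 0.1, size=(100, 4))
        b = rng.negative_binomial(10, 0.05, size=(100, 4))
        counts = self._frame(a, b)
        ones = pd.Series(1.0, index=counts.columns)
        ga, gb = [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
        r1 = nb_test(counts, ga, gb, factors=ones)
        r2 = nb_test(counts, gb, ga, factors=ones)
        assert np.allclose(r1["log2fc"], -r2["log2fc"])
        assert np.allclose(r1["p"].fillna(-1), r2["p"].fillna(-1))

    def test_all_zero_genes_reported_as_null(self):
        a = np.zeros((3, 3), dtype=int)
        counts = self._frame(a, a)
        res = nb_test(counts, ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                      factors=pd.Series(1.0, index=counts.columns))
        assert (res["p"] == 1.0).all()
        assert (res["log2fc"] == 0.0).all()

    def test_low_count_genes_excluded_from_testing(self):
        a = np.array([[1, 0, 0], [50, 60, 55]])
        b = np.array([[0, 0, 0], [45, 52, 58]])
        counts = self._frame(a, b)
        res = nb_test(counts, ["a0", "a1", "a2"], ["b0", "b1", "b2"],
                      factors=pd.Series(1.0, index=counts.columns), min_total=2.0)
        assert np.isnan(res["p"].iloc[0])
        assert not np.isnan(res["p"].iloc[1])

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"a0": [1], "b0": [2], "b1": [3]})
        with pytest.raises(ValueError, match=">= 2"):
            nb_test(counts, ["a0"], ["b0", "b1"])

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(3)
        r = 10.0  # alpha = 0.1
        a = rng.negative_binomial(r, r / (r + 400.0), size=(200, 6))
        b = rng.negative_binomial(r, r / (r + 100.0), size=(200, 6))
        counts = self._frame(a, b)
        res = nb_test(counts, [f"a{i}" for i in range(6)],
                      [f"b{i}" for i in range(6)],
                      factors=pd.Series(1.0, index=counts.columns))
        assert (res["p"] < 0.05).mean() > 0.95
        assert res["log2fc"].median() == pytest.approx(2.0, abs=0.2)


class TestBhAdjust:
    def test_hand_worked_equal_steps(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_hand_worked_mixed(self):
        got = bh_adjust([0.005, 0.011, 0.02, 0.04])
        assert np.allclose(got, [0.02, 0.022, 0.0267, 0.04], atol=1e-4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_nan_propagates_and_excluded_from_m(self):
        got = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(got[1])
        # m = 2, not 3
        assert got[0] == pytest.approx(0.02)
        assert got[2] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_on_random_vector(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_order_preserving(self, p):
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)  # order-preserving
        assert np.all((q >= np.asarray(p) - 1e-12) & (q <= 1.0))


class TestWilcoxon:
    def test_separated_triples_exact_p(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("nx,ny", [(3, 4), (5, 5), (2, 8)])
    def test_matches_enumeration_oracle(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x = rng.normal(size=nx)
        y = rng.normal(0.5, size=ny)
        _, p = wilcoxon_ranksum(x, y)
        assert p == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestReplicateQc:
    def _design(self, samples):
        return pd.DataFrame(
            {
                "sex": ["F"] * len(samples),
                "tissue": ["brain"] * len(samples),
                "treatment": ["control"] * len(samples),
                "replicate": range(1, len(samples) + 1),
            },
            index=samples,
        )

    def test_duplicate_replicates_correlate_perfectly(self):
        counts = pd.DataFrame({"r1": [10, 50, 200], "r2": [10, 50, 200]})
        lengths = pd.Series([1000, 1000, 1000], index=counts.index)
        qc = replicate_qc(counts, self._design(["r1", "r2"]), lengths)
        assert qc["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_log_fpkm_is_minus_one(self):
        # lengths chosen so fpkm = counts/1000 and log2(fpkm+1) is linear
        counts = pd.DataFrame({"r1": [1000, 3000, 7000], "r2": [7000, 3000, 1000]})
        lengths = pd.Series([1e9 / 11] * 3, index=counts.index)
        qc = replicate_qc(counts, self._design(["r1", "r2"]), lengths)
        assert qc["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_sample_flagged(self):
        counts = pd.DataFrame({"r1": [5, 5, 5], "r2": [1, 2, 3]})
        lengths = pd.Series([1000.0] * 3, index=counts.index)
        qc = replicate_qc(counts, self._design(["r1", "r2"]), lengths)
        assert not qc["defined"].iloc[0]


class TestRunContrast:
    def test_contrast_parsing_and_direction(self, small_dataset):
        cfg, genome, genes, truth, counts, design, lengths = small_dataset
        res = run_contrast(counts, design, "CF-CM", cfg.switch_tissue)
        assert {"log2fc", "p", "p_adj"} <= set(res.columns)
        # planted female-biased bias in the switch tissue is negative for
        # shared-antagonistic genes (male-biased there)
        anta = truth.genes.loc[
            truth.genes["gene_class"] == "shared_antagonistic", "gene_id"
        ]
        assert res.loc[anta, "log2fc"].median() < -1

    def test_bad_contrast_label_rejected(self, small_dataset):
        _, _, _, _, counts, design, _ = small_dataset
        with pytest.raises(ValueError, match="contrast"):
            run_contrast(counts, design, "XX-YY", "brain")
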