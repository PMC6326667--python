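"""NB engine contracts: size factors, filters, nRPKM, BH, DEG calling, the
Wald contrast machinery (calibration, recovery, antisymmetry, external
cross-checks) and the sequencing-day bias filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midtraject import expression_core as ec
from midtraject import synthetic_data as sd
from midtraject.expression_core import DEConfig


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 100, size=20)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        assert np.allclose(ec.size_factors(counts), 1.0)

    def test_scaling_equivariance(self, rng):
        base = rng.integers(1, 100, size=30)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = ec.size_factors(counts)
        assert f["b"] == pytest.approx(2 * f["a"])

    def test_hand_computed_example(self, toy_counts):
        f = ec.size_factors(toy_counts)
        assert f.to_numpy() == pytest.approx([2 ** -0.5, 2 ** 0.5])

    def test_gene_permutation_invariance(self, small_counts):
        f1 = ec.size_factors(small_counts)
        f2 = ec.size_factors(small_counts.sample(frac=1, random_state=0))
        assert np.allclose(f1, f2)

    def test_no_reference_gene_error(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ec.NoReferenceGeneError):
            ec.size_factors(counts)


class TestLowCountFilter:
    def test_total_count_boundary(self):
        counts = pd.DataFrame(
            {"s1": [25, 25], "s2": [24, 25]}, index=["dropme", "keepme"]
        )
        kept = ec.low_count_filter(counts, 50)
        assert list(kept.index) == ["keepme"]

    def test_zero_threshold_keeps_everything(self, small_counts):
        pd.testing.assert_frame_equal(ec.low_count_filter(small_counts, 0), small_counts)

    def test_idempotence_and_brute_force(self, rng):
        counts = pd.DataFrame(rng.integers(0, 20, size=(100, 5)))
        once = ec.low_count_filter(counts, 50)
        twice = ec.low_count_filter(once, 50)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == [i for i in counts.index if counts.loc[i].sum() >= 50]


class TestNrpkm:
    def test_direct_formula(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(10, 3)).astype(float),
            index=[f"g{i}" for i in range(10)],
        )
        factors = pd.Series([1.0, 0.8, 1.3], index=counts.columns)
        lengths = pd.Series(rng.uniform(0.5, 5, 10), index=counts.index)
        got = ec.nrpkm(counts, factors, lengths)
        for j in counts.columns:
            total = (counts[j] / factors[j]).sum()
            for g in counts.index:
                expected = (counts.loc[g, j] / factors[j]) / (lengths[g] * total / 1e6)
                assert got.loc[g, j] == pytest.approx(expected)

    def test_length_homogeneity(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(4, 2)).astype(float))
        factors = pd.Series([1.0, 1.0], index=counts.columns)
        lengths = pd.Series([1.0, 1.0, 1.0, 1.0], index=counts.index)
        a = ec.nrpkm(counts, factors, lengths)
        b = ec.nrpkm(counts, factors, 2 * lengths)
        assert np.allclose(b.to_numpy(), a.to_numpy() / 2)

    def test_zero_gene_and_bad_length(self):
        counts = pd.DataFrame({"s": [0.0, 10.0]}, index=["z", "g"])
        factors = pd.Series([1.0], index=["s"])
        out = ec.nrpkm(counts, factors, pd.Series([1.0, 1.0], index=["z", "g"]))
        assert (out.loc["z"] == 0).all()
        with pytest.raises(ValueError):
            ec.nrpkm(counts, factors, pd.Series([0.0, 1.0], index=["z", "g"]))


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert ec.bh_adjust([0.01, 0.02, 0.09]) == pytest.approx([0.03, 0.03, 0.09])

    def test_single_p_unchanged(self):
        assert ec.bh_adjust([0.42]) == pytest.approx([0.42])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_property(self, ps):
        adj = ec.bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15) and np.all(adj <= 1.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ec.bh_adjust(p), ref)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            ec.bh_adjust([0.5, 1.5])


class TestCallDegs:
    def test_threshold_boundaries_inclusive(self):
        res = pd.DataFrame(
            {
                "log2fc": [0.3, 0.29, 2.0, -0.5],
                "padj": [0.1, 0.01, 0.11, 0.05],
            },
            index=["in_edge", "out_small_fc", "out_padj", "in_down"],
        )
        degs = ec.call_degs(res, DEConfig())
        assert set(degs.index) == {"in_edge", "in_down"}
        assert degs.loc["in_down", "direction"] == "down"

    def test_brute_force_equivalence(self, rng):
        res = pd.DataFrame(
            {"log2fc": rng.normal(0, 1, 300), "padj": rng.uniform(0, 1, 300)}
        )
        degs = set(ec.call_degs(res, DEConfig()).index)
        brute = {
            i for i in res.index
            if abs(res.loc[i, "log2fc"]) >= 0.3 and res.loc[i, "padj"] <= 0.1
        }
        assert degs == brute


class TestContrasts:
    def test_antisymmetry(self, two_cell_fit):
        _, design, counts, fit = two_cell_fit
        ab = ec.contrast(fit, ("WT", 6, "SE"), ("WT", 12, "SE"))
        ba = ec.contrast(fit, ("WT", 12, "SE"), ("WT", 6, "SE"))
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_effect_recovery(self, two_cell_fit):
        truth, design, counts, fit = two_cell_fit
        res = ec.contrast(fit, ("WT", 6, "SE"), ("WT", 12, "SE"))
        planted = truth.class_genes(3).intersection(res.index)
        assert len(planted) >= 100
        sign = np.where(truth.genes.loc[planted, "direction"] == "up", 1.0, -1.0)
        mean_lfc = (res.loc[planted, "log2fc"] * sign).mean()
        assert mean_lfc == pytest.approx(1.0, abs=0.1)

    def test_type_one_error_range(self):
        design = sd.make_design(6, n_batches=6, seed=0)
        truth = sd.make_truth(2000, {}, 1.0, seed=1)
        counts = sd.simulate_counts(truth, design, seed=2)
        fit = ec.fit_nb_glm(counts, design)
        res = ec.contrast(fit, ("WT", 12, "SE"), ("TG", 12, "SE"))
        rate = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_matches_statsmodels_nb_glm(self, two_cell_fit):
        sm = pytest.importorskip("statsmodels.api")
        truth, design, counts, fit = two_cell_fit
        X = np.column_stack(
            [
                (design["age_months"] == 12).astype(float),  # WT_12_SE sorts first
                (design["age_months"] == 6).astype(float),
            ]
        )
        offset = np.log(fit.size_factors.to_numpy())
        for gi, g in enumerate(counts.index[:8]):
            model = sm.GLM(
                counts.loc[g].to_numpy(),
                X,
                family=sm.families.NegativeBinomial(alpha=float(fit.alpha[g])),
                offset=offset,
            ).fit()
            assert model.params == pytest.approx(fit.coef.loc[g].to_numpy(), abs=1e-5)
            assert model.bse == pytest.approx(
                np.sqrt(np.diagonal(fit.cov[gi])), abs=1e-5
            )

    def test_poisson_limit_matches_poisson_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        cells = [("WT", 6, "SE"), ("WT", 12, "SE")]
        design = sd.make_design(6, cells=cells, n_batches=2, seed=3)
        truth = sd.make_truth(
            40, {2: 0.5}, 1.0, seed=4, cells=cells,
            dispersion_coef=(0.0, 1e-8), dispersion_lognoise_sd=0.0,
        )
        counts = sd.simulate_counts(truth, design, library_sizes=np.ones(12), seed=5)
        alpha = pd.Series(1e-8, index=counts.index)
        fit = ec.fit_nb_glm(counts, design, factors=pd.Series(1.0, index=counts.columns),
                            alpha=alpha)
        res = ec.contrast(fit, ("WT", 6, "SE"), ("WT", 12, "SE"))
        X = np.column_stack(
            [
                (design["age_months"] == 12).astype(float),
                (design["age_months"] == 6).astype(float),
            ]
        )
        for g in counts.index[:10]:
            m = sm.GLM(counts.loc[g].to_numpy(), X, family=sm.families.Poisson()).fit()
            lfc = (m.params[0] - m.params[1]) / np.log(2)  # 12-months vs 6-months
            assert res.loc[g, "log2fc"] == pytest.approx(lfc, abs=1e-4)

    def test_agrees_with_pydeseq2(self, two_cell_fit):
        """Independent cross-check of the whole engine against DESeq2's
        Python port on the same counts (fold-change scale)."""
        pytest.importorskip("pydeseq2")
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        truth, design, counts, fit = two_cell_fit
        meta = pd.DataFrame(
            {"condition": np.where(design["age_months"] == 6, "A", "B")},
            index=design["sample_id"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
            ds.summary()
        ref = ds.results_df["log2FoldChange"]
        ours = ec.contrast(fit, ("WT", 6, "SE"), ("WT", 12, "SE"))["log2fc"]
        assert np.corrcoef(ref, ours.loc[ref.index])[0, 1] > 0.99
        assert np.abs(ref - ours.loc[ref.index]).mean() < 0.05

    def test_small_cell_rejected(self, small_counts):
        design = sd.make_design(2, cells=[("WT", 6, "SE"), ("WT", 12, "SE")],
                                n_batches=1, seed=0)
        design = design.iloc[:3]  # second cell left with a single sample
        with pytest.raises(ValueError, match="fewer than 2"):
            ec.fit_contrast(
                small_counts[design["sample_id"]], design,
                ("WT", 6, "SE"), ("WT", 12, "SE"),
            )


class TestBiasFilter:
    def test_constant_gene_never_excluded(self, small_design):
        expr = pd.DataFrame(
            5.0, index=["flat"], columns=small_design["sample_id"]
        )
        excluded, flags = ec.technical_bias_filter(expr, small_design, ["flat"])
        assert excluded == set() and not flags.to_numpy().any()

    def test_leave_one_out_oracle(self, rng):
        block = rng.normal(size=(10, 9))
        loo_mean, loo_sd = ec.leave_one_out_stats(block)
        for i in range(10):
            for j in range(9):
                others = np.delete(block[i], j)
                assert loo_mean[i, j] == pytest.approx(others.mean())
                assert loo_sd[i, j] == pytest.approx(others.std(ddof=1))

    def test_planted_batch_shift_recovery(self):
        from midtraject.benchmarks import bias_filter_benchmark

        out = bias_filter_benchmark(3, n_genes=1200)
        assert out["detected_frac"] >= 0.9
        assert out["false_excluded_frac"] <= 0.02

    def test_small_cells_skipped_with_warning(self):
        design = sd.make_design(2, cells=[("WT", 6, "SE")], n_batches=1, seed=0)
        expr = pd.DataFrame(
            [[1.0, 9.0]], index=["g"], columns=design["sample_id"]
        )
        with pytest.warns(UserWarning, match="skipped"):
            excluded, _ = ec.technical_bias_filter(expr, design, ["g"])
        assert excluded == set()


class TestIsoformShares:
    def test_single_transcript_gene(self):
        abund = pd.DataFrame({"s1": [4.0], "s2": [0.0]}, index=["t1"])
        shares = ec.isoform_shares(
            abund, {"t1": "g1"}, pd.Series([1.0, 1.0], index=["s1", "s2"])
        )
        assert shares.loc["t1", "s1"] == 1.0
        assert np.isnan(shares.loc["t1", "s2"])

    def test_shares_sum_to_one_and_hand_ratios(self):
        abund = pd.DataFrame(
            {"s1": [2.0, 6.0, 5.0], "s2": [1.0, 1.0, 3.0]},
            index=["t1", "t2", "t3"],
        )
        t2g = {"t1": "gA", "t2": "gA", "t3": "gB"}
        factors = pd.Series([1.0, 0.5], index=["s1", "s2"])
        shares = ec.isoform_shares(abund, t2g, factors)
        assert shares.loc["t1", "s1"] == pytest.approx(0.25)
        assert shares.loc["t2", "s1"] == pytest.approx(0.75)
        assert shares.loc["t3", "s2"] == pytest.approx(1.0)
        sums = shares.drop(columns="gene_id").groupby(shares["gene_id"]).sum()
        assert np.allclose(sums.to_numpy(), 1.0)

    def test_orphan_transcript_rejected(self):
        abund = pd.DataFrame({"s1": [1.0]}, index=["t_orphan"])
        with pytest.raises(ValueError, match="without a gene"):
            ec.isoform_shares(abund, {}, pd.Series([1.0], index=["s1"]))
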