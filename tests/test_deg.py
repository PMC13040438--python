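"""Differential expression: size factors, NB Wald test, BH, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acetoledger.deg import (
    CountMatrix,
    bh_adjust,
    classify_and_summarize,
    nb_wald_test,
    run_deg,
    size_factors,
)
from acetoledger.synth import SynthConfig, generate_counts

CONDS = ["reference"] * 3 + ["treatment"] * 3


def toy_matrix(counts):
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(gene_ids=genes, counts=counts, condition=CONDS[: counts.shape[1]])


class TestCountMatrix:
    def test_rejects_negative_and_noninteger_counts(self):
        with pytest.raises(ValueError):
            toy_matrix([[1, -2, 3, 4, 5, 6]])
        with pytest.raises(ValueError):
            toy_matrix(np.full((1, 6), 1.5))

    def test_requires_two_replicates_per_condition(self):
        with pytest.raises(ValueError):
            CountMatrix(["g0"], np.ones((1, 3), int), ["reference", "reference", "treatment"])

    def test_requires_both_labels(self):
        with pytest.raises(ValueError):
            CountMatrix(["g0"], np.ones((1, 4), int), ["reference"] * 4)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = toy_matrix(np.tile([[10], [20], [30], [40], [50]], (1, 6)))
        assert size_factors(m) == pytest.approx(np.ones(6))

    def test_doubled_column_keeps_the_two_to_one_ratio(self):
        base = np.array([11, 25, 47, 90, 160])
        counts = np.tile(base[:, None], (1, 6))
        counts[:, 2] *= 2
        factors = size_factors(toy_matrix(counts))
        assert factors[2] / factors[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)

    def test_single_gene_factors_proportional_to_counts(self):
        counts = np.array([[10, 20, 40, 10, 20, 40]])
        factors = size_factors(toy_matrix(counts))
        assert factors / factors[0] == pytest.approx(counts[0] / counts[0, 0])

    def test_all_zero_sample_rejected(self):
        counts = np.tile([[5], [7], [9]], (1, 6))
        counts[:, 4] = 0
        with pytest.raises(ValueError, match="all-zero"):
            size_factors(toy_matrix(counts))


class TestNbWaldTest:
    def test_identical_groups_give_zero_fc_and_p_near_one(self):
        counts = np.tile([[100], [200], [300]], (1, 6))
        table = nb_wald_test(toy_matrix(counts), np.ones(6))
        assert table["log2FC"].to_numpy() == pytest.approx(np.zeros(3))
        assert (table["pvalue"] > 0.99).all()

    def test_fourfold_means_give_log2fc_two(self):
        counts = np.array([[100, 100, 100, 400, 400, 400]])
        table = nb_wald_test(toy_matrix(counts), np.ones(6))
        expected = np.log2(400.5 / 100.5)
        assert table["log2FC"].iloc[0] == pytest.approx(expected)
        assert table["log2FC"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_all_zero_gene_flagged_not_nan(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [10, 12, 9, 50, 60, 55]])
        table = nb_wald_test(toy_matrix(counts), np.ones(6))
        row = table.iloc[0]
        assert row["all_zero"] and row["pvalue"] == 1.0 and row["log2FC"] == 0.0
        assert not table["pvalue"].isna().any()

    def test_null_simulation_calibrates_to_nominal_level(self):
        """Seeded null NB counts: the raw p < 0.05 fraction sits in the binomial 99% CI."""
        m, _ = generate_counts(SynthConfig(seed=11, n_genes=2000, deg_fraction=0.0))
        table = nb_wald_test(m, size_factors(m))
        frac = (table["pvalue"] < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < half_width

    def test_rank_agreement_with_exhaustive_permutation_oracle(self):
        """Wald p and exhaustive label-permutation p agree in rank order (Spearman >= 0.9)."""
        cfg = SynthConfig(seed=3, n_genes=50, deg_fraction=0.4, lfc_low=0.5, lfc_high=3.0)
        m, _ = generate_counts(cfg)
        factors = size_factors(m)
        table = nb_wald_test(m, factors)
        norm = m.counts / factors
        ref_mask = np.array([c == "reference" for c in m.condition])

        def abs_lfc(trt_idx):
            trt = norm[:, trt_idx].mean(axis=1)
            ref = norm[:, [i for i in range(6) if i not in trt_idx]].mean(axis=1)
            return np.abs(np.log2(trt + 0.5) - np.log2(ref + 0.5))

        observed = abs_lfc([i for i in range(6) if not ref_mask[i]])
        perm_stats = np.array([abs_lfc(list(c)) for c in itertools.combinations(range(6), 3)])
        p_perm = (perm_stats >= observed[None, :]).mean(axis=0)
        rho = stats.spearmanr(table["pvalue"], p_perm).statistic
        assert rho >= 0.9


class TestBhAdjust:
    def test_equal_p_values_unchanged(self):
        p = np.full(5, 0.2)
        assert bh_adjust(p) == pytest.approx(p)

    def test_hand_worked_uniform_ladder(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_hand_worked_pair(self):
        assert bh_adjust([0.005, 0.5]) == pytest.approx([0.01, 0.5])

    def test_out_of_range_rejected(self):
        for bad in ([-0.1, 0.5], [0.5, 1.5], [np.nan, 0.2]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    def test_monotone_in_rank_never_below_raw_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p).all() and ((0 <= adj) & (adj <= 1)).all()

    def test_reapplication_is_order_preserving_and_inflationary(self):
        """Re-adjusting adjusted values never shrinks them or changes their order;
        a fully tied vector (the post-step-up fixed point) is reproduced exactly."""
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        readj = bh_adjust(adj)
        assert (readj >= adj - 1e-12).all()
        order = np.argsort(adj, kind="stable")
        assert (np.diff(readj[order]) >= -1e-12).all()
        tied = np.full(6, 0.03)
        assert bh_adjust(tied) == pytest.approx(tied)


class TestClassifyAndSummarize:
    @staticmethod
    def frame(log2fc, pvalue):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(log2fc))],
                "log2FC": log2fc,
                "pvalue": pvalue,
                "all_zero": [False] * len(log2fc),
            }
        )

    def test_printed_percentages_from_the_gene_universe(self):
        # 489 DEG-like rows of 2594 genes -> 18.85%; 517 -> 19.93%
        for n_deg, expected in ((489, 18.85), (517, 19.93)):
            table = self.frame([3.0] * n_deg, [1e-8] * n_deg)
            result = classify_and_summarize(table, n_total_genes=2594)
            assert result.n_deg == n_deg
            assert result.fraction_deg_percent == expected

    def test_below_fc_threshold_is_not_deg_despite_tiny_p(self):
        result = classify_and_summarize(self.frame([1.9], [0.001]))
        assert not result.table["is_deg"].iloc[0]

    def test_deg_rule_is_conjunction_of_both_thresholds(self):
        table = self.frame([2.5, 2.5, 1.0], [1e-6, 0.9, 1e-6])
        result = classify_and_summarize(table)
        assert result.table["is_deg"].tolist() == [True, False, False]

    def test_category_counts_allow_multiple_membership(self):
        table = self.frame([4.0, -3.0, 0.1], [1e-9, 1e-9, 0.5])
        annotation = {"g0": ["carbon", "energy"], "g1": ["carbon"], "g2": ["energy"]}
        result = classify_and_summarize(table, annotation=annotation)
        assert result.category_counts == {"carbon": 2, "energy": 1}


class TestPipeline:
    def test_null_fdr_controlled_at_padj_threshold(self):
        fractions = []
        for seed in (21, 22, 23):
            m, _ = generate_counts(SynthConfig(seed=seed, n_genes=1500, deg_fraction=0.0))
            result = run_deg(m)
            fractions.append((result.table["padj"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05

    def test_planted_high_expression_effects_recovered(self):
        cfg = SynthConfig(seed=7, n_genes=2000, deg_fraction=0.1, lfc_low=3.0, lfc_high=3.0)
        m, truth = generate_counts(cfg)
        result = run_deg(m)
        merged = result.table.merge(truth, on="gene_id")
        planted_high = merged["planted"] & (merged["baseline_mean"] > 100)
        assert planted_high.sum() > 50
        assert merged.loc[planted_high, "is_deg"].mean() >= 0.9
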