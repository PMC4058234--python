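import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, poisson, spearmanr

from multirank import (
    CountMatrix,
    SimulationConfig,
    estimate_dispersions,
    nb_exact_test,
    run_bayseq_like,
    run_engine,
    simulate_counts,
    size_factors_median_ratio,
    size_factors_tmm,
)
from conftest import mann_whitney_auc


def _matrix(rows, **kw):
    rows = np.asarray(rows)
    return CountMatrix(
        pd.DataFrame(
            rows,
            index=[f"g{i}" for i in range(rows.shape[0])],
            columns=[f"s{i}" for i in range(rows.shape[1])],
        )
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _matrix(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(size_factors_median_ratio(counts).values(), 1.0)
        assert np.allclose(size_factors_tmm(counts).values(), 1.0)

    def test_doubled_column_doubles_median_ratio_factor(self):
        rng = np.random.default_rng(1)
        col = rng.integers(5, 500, size=50)
        counts = _matrix(np.column_stack([col, 2 * col, col]))
        f = size_factors_median_ratio(counts).values()
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_median_ratio_hand_computed_with_zero_gene(self):
        counts = _matrix([[2, 4, 8], [3, 6, 12], [5, 10, 20], [0, 7, 1]])
        f = size_factors_median_ratio(counts).values()
        # 3 eligible genes all share column ratios 1:2:4 about geomean 2
        expected = np.array([0.5, 1.0, 2.0])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f, expected)

    def test_no_eligible_gene_errors_unless_fallback(self):
        counts = _matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="fallback"):
            size_factors_median_ratio(counts)
        f = size_factors_median_ratio(counts, fallback_total_count=True)
        assert np.allclose(f.values(), 1.0)  # equal totals

    def test_tmm_trims_a_tripled_gene_subset(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 500, size=200).astype(float)
        b = base.copy()
        b[:20] *= 3.0  # 10% of genes tripled in sample B
        counts = _matrix(np.column_stack([base, b]).astype(int))
        f = size_factors_tmm(counts).values()
        # the tripled genes are trimmed away, and the remaining genes are
        # identical between samples, so no net scaling should remain
        assert f[1] / f[0] == pytest.approx(1.0, rel=0.05)

    def test_factors_must_be_positive(self):
        from multirank.de_methods import SizeFactors

        with pytest.raises(ValueError):
            SizeFactors(pd.Series([1.0, -1.0]), method="x")


class TestDispersions:
    def test_poisson_truth_recovered_as_small(self, groups33):
        counts, _ = simulate_counts(
            SimulationConfig(n_genes=2000, dispersion=0.0, seed=10)
        )
        f = size_factors_median_ratio(counts)
        for mode in ("deseq_like", "edger_like"):
            d = estimate_dispersions(counts, groups33, f, mode)
            assert np.median(d.final) < 0.05

    def test_constant_truth_recovered_within_band(self, groups33):
        counts, _ = simulate_counts(
            SimulationConfig(n_genes=2000, dispersion=0.2, seed=11)
        )
        f = size_factors_median_ratio(counts)
        for mode in ("deseq_like", "edger_like"):
            d = estimate_dispersions(counts, groups33, f, mode)
            assert 0.1 <= np.median(d.final) <= 0.4

    def test_deseq_rule_is_gene_wise_maximum(self, groups33, de_study):
        counts, _ = de_study
        f = size_factors_median_ratio(counts)
        d = estimate_dispersions(counts, groups33, f, "deseq_like")
        assert (d.final >= d.raw - 1e-12).all()
        assert (d.final >= d.trend - 1e-12).all()

    def test_edger_moderation_lies_between_raw_and_trend(self, groups33, de_study):
        counts, _ = de_study
        f = size_factors_tmm(counts)
        d = estimate_dispersions(counts, groups33, f, "edger_like")
        lo = np.minimum(d.raw, d.trend)
        hi = np.maximum(d.raw, d.trend)
        assert ((d.final >= lo - 1e-12) & (d.final <= hi + 1e-12)).all()

    def test_sparse_positive_dispersion_falls_back_to_median(self, groups33):
        counts = _matrix(np.tile([[5], [9], [14], [3], [8], [2], [4], [6],
                                  [7], [11], [13], [5]], (1, 6)))
        f = size_factors_median_ratio(counts)
        with pytest.warns(UserWarning, match="median raw dispersion"):
            estimate_dispersions(counts, groups33, f, "deseq_like")


def _enumeration_oracle(sum_a, sum_b, n_a, n_b, alpha):
    """Brute-force conditional p-value via scipy pmfs."""
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)

    def pmf(x, n):
        if alpha == 0:
            return poisson.pmf(x, n * mu)
        r = n / alpha
        return nbinom.pmf(x, r, r / (r + n * mu))

    probs = np.array([pmf(x, n_a) * pmf(total - x, n_b) for x in range(total + 1)])
    obs = probs[sum_a]
    return min(1.0, probs[probs <= obs * (1 + 1e-8)].sum() / probs.sum())


class TestExactTest:
    def test_zero_total_has_no_evidence(self):
        assert nb_exact_test(0, 0, 3, 3, 0.1) == 1.0

    def test_balanced_split_is_p_one(self):
        assert nb_exact_test(30, 30, 3, 3, 0.2) == pytest.approx(1.0)

    def test_poisson_limit_matches_binomial_tail(self):
        # 10 vs 0 with equal groups: two-sided binomial(10, 1/2) tail
        assert nb_exact_test(10, 0, 3, 3, 0.0) == pytest.approx(2 / 1024)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.5])
    def test_agrees_with_enumeration_on_sample_grid(self, alpha):
        for total in (1, 5, 12, 25):
            for sum_a in range(total + 1):
                got = nb_exact_test(sum_a, total - sum_a, 3, 3, alpha)
                want = _enumeration_oracle(sum_a, total - sum_a, 3, 3, alpha)
                assert got == pytest.approx(want, abs=1e-10)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1, 2, 3, 3, -0.5)


class TestEngines:
    @pytest.mark.parametrize("mode", ["deseq_like", "edger_like"])
    def test_duplicated_groups_are_entirely_null(self, groups33, mode):
        rng = np.random.default_rng(5)
        half = rng.integers(0, 300, size=(100, 3))
        counts = _matrix(np.hstack([half, half]))
        res = run_engine(counts, groups33, mode)
        assert np.allclose(res.table["raw_score"], 1.0)
        assert np.allclose(res.table["log2_fold_change"], 0.0)

    @pytest.mark.parametrize("mode", ["deseq_like", "edger_like"])
    def test_label_swap_keeps_p_and_negates_fold_change(self, groups33, de_study, mode):
        counts, _ = de_study
        res = run_engine(counts, groups33, mode)
        res_swapped = run_engine(counts, groups33.swapped(), mode)
        assert np.allclose(
            res.table["raw_score"], res_swapped.table["raw_score"]
        )
        assert np.allclose(
            res.table["log2_fold_change"],
            -res_swapped.table["log2_fold_change"],
            atol=1e-9,
        )

    def test_scaling_one_sample_barely_moves_deseq_p_ranking(self, groups33, de_study):
        counts, _ = de_study
        scaled = counts.data.copy()
        scaled.iloc[:, 0] *= 3
        res1 = run_engine(counts, groups33, "deseq_like")
        res2 = run_engine(CountMatrix(scaled), groups33, "deseq_like")
        rho = spearmanr(res1.table["raw_score"], res2.table["raw_score"]).statistic
        assert rho > 0.99

    def test_fdr_dominates_raw_scores(self, groups33, de_study):
        counts, _ = de_study
        for mode in ("deseq_like", "edger_like"):
            res = run_engine(counts, groups33, mode)
            assert (res.table["fdr_score"] >= res.table["raw_score"] - 1e-12).all()
            assert (res.table["fdr_score"] <= 1.0).all()

    def test_power_increases_with_effect_size(self, groups33):
        powers = []
        for lfc in (0.5, 1.0, 2.0):
            hits = []
            for seed in (21, 22, 23):
                counts, truth = simulate_counts(
                    SimulationConfig(
                        n_genes=800, de_fraction=0.1, log2fc=lfc,
                        dispersion=0.1, seed=seed,
                    )
                )
                res = run_engine(counts, groups33, "edger_like")
                de = truth.genes["is_de"]
                hits.append((res.table.loc[de, "raw_score"] < 0.05).mean())
            powers.append(np.mean(hits))
        assert powers[0] <= powers[1] <= powers[2]


class TestBayseqLike:
    def test_flat_gene_scores_below_median_posterior(self, groups33, de_study):
        counts, _ = de_study
        flat = counts.data.copy()
        flat.iloc[0] = 150  # identical counts in all samples
        res = run_bayseq_like(CountMatrix(flat), groups33, n_prior_samples=200, seed=3)
        posterior = 1 - res.table["raw_score"]
        assert posterior.iloc[0] < posterior.median()

    def test_all_null_data_converges_to_small_de_weight(self, groups33):
        counts, _ = simulate_counts(
            SimulationConfig(n_genes=1000, de_fraction=0.0, dispersion=0.1, seed=5)
        )
        res = run_bayseq_like(counts, groups33, n_prior_samples=250, seed=5)
        assert res.info["prior_weight_de"] < 0.1

    def test_separates_de_from_null_genes(self, groups33, de_study):
        counts, truth = de_study
        res = run_bayseq_like(counts, groups33, n_prior_samples=250, seed=9)
        posterior = 1 - res.table["raw_score"].to_numpy()
        is_de = truth.genes["is_de"].to_numpy()
        assert posterior[is_de].mean() > posterior[~is_de].mean()
        assert mann_whitney_auc(is_de, posterior) > 0.9

    def test_deterministic_given_seed(self, groups33, de_study):
        counts, _ = de_study
        a = run_bayseq_like(counts, groups33, n_prior_samples=100, seed=7)
        b = run_bayseq_like(counts, groups33, n_prior_samples=100, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_reports_no_fold_change(self, groups33, de_study):
        counts, _ = de_study
        res = run_bayseq_like(counts, groups33, n_prior_samples=100, seed=1)
        assert not res.has_fold_change
        assert res.table["log2_fold_change"].isna().all()

    def test_prior_size_floor_enforced(self, groups33, de_study):
        counts, _ = de_study
        with pytest.raises(ValueError, match=">= 50"):
            run_bayseq_like(counts, groups33, n_prior_samples=10)

    def test_degenerate_prior_rejected(self, groups33):
        counts = _matrix(np.tile([7, 7, 7, 7, 7, 7], (60, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            run_bayseq_like(counts, groups33, n_prior_samples=50, seed=0)
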