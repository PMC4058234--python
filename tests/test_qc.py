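import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multirank import (
    BatchAnnotation,
    CountMatrix,
    GroupAssignment,
    batch_effect_tests,
    coefficient_of_variation,
    distribution_summary,
    noise_dominated_scenario,
    filter_top_cv,
    hierarchical_cluster,
    normalize_per_sample,
    spearman_distance_matrix,
)
from multirank.qc import NormalizedMatrix


def _matrix(rows, genes=None, samples=None):
    rows = np.asarray(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return CountMatrix(pd.DataFrame(rows, index=genes, columns=samples))


class TestNormalization:
    def test_formula_on_published_counts(self):
        counts = _matrix([[391, 2038, 338, 634, 10282, 1764],
                          [49870084 - 391, 65550902 - 2038, 71454121 - 338,
                           35641084 - 634, 44863975 - 10282, 49052840 - 1764]])
        norm = normalize_per_sample(counts, 1e7)
        assert norm.rounded().iloc[0].tolist() == [78, 311, 47, 178, 2292, 360]

    def test_zero_count_stays_zero(self):
        norm = normalize_per_sample(_matrix([[0, 0], [10, 20]]), 1e6)
        assert (norm.data.iloc[0] == 0).all()

    def test_column_sums_equal_scale_constant(self, toy_counts):
        norm = normalize_per_sample(toy_counts, 1e7)
        assert np.allclose(norm.data.sum(axis=0), 1e7, rtol=1e-6)

    def test_zero_total_sample_named_in_error(self):
        counts = _matrix([[0, 5], [0, 5]], samples=["empty", "ok"])
        with pytest.raises(ValueError, match="empty"):
            normalize_per_sample(counts)


class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([5, 5, 5, 5], 0.0),
            ([0, 0, 0, 0], 0.0),  # mean-zero convention
            ([2, 4, 6], 0.5),  # sd(n-1)=2, mean=4
        ],
    )
    def test_known_values(self, row, expected):
        counts = _matrix([row, [1] * len(row)])
        assert coefficient_of_variation(counts)["g0"] == pytest.approx(expected)

    def test_fraction_one_is_identity(self, toy_counts):
        assert filter_top_cv(toy_counts, 1.0) is toy_counts

    def test_top_fraction_keeps_highest_cv(self):
        rng = np.random.default_rng(0)
        counts = _matrix(rng.integers(1, 1000, size=(100, 4)))
        kept = filter_top_cv(counts, 0.05)
        assert kept.n_genes == 5
        cv = coefficient_of_variation(counts)
        assert cv[kept.gene_ids].min() >= cv.drop(kept.gene_ids).max()

    def test_ties_break_lexicographically(self):
        counts = _matrix(np.tile([1, 2, 3], (10, 1)),
                         genes=[f"g{i}" for i in range(9, -1, -1)])
        kept = filter_top_cv(counts, 0.5)
        assert sorted(kept.gene_ids) == ["g0", "g1", "g2", "g3", "g4"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_nested_fractions_are_nested_gene_sets(self, seed):
        rng = np.random.default_rng(seed)
        counts = _matrix(rng.integers(0, 500, size=(40, 5)))
        small = set(filter_top_cv(counts, 0.10).gene_ids)
        large = set(filter_top_cv(counts, 0.30).gene_ids)
        assert small <= large


class TestSpearmanDistance:
    def test_self_distance_zero_and_symmetry(self, toy_counts):
        d = spearman_distance_matrix(toy_counts)
        assert np.allclose(np.diag(d), 0)
        assert np.allclose(d, d.T)

    def test_reversed_ordering_gives_two(self):
        counts = _matrix([[1, 4], [2, 3], [3, 2], [4, 1]])
        assert spearman_distance_matrix(counts)[0, 1] == pytest.approx(2.0)

    def test_hand_computed_toy(self):
        # ranks (1,2,3,4) vs (2,1,4,3): sum d^2 = 4,
        # rho = 1 - 6*4/(4*(16-1)) = 0.6, distance 0.4
        counts = _matrix([[1, 2], [2, 1], [3, 4], [4, 3]])
        assert spearman_distance_matrix(counts)[0, 1] == pytest.approx(0.4)

    def test_invariant_to_monotone_transform(self, toy_counts):
        d1 = spearman_distance_matrix(toy_counts)
        cubed = CountMatrix(toy_counts.data ** 3)
        d2 = spearman_distance_matrix(cubed)
        assert np.allclose(d1, d2)

    def test_constant_sample_named_in_error(self):
        counts = _matrix([[7, 1], [7, 5], [7, 2]], samples=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            spearman_distance_matrix(counts)


class TestHierarchicalCluster:
    def _block_distance(self, n=6):
        d = np.full((n, n), 1.0)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        return d

    def test_separable_blocks_have_no_misclassification(self, groups33):
        res = hierarchical_cluster(
            self._block_distance(), groups33, [f"s{i}" for i in range(6)]
        )
        assert res.misclassified == frozenset()
        assert np.all(np.diff(res.merge_tree[:, 2]) >= 0)

    def test_permuting_samples_permutes_labels(self, groups33):
        d = self._block_distance()
        perm = np.array([5, 4, 3, 2, 1, 0])
        res1 = hierarchical_cluster(d, groups33, [f"s{i}" for i in range(6)])
        res2 = hierarchical_cluster(
            d[np.ix_(perm, perm)],
            GroupAssignment(groups33.labels[perm]),
            [f"s{i}" for i in perm],
        )
        relabeled = res1.cut_labels[perm]
        if relabeled[0] != res2.cut_labels[0]:
            relabeled = 1 - relabeled
        assert np.array_equal(relabeled, res2.cut_labels)

    def test_fewer_than_three_samples_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            res = hierarchical_cluster(
                np.zeros((2, 2)),
                GroupAssignment(np.array([0, 0, 1, 1])),
                ["a", "b"],
            )
        assert res is None

    def test_noise_dominated_study_recovers_under_cv_filter(self):
        """One misleading control clusters with the disease block on all
        genes but not after the top-5% CV filter."""
        counts, groups, outlier = noise_dominated_scenario(seed=7)
        unfiltered = hierarchical_cluster(
            spearman_distance_matrix(counts), groups, counts.sample_ids, 1.0
        )
        assert outlier in unfiltered.misclassified
        filtered_counts = filter_top_cv(counts, 0.05)
        filtered = hierarchical_cluster(
            spearman_distance_matrix(filtered_counts),
            groups,
            counts.sample_ids,
            0.05,
        )
        assert filtered.misclassified == frozenset()


class TestBatchTests:
    def _normalized(self, values, samples):
        frame = pd.DataFrame(
            values, index=[f"g{i}" for i in range(len(values))], columns=samples
        )
        return NormalizedMatrix(data=frame, scale_constant=1.0)

    def test_single_level_factor_skipped(self):
        samples = [f"s{i}" for i in range(4)]
        norm = self._normalized(np.random.default_rng(0).uniform(size=(30, 4)), samples)
        ann = BatchAnnotation(lane_id={s: "L1" for s in samples})
        with pytest.warns(UserWarning, match="skipped"):
            res = batch_effect_tests(norm, ann)
        assert res.table.empty

    def test_identical_summaries_give_p_one(self):
        samples = [f"s{i}" for i in range(4)]
        norm = self._normalized(np.tile([[1.0], [2.0], [3.0]], (1, 4)), samples)
        ann = BatchAnnotation(lane_id={"s0": "L1", "s1": "L1", "s2": "L2", "s3": "L2"})
        res = batch_effect_tests(norm, ann)
        row = res.table.set_index("factor").loc["lane_id"]
        assert row["kruskal_wallis_p"] == 1.0
        assert row["fligner_killeen_p"] == 1.0

    def test_lane_shift_detected(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(12)]
        values = rng.lognormal(3, 0.2, size=(200, 12))
        values[:60, 6:] *= 4.0  # gene-subset lane effect
        norm = self._normalized(values, samples)
        ann = BatchAnnotation(
            lane_id={s: ("L1" if i < 6 else "L2") for i, s in enumerate(samples)}
        )
        res = batch_effect_tests(norm, ann)
        row = res.table.set_index("factor").loc["lane_id"]
        assert row["kruskal_wallis_p"] < 0.05
        assert "lane_id" in res.flagged


class TestDistributionSummary:
    def test_all_zero_sample_summarizes_to_zero(self):
        counts = _matrix([[0, 5], [0, 7], [0, 2]], samples=["zero", "ok"])
        norm = NormalizedMatrix(data=counts.data.astype(float), scale_constant=1.0)
        summary = distribution_summary(counts, norm)
        assert (summary["raw"].loc["zero"] == 0).all()

    def test_duplicate_samples_correlate_perfectly(self):
        counts = _matrix([[1, 1], [5, 5], [3, 3]], samples=["a", "b"])
        summary = distribution_summary(
            counts, normalize_per_sample(counts, 100.0)
        )
        assert summary["correlation"].loc["a", "b"] == pytest.approx(1.0)

    def test_quartiles_match_linear_interpolation_rule(self):
        counts = _matrix([[1, 10, 100], [2, 20, 200], [3, 30, 300], [4, 40, 400]])
        summary = distribution_summary(counts, normalize_per_sample(counts, 1.0))
        logged = np.log2(np.array([1.0, 2.0, 3.0, 4.0]) + 1.0)
        # type-7: Q1 at position 0.25*(n-1) interpolated
        expected_q1 = logged[0] + 0.75 * (logged[1] - logged[0])
        assert summary["raw"].loc["s0", "q1"] == pytest.approx(expected_q1)
        assert summary["raw"].loc["s0", "median"] == pytest.approx(
            (logged[1] + logged[2]) / 2
        )
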