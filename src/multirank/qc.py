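"""Multi-perspective sample quality control.

Three perspectives on a count matrix before any differential testing:

* per-sample total-count normalization and distribution summaries
  (boxplot five-number summaries, pairwise Spearman correlation);
* unsupervised hierarchical clustering of samples on Spearman distance,
  repeated under coefficient-of-variation gene filters, with detection of
  samples that cluster against their declared phenotype;
* batch-effect testing of machine / run / flowcell / lane factors with the
  Kruskal-Wallis (location) and Fligner-Killeen (scale) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_counts import BatchAnnotation, CountMatrix, GroupAssignment

__all__ = [
    "NormalizedMatrix",
    "ClusterResult",
    "BatchTestResult",
    "normalize_per_sample",
    "coefficient_of_variation",
    "filter_top_cv",
    "spearman_distance_matrix",
    "hierarchical_cluster",
    "batch_effect_tests",
    "distribution_summary",
]

#: default normalization constant: counts per ten million
DEFAULT_SCALE = 1e7


@dataclass(frozen=True)
class NormalizedMatrix:
    """Total-count normalized expression: count / sample total * constant."""

    data: pd.DataFrame
    scale_constant: float

    def rounded(self) -> pd.DataFrame:
        """Integer-rounded view for display (round-half-up)."""
        return np.floor(self.data + 0.5).astype(np.int64)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of one sample-clustering pass at a given CV filter."""

    sample_ids: list[str]
    distance_matrix: np.ndarray
    merge_tree: np.ndarray  # scipy linkage matrix (merges with heights)
    cut_labels: np.ndarray  # cluster id per sample at k=2
    misclassified: frozenset[str]
    cv_fraction: float


@dataclass
class BatchTestResult:
    """Per-factor Kruskal-Wallis / Fligner-Killeen p-values.

    Only factors with >= 2 levels, each level holding >= 2 samples, are
    testable and appear in ``table``.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["factor", "n_levels", "kruskal_wallis_p", "fligner_killeen_p"]
        )
    )
    alpha: float = 0.05

    @property
    def flagged(self) -> list[str]:
        if self.table.empty:
            return []
        hit = (self.table["kruskal_wallis_p"] < self.alpha) | (
            self.table["fligner_killeen_p"] < self.alpha
        )
        return self.table.loc[hit, "factor"].tolist()


def normalize_per_sample(
    counts: CountMatrix, scale_constant: float = DEFAULT_SCALE
) -> NormalizedMatrix:
    """Divide each gene's count by the sample's total and scale.

    value(g, s) = count(g, s) / total(s) * scale_constant, so every column
    sums to the scale constant.
    """
    if scale_constant <= 0:
        raise ValueError("scale_constant must be positive")
    totals = counts.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with zero total count cannot be normalized: "
            f"{zero.index.tolist()}"
        )
    data = counts.data / totals * float(scale_constant)
    return NormalizedMatrix(data=data, scale_constant=float(scale_constant))


def coefficient_of_variation(counts: CountMatrix) -> pd.Series:
    """Per-gene CV = sample standard deviation (n-1) / mean across samples.

    Genes with mean 0 (all-zero rows) get CV 0 by convention.
    """
    values = counts.values().astype(float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    return pd.Series(cv, index=counts.data.index, name="cv")


def filter_top_cv(counts: CountMatrix, fraction: float) -> CountMatrix:
    """Keep the ceil(fraction * n_genes) genes with largest CV.

    Ties at the cutoff break by lexicographic gene id, so the result is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return counts
    cv = coefficient_of_variation(counts)
    n_keep = int(np.ceil(fraction * counts.n_genes))
    order = sorted(cv.index, key=lambda g: (-cv[g], str(g)))
    keep = set(order[:n_keep])
    kept_in_input_order = [g for g in counts.data.index if g in keep]
    return CountMatrix(counts.data.loc[kept_in_input_order])


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """Full pairwise Spearman correlation over columns (average ranks)."""
    res = stats.spearmanr(values, axis=0).statistic
    if np.ndim(res) == 0:  # scipy collapses the 2-column case to a scalar
        res = np.array([[1.0, float(res)], [float(res), 1.0]])
    return np.asarray(res, dtype=float)


def spearman_distance_matrix(counts: CountMatrix) -> np.ndarray:
    """Pairwise sample dissimilarity d(i, j) = 1 - Spearman rho.

    Ties get average ranks.  A sample with constant values across all genes
    has undefined rho and raises.
    """
    values = counts.values().astype(float)
    if values.shape[0] < 3:
        raise ValueError("need >= 3 genes for a meaningful Spearman distance")
    constant = np.nonzero(values.max(axis=0) == values.min(axis=0))[0]
    if len(constant):
        names = [counts.sample_ids[i] for i in constant]
        raise ValueError(
            f"Spearman correlation undefined for constant sample(s): {names}"
        )
    rho = _spearman_matrix(values)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return dist


def hierarchical_cluster(
    distance: np.ndarray,
    groups: GroupAssignment,
    sample_ids: list[str],
    cv_fraction: float = 1.0,
) -> ClusterResult | None:
    """Average-linkage clustering of the distance matrix, cut at k=2.

    Samples landing in the minority under the best label permutation
    (the cut-label relabeling that maximizes agreement with the declared
    groups) are flagged as misclassified.  With fewer than 3 samples
    clustering is skipped with a warning and ``None`` returned.
    """
    n = distance.shape[0]
    if n < 3:
        warnings.warn(
            f"only {n} samples; clustering skipped", UserWarning, stacklevel=2
        )
        return None
    # squareform rejects tiny negative/asymmetric float fuzz; symmetrize
    sym = (distance + distance.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    condensed = squareform(np.maximum(sym, 0.0), checks=False)
    merge_tree = hierarchy.linkage(condensed, method="average")
    cut = hierarchy.fcluster(merge_tree, t=2, criterion="maxclust") - 1
    labels = np.asarray(groups.labels)
    agree = (cut == labels).sum()
    if (1 - cut == labels).sum() > agree:
        cut = 1 - cut
    mis = frozenset(
        sample_ids[i] for i in range(n) if cut[i] != labels[i]
    )
    return ClusterResult(
        sample_ids=list(sample_ids),
        distance_matrix=sym,
        merge_tree=merge_tree,
        cut_labels=cut,
        misclassified=mis,
        cv_fraction=cv_fraction,
    )


def _per_sample_summary(normalized: NormalizedMatrix) -> pd.Series:
    """The batch-test response: per-sample median of log2(normalized + 1)."""
    return np.log2(normalized.data + 1.0).median(axis=0)


def batch_effect_tests(
    normalized: NormalizedMatrix,
    batch: BatchAnnotation,
    alpha: float = 0.05,
) -> BatchTestResult:
    """Test each batch factor for location and scale differences.

    The per-sample summary statistic (median of log2(normalized + 1)
    across genes) is compared across factor levels with the Kruskal-Wallis
    test and the Fligner-Killeen test of homogeneity of variances.  Factors
    without >= 2 levels of >= 2 samples each are skipped; if nothing is
    testable an empty result is returned with a warning.
    """
    summary = _per_sample_summary(normalized)
    rows = []
    for factor in BatchAnnotation.FACTORS:
        mapping = batch.factor(factor)
        annotated = [s for s in summary.index if s in mapping]
        if not annotated:
            continue
        levels: dict[str, list[float]] = {}
        for s in annotated:
            levels.setdefault(mapping[s], []).append(float(summary[s]))
        usable = [v for v in levels.values() if len(v) >= 2]
        if len(usable) < 2:
            continue
        if all(len(set(v)) == 1 for v in usable) and len(
            {v[0] for v in usable}
        ) == 1:
            kw_p = fk_p = 1.0  # identical summaries: no evidence by convention
        else:
            kw_p = float(stats.kruskal(*usable).pvalue)
            fk_p = float(stats.fligner(*usable).pvalue)
        rows.append(
            {
                "factor": factor,
                "n_levels": len(usable),
                "kruskal_wallis_p": kw_p,
                "fligner_killeen_p": fk_p,
            }
        )
    if not rows:
        warnings.warn(
            "no batch factor has >= 2 levels with >= 2 samples each; "
            "batch testing skipped",
            UserWarning,
            stacklevel=2,
        )
        return BatchTestResult(alpha=alpha)
    return BatchTestResult(table=pd.DataFrame(rows), alpha=alpha)


def distribution_summary(
    counts: CountMatrix, normalized: NormalizedMatrix
) -> dict[str, pd.DataFrame]:
    """Boxplot five-number summaries and the sample correlation matrix.

    Summaries (min/Q1/median/Q3/max) are on the log2(value + 1) scale for
    both raw and normalized values; quartiles use linear interpolation
    (type-7).  The correlation matrix is pairwise Spearman over samples on
    raw counts.
    """
    out = {}
    for name, frame in (("raw", counts.data), ("normalized", normalized.data)):
        logged = np.log2(frame.astype(float) + 1.0)
        q = logged.quantile([0.0, 0.25, 0.5, 0.75, 1.0], interpolation="linear")
        q.index = ["min", "q1", "median", "q3", "max"]
        out[name] = q.T
    rho = _spearman_matrix(counts.values().astype(float))
    out["correlation"] = pd.DataFrame(
        rho, index=counts.sample_ids, columns=counts.sample_ids
    )
    return out
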