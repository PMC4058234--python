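"""End-to-end orchestration: QC -> engines -> rank aggregation -> report.

This is the single-command surface: one call takes a count matrix and a
binary group vector and produces the consensus rank table, the QC stage
and the HTML report bundle.  Genes with zero counts in every sample are
excluded up front (they carry no evidence), so ranks and rank sums cover
tested genes only; the exclusion is recorded in the report provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import qc
from .de_methods import ENGINE_NAMES, MethodResult, run_bayseq_like, run_engine
from .io_counts import (
    BatchAnnotation,
    CountMatrix,
    GroupAssignment,
    write_result_table,
)
from .rank_aggregation import RankTable, aggregate, concordance
from .report import ReportBundle, heatmap_data, render_html, venn_sets, volcano_data

__all__ = ["AnalysisResult", "run_analysis", "write_outputs"]


@dataclass
class AnalysisResult:
    """Everything one analysis produced."""

    counts: CountMatrix  # tested genes only (all-zero rows dropped)
    groups: GroupAssignment
    normalized: qc.NormalizedMatrix
    method_results: list[MethodResult]
    rank_table: RankTable
    bundle: ReportBundle
    n_excluded_genes: int


def run_analysis(
    counts: CountMatrix,
    groups: GroupAssignment,
    engines: Sequence[str] = ENGINE_NAMES,
    seed: int = 0,
    cv_fractions: Sequence[float] = (1.0, 0.10, 0.05),
    batch: BatchAnnotation | None = None,
    scale_constant: float = qc.DEFAULT_SCALE,
    n_prior_samples: int = 1000,
    venn_criterion: str = "fdr",
    venn_threshold: float = 0.05,
    top_n: int = 50,
    title: str = "Consensus differential expression report",
) -> AnalysisResult:
    """Run QC, every requested engine and the rank aggregation."""
    if groups.n_samples != counts.n_samples:
        raise ValueError(
            f"group vector covers {groups.n_samples} samples but the matrix "
            f"has {counts.n_samples}"
        )
    unknown = set(engines) - set(ENGINE_NAMES)
    if unknown:
        raise ValueError(f"unknown engines: {sorted(unknown)}")
    if len(engines) < 2:
        raise ValueError("rank aggregation needs >= 2 engines")

    nonzero = counts.data.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    tested = CountMatrix(counts.data[nonzero]) if n_excluded else counts

    normalized = qc.normalize_per_sample(tested, scale_constant)
    summaries = qc.distribution_summary(tested, normalized)

    cluster_results = []
    for fraction in cv_fractions:
        filtered = qc.filter_top_cv(tested, fraction)
        try:
            dist = qc.spearman_distance_matrix(filtered)
        except ValueError as exc:
            warnings.warn(
                f"clustering at CV fraction {fraction} skipped: {exc}",
                UserWarning,
                stacklevel=2,
            )
            continue
        clustered = qc.hierarchical_cluster(
            dist, groups, tested.sample_ids, cv_fraction=fraction
        )
        if clustered is not None:
            cluster_results.append(clustered)

    batch_tests = None
    if batch is not None:
        batch.validate_against(tested)
        batch_tests = qc.batch_effect_tests(normalized, batch)

    results: list[MethodResult] = []
    for engine in engines:
        if engine == "bayseq_like":
            results.append(
                run_bayseq_like(
                    tested, groups, n_prior_samples=n_prior_samples, seed=seed
                )
            )
        else:
            results.append(run_engine(tested, groups, engine))

    rank_table = aggregate(results)
    concordance_matrix, _ = concordance(
        results, criterion=venn_criterion, threshold=venn_threshold, top_n=top_n
    )
    venn_counts = venn_sets(
        results,
        criterion=venn_criterion,
        threshold=venn_threshold,
        top_n=top_n,
        rank_table=rank_table,
    )
    volcano = {
        r.method_name: volcano_data(r, rank_table)
        for r in results
        if r.has_fold_change
    }
    heatmap = heatmap_data(
        normalized,
        selection=rank_table.rank_sums,
        n=min(top_n, tested.n_genes),
        groups=groups.labels,
    )
    top_table = _top_table(rank_table, results, n=min(20, tested.n_genes))

    bundle = ReportBundle(
        title=title,
        parameters={
            "engines": ",".join(engines),
            "seed": seed,
            "scale_constant": scale_constant,
            "cv_fractions": ",".join(str(f) for f in cv_fractions),
            "venn_criterion": venn_criterion,
            "venn_threshold": venn_threshold,
            "n_genes_tested": tested.n_genes,
            "n_genes_excluded_all_zero": n_excluded,
            "n_samples": tested.n_samples,
        },
        cluster_results=cluster_results,
        boxplot_summaries=summaries,
        correlation=summaries["correlation"],
        batch_tests=batch_tests,
        method_results=results,
        rank_table=rank_table,
        venn_counts=venn_counts,
        volcano=volcano,
        heatmap=heatmap,
        concordance_matrix=concordance_matrix,
        top_table=top_table,
    )
    return AnalysisResult(
        counts=tested,
        groups=groups,
        normalized=normalized,
        method_results=results,
        rank_table=rank_table,
        bundle=bundle,
        n_excluded_genes=n_excluded,
    )


def _top_table(
    rank_table: RankTable, results: Sequence[MethodResult], n: int
) -> pd.DataFrame:
    """The head of the full report table, for display in the HTML."""
    genes = rank_table.order[:n]
    frame = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for res in results:
        m = res.method_name
        sub = res.table.reindex(genes)
        if res.has_fold_change:
            frame[f"{m}_log2fc"] = sub["log2_fold_change"]
        frame[f"{m}_raw"] = sub["raw_score"]
        frame[f"{m}_fdr"] = sub["fdr_score"]
        frame[f"{m}_rank"] = rank_table.ranks[m].reindex(genes)
    frame["rank_sum"] = rank_table.rank_sums.reindex(genes)
    return frame


def write_outputs(
    analysis: AnalysisResult,
    html_path: str | Path,
    table_path: str | Path | None = None,
) -> None:
    """Write the HTML report and the full TSV result table."""
    html_path = Path(html_path)
    if table_path is None:
        table_path = html_path.with_suffix(".tsv")
    write_result_table(analysis.rank_table, analysis.method_results, table_path)
    render_html(analysis.bundle, html_path)
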