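"""Figure data and the self-contained HTML report.

Every figure is computed twice over the same numbers: once as plain
tabular data (what the tests assert on) and once as an embedded SVG drawn
from exactly that data.  The report is a single HTML file with no external
assets; rendering the same bundle twice is byte-identical apart from the
timestamp line.
"""

from __future__ import annotations

import io
import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "multirank"

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .de_methods import MethodResult
from .qc import BatchTestResult, ClusterResult, NormalizedMatrix
from .rank_aggregation import RankTable, significant_set

__all__ = [
    "ReportBundle",
    "venn_sets",
    "volcano_data",
    "heatmap_data",
    "render_html",
]


@dataclass
class ReportBundle:
    """Everything the HTML report displays, as data."""

    title: str
    parameters: dict
    cluster_results: Sequence[ClusterResult] = ()
    boxplot_summaries: Mapping[str, pd.DataFrame] | None = None
    correlation: pd.DataFrame | None = None
    batch_tests: BatchTestResult | None = None
    method_results: Sequence[MethodResult] = ()
    rank_table: RankTable | None = None
    venn_counts: Mapping[str, int] | None = None
    volcano: Mapping[str, pd.DataFrame] = field(default_factory=dict)
    heatmap: pd.DataFrame | None = None
    concordance_matrix: pd.DataFrame | None = None
    top_table: pd.DataFrame | None = None


def venn_sets(
    results: Sequence[MethodResult],
    criterion: str = "fdr",
    threshold: float = 0.05,
    top_n: int = 100,
    rank_table: RankTable | None = None,
) -> dict[str, int]:
    """Exclusive region counts for the 2- or 3-set Venn of significant genes.

    Region keys join method names with ``&`` (e.g. ``"deseq_like&edger_like"``
    is genes in exactly those two sets).  Under the fold-change criterion an
    engine without fold changes contributes an empty set.  Region counts sum
    to the size of the union.
    """
    if not 2 <= len(results) <= 3:
        raise ValueError("Venn layer supports 2 or 3 methods")
    sets = {
        r.method_name: significant_set(
            r, criterion=criterion, threshold=threshold, top_n=top_n,
            rank_table=rank_table,
        )
        for r in results
    }
    names = list(sets)
    counts: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                set(), *(sets[n] for n in names if n not in combo)
            )
            counts["&".join(combo)] = len(inside - outside)
    return counts


def volcano_data(
    result: MethodResult,
    rank_table: RankTable,
    s_min: float = 10.0,
    s_max: float = 120.0,
) -> pd.DataFrame:
    """Scalable volcano points: (log2FC, -log10 raw score, dot size).

    Dot size decreases linearly in the gene's rank sum from ``s_max`` (best
    consensus rank) to ``s_min`` (worst); if every gene is tied all dots get
    ``s_max``.  The engine without fold changes has no volcano.
    """
    if not result.has_fold_change:
        raise ValueError(f"{result.method_name} reports no fold change")
    rs = rank_table.rank_sums.reindex(result.table.index).to_numpy(dtype=float)
    lo, hi = rs.min(), rs.max()
    if hi > lo:
        size = s_max - (s_max - s_min) * (rs - lo) / (hi - lo)
    else:
        size = np.full_like(rs, s_max)
    return pd.DataFrame(
        {
            "log2_fold_change": result.table["log2_fold_change"],
            "neg_log10_score": -np.log10(result.table["raw_score"]),
            "size": size,
            "rank_sum": rs,
        },
        index=result.table.index,
    )


def heatmap_data(
    normalized: NormalizedMatrix,
    selection: pd.Series,
    n: int,
    groups: np.ndarray | None = None,
    ascending: bool = True,
) -> pd.DataFrame:
    """Row-standardized expression of the top-``n`` genes under a selection.

    ``selection`` scores genes (rank sum, FDR, or -|log2FC|; smaller wins
    with ``ascending``).  Values are per-gene z-scores of log2(normalized+1)
    (zero-variance rows become all 0); rows are ordered by average-linkage
    hierarchical clustering on the z-scores, columns by group then sample id.
    """
    if n > normalized.data.shape[0]:
        raise ValueError("n exceeds the number of genes")
    chosen = selection.sort_values(ascending=ascending, kind="mergesort").index[:n]
    logged = np.log2(normalized.data.loc[chosen] + 1.0)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    sd = logged.std(axis=1, ddof=1)
    z = centered.div(sd.where(sd > 0, 1.0), axis=0)
    z[sd == 0] = 0.0
    if len(z) > 2:
        link = hierarchy.linkage(z.to_numpy(), method="average")
        row_order = hierarchy.leaves_list(link)
        z = z.iloc[row_order]
    cols = list(z.columns)
    if groups is not None:
        key = dict(zip(normalized.data.columns, groups))
        cols = sorted(cols, key=lambda c: (key[c], str(c)))
    else:
        cols = sorted(cols, key=str)
    return z[cols]


# ---------------------------------------------------------------------------
# SVG figure builders (data already computed above; these only draw)

def _fig_to_svg(fig) -> str:
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _dendrogram_svg(cluster: ClusterResult) -> str:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    hierarchy.dendrogram(
        cluster.merge_tree, labels=cluster.sample_ids, ax=ax,
        color_threshold=0.0, above_threshold_color="tab:blue",
    )
    pct = f"top {cluster.cv_fraction:.0%} CV" if cluster.cv_fraction < 1 else "all genes"
    ax.set_title(f"Sample clustering ({pct})", fontsize=10)
    ax.set_ylabel("1 - Spearman rho")
    fig.tight_layout()
    return _fig_to_svg(fig)


def _boxplot_svg(summaries: Mapping[str, pd.DataFrame]) -> str:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=False)
    for ax, name in zip(axes, ("raw", "normalized")):
        table = summaries[name]
        stats_list = [
            {
                "med": row["median"], "q1": row["q1"], "q3": row["q3"],
                "whislo": row["min"], "whishi": row["max"], "fliers": [],
                "label": str(s),
            }
            for s, row in table.iterrows()
        ]
        ax.bxp(stats_list, showfliers=False)
        ax.set_title(f"{name} counts, log2(x+1)", fontsize=10)
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _matrix_svg(frame: pd.DataFrame, title: str, cmap: str = "viridis",
                center: bool = False) -> str:
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    values = frame.to_numpy(dtype=float)
    kwargs = {}
    if center:
        extreme = max(abs(values.min()), abs(values.max()), 1e-9)
        kwargs = {"vmin": -extreme, "vmax": extreme}
        cmap = "RdBu_r"
    im = ax.imshow(values, aspect="auto", cmap=cmap, **kwargs)
    ax.set_xticks(range(frame.shape[1]))
    ax.set_xticklabels([str(c) for c in frame.columns], rotation=60, fontsize=7)
    if frame.shape[0] <= 40:
        ax.set_yticks(range(frame.shape[0]))
        ax.set_yticklabels([str(i) for i in frame.index], fontsize=6)
    else:
        ax.set_yticks([])
    ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _venn_svg(counts: Mapping[str, int]) -> str:
    names = [k for k in counts if "&" not in k]
    fig, ax = plt.subplots(figsize=(5, 4.2))
    centers = {2: [(-0.5, 0), (0.5, 0)], 3: [(-0.55, -0.3), (0.55, -0.3), (0, 0.65)]}
    pos = centers[len(names)]
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (x, y), name, color in zip(pos, names, colors):
        ax.add_patch(plt.Circle((x, y), 1.0, alpha=0.25, color=color))
        ax.annotate(name, (x, y + 1.05), ha="center", fontsize=9)
    # region label anchors for the exclusive counts
    anchor = {name: p for name, p in zip(names, pos)}
    for region, count in counts.items():
        members = region.split("&")
        x = float(np.mean([anchor[m][0] for m in members]))
        y = float(np.mean([anchor[m][1] for m in members]))
        if len(members) == 1:  # push singletons outward
            x, y = 1.45 * x, 1.45 * y if y else -0.15
        ax.annotate(str(count), (x, y), ha="center", fontsize=11)
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-1.9, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("Significant genes per engine", fontsize=10)
    return _fig_to_svg(fig)


def _volcano_svg(name: str, points: pd.DataFrame) -> str:
    fig, ax = plt.subplots(figsize=(4.6, 3.6))
    ax.scatter(
        points["log2_fold_change"], points["neg_log10_score"],
        s=points["size"] * 0.35, alpha=0.45, linewidths=0, color="tab:purple",
    )
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 raw score")
    ax.set_title(f"{name} (dot size = consensus rank)", fontsize=10)
    fig.tight_layout()
    return _fig_to_svg(fig)


def _scatter_svg(a: MethodResult, b: MethodResult, rho: float) -> str:
    fig, ax = plt.subplots(figsize=(3.8, 3.4))
    x = -np.log10(a.table["raw_score"])
    y = -np.log10(b.table["raw_score"].reindex(a.table.index))
    ax.scatter(x, y, s=6, alpha=0.4, linewidths=0)
    ax.set_xlabel(f"-log10 score, {a.method_name}")
    ax.set_ylabel(f"-log10 score, {b.method_name}")
    ax.set_title(f"Spearman rho = {rho:.3f}", fontsize=10)
    fig.tight_layout()
    return _fig_to_svg(fig)


_PAGE = string.Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 1100px; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { border-bottom: 1px solid #bbb; margin-top: 2em; }
table.data { border-collapse: collapse; font-size: 0.85em; }
table.data th, table.data td { border: 1px solid #ccc; padding: 2px 8px; text-align: right; }
table.data th { background: #eee; }
.notice { color: #884400; font-style: italic; }
.figrow { display: flex; flex-wrap: wrap; gap: 1em; }
pre.prov { background: #f6f6f6; padding: 0.8em; font-size: 0.8em; }
</style>
</head>
<body>
<h1>$title</h1>
<h2 id="qc-clustering">QC: sample clustering</h2>
$clustering
<h2 id="qc-distributions">QC: count distributions</h2>
$distributions
<h2 id="qc-batch">QC: batch effects</h2>
$batch
<h2 id="de-concordance">Differential expression: concordance</h2>
$concordance
<h2 id="de-venn">Venn of significant genes</h2>
$venn
<h2 id="de-volcano">Volcano plots</h2>
$volcano
<h2 id="de-heatmap">Heatmap of top genes</h2>
$heatmap
<h2 id="de-table">Top consensus genes</h2>
$table
<h2 id="provenance">Provenance</h2>
<pre class="prov">$provenance</pre>
</body>
</html>
"""
)


def _html_table(frame: pd.DataFrame, float_fmt: str = "%.4g") -> str:
    return frame.to_html(
        classes="data", float_format=lambda v: float_fmt % v, border=0
    )


def render_html(bundle: ReportBundle, path: str | Path, timestamp: str | None = None) -> None:
    """Render the bundle into one self-contained HTML file.

    Missing optional components (batch tests, clustering) render as an
    explicit notice rather than failing.  All displayed numbers come from
    the bundle's data frames, the same objects serialized to TSV.
    """
    missing = '<p class="notice">%s</p>'

    if bundle.cluster_results:
        clustering = "".join(
            f'<div>{_dendrogram_svg(c)}'
            f"<p>CV filter {c.cv_fraction:g}: misclassified = "
            f"{sorted(c.misclassified) if c.misclassified else 'none'}</p></div>"
            for c in bundle.cluster_results
        )
        clustering = f'<div class="figrow">{clustering}</div>'
    else:
        clustering = missing % "clustering unavailable (fewer than 3 samples)"

    parts = []
    if bundle.boxplot_summaries is not None:
        parts.append(_boxplot_svg(bundle.boxplot_summaries))
        parts.append("<h3>Five-number summaries (log2(x+1), normalized)</h3>")
        parts.append(_html_table(bundle.boxplot_summaries["normalized"]))
    if bundle.correlation is not None:
        parts.append(
            _matrix_svg(bundle.correlation, "Sample Spearman correlation")
        )
    distributions = "".join(parts) or missing % "distribution summaries unavailable"

    if bundle.batch_tests is not None and not bundle.batch_tests.table.empty:
        flagged = bundle.batch_tests.flagged
        note = (
            f"<p>Factors with p &lt; {bundle.batch_tests.alpha:g}: "
            f"{', '.join(flagged) if flagged else 'none'}</p>"
        )
        batch = _html_table(bundle.batch_tests.table.set_index("factor")) + note
    else:
        batch = missing % "batch info unavailable"

    if bundle.concordance_matrix is not None:
        scat = ""
        res = list(bundle.method_results)
        for a, b in combinations(res, 2):
            rho = float(
                bundle.concordance_matrix.loc[a.method_name, b.method_name]
            )
            scat += _scatter_svg(a, b, rho)
        concord = (
            _html_table(bundle.concordance_matrix)
            + f'<div class="figrow">{scat}</div>'
        )
    else:
        concord = missing % "concordance unavailable (fewer than 2 engines)"

    if bundle.venn_counts:
        venn = _venn_svg(bundle.venn_counts)
        venn += _html_table(
            pd.DataFrame(
                {"genes": pd.Series(dict(bundle.venn_counts))}
            ).rename_axis("region")
        )
        no_fc = [r.method_name for r in bundle.method_results
                 if not r.has_fold_change]
        if no_fc and bundle.parameters.get("venn_criterion") == "fold_change":
            venn += missing % (
                f"{', '.join(no_fc)} reports no fold change and contributes "
                "an empty set under the fold-change criterion"
            )
    else:
        venn = missing % "venn unavailable"

    if bundle.volcano:
        volcano = '<div class="figrow">' + "".join(
            _volcano_svg(name, pts) for name, pts in bundle.volcano.items()
        ) + "</div>"
    else:
        volcano = missing % "volcano unavailable (no engine reports fold changes)"

    heat = (
        _matrix_svg(bundle.heatmap, "Row z-score of log2(normalized+1)",
                    center=True)
        if bundle.heatmap is not None
        else missing % "heatmap unavailable"
    )

    table = (
        _html_table(bundle.top_table)
        if bundle.top_table is not None
        else missing % "rank table unavailable"
    )

    stamp = timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds")
    prov_lines = [f"generated: {stamp}"] + [
        f"{k}: {v}" for k, v in sorted(bundle.parameters.items())
    ]
    html = _PAGE.substitute(
        title=bundle.title,
        clustering=clustering,
        distributions=distributions,
        batch=batch,
        concordance=concord,
        venn=venn,
        volcano=volcano,
        heatmap=heat,
        table=table,
        provenance="\n".join(prov_lines),
    )
    Path(path).write_text(html)
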