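"""Combine per-engine significance into a consensus rank-sum statistic.

Each engine's genes are ranked by raw significance score (raw p-value or
1 - posterior) rather than the FDR-adjusted score, because adjusted values
carry long runs of ties.  The per-gene sum of ranks across engines is the
headline statistic: small rank sums mean the engines consistently place
the gene among their most significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover
    from .de_methods import MethodResult

__all__ = [
    "RankTable",
    "rank_by_raw_score",
    "rank_sum",
    "bh_adjust",
    "concordance",
]


@dataclass(frozen=True)
class RankTable:
    """Per-gene per-method ranks and their sum.

    ``ranks`` maps method name -> per-gene rank Series (average ranks for
    ties, so each method's ranks sum to n(n+1)/2); ``rank_sums`` is their
    per-gene sum.  ``order`` lists gene ids sorted ascending by rank sum,
    ties broken by gene id.
    """

    ranks: dict[str, pd.Series]
    rank_sums: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.rank_sums.index]

    @property
    def n_methods(self) -> int:
        return len(self.ranks)

    @property
    def order(self) -> list[str]:
        pairs = sorted(
            zip(self.rank_sums.to_numpy(), self.rank_sums.index.astype(str))
        )
        return [gene for _, gene in pairs]

    def sorted(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.ranks)
        frame["rank_sum"] = self.rank_sums
        return frame.loc[self.order]


def rank_by_raw_score(result: "MethodResult", ties: str = "average") -> pd.Series:
    """Ascending ranks of the engine's raw scores (rank 1 = most significant).

    Tied scores get the average of their rank positions by default;
    ``ties="min"`` switches to min-rank.
    """
    scores = result.raw_scores
    if scores.isna().any():
        raise ValueError(f"{result.method_name}: raw scores contain NaN")
    method = {"average": "average", "min": "min"}[ties]
    return pd.Series(
        stats.rankdata(scores.to_numpy(), method=method),
        index=scores.index,
        name=result.method_name,
    )


def rank_sum(
    rank_vectors: Sequence[pd.Series],
    weights: Sequence[float] | None = None,
) -> RankTable:
    """Sum per-gene ranks across methods into a :class:`RankTable`.

    All vectors must cover the identical gene set.  ``weights`` (default all
    1, the plain rank sum) allows a weighted combination.
    """
    if len(rank_vectors) < 2:
        raise ValueError("need ranks from >= 2 methods")
    base = set(rank_vectors[0].index)
    for vec in rank_vectors[1:]:
        if set(vec.index) != base:
            raise ValueError(
                f"gene sets differ between methods "
                f"({rank_vectors[0].name!r} vs {vec.name!r})"
            )
    if weights is None:
        weights = [1.0] * len(rank_vectors)
    if len(weights) != len(rank_vectors):
        raise ValueError("one weight per method required")
    index = rank_vectors[0].index
    ranks = {str(v.name): v.reindex(index) for v in rank_vectors}
    total = sum(
        w * v.reindex(index) for w, v in zip(weights, rank_vectors)
    )
    total.name = "rank_sum"
    return RankTable(ranks=ranks, rank_sums=total)


def aggregate(results: Sequence["MethodResult"], ties: str = "average") -> RankTable:
    """Convenience: rank each engine's raw scores and sum the ranks."""
    return rank_sum([rank_by_raw_score(r, ties=ties) for r in results])


def bh_adjust(raw_scores: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1, input order kept."""
    arr = np.asarray(raw_scores, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("raw scores must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def significant_set(
    result: "MethodResult",
    criterion: str = "fdr",
    threshold: float = 0.05,
    top_n: int = 100,
    rank_table: RankTable | None = None,
) -> set[str]:
    """Genes called significant by one engine under a criterion.

    ``criterion``: ``"fdr"`` (fdr_score < threshold), ``"fold_change"``
    (|log2FC| > threshold; empty for the engine without fold changes) or
    ``"top_rank"`` (the engine's top_n best-ranked genes).
    """
    table = result.table
    if criterion == "fdr":
        return set(table.index[table["fdr_score"] < threshold].astype(str))
    if criterion == "fold_change":
        if not result.has_fold_change:
            return set()
        return set(
            table.index[table["log2_fold_change"].abs() > threshold].astype(str)
        )
    if criterion == "top_rank":
        ranks = rank_by_raw_score(result)
        return set(ranks.nsmallest(top_n).index.astype(str))
    raise ValueError(f"unknown criterion {criterion!r}")


def concordance(
    results: Sequence["MethodResult"],
    criterion: str = "fdr",
    threshold: float = 0.05,
    top_n: int = 100,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Pairwise Spearman correlation of engine rank vectors plus the
    per-engine significant gene sets feeding the Venn layer."""
    if len(results) < 2:
        raise ValueError("concordance needs >= 2 methods")
    names = [r.method_name for r in results]
    ranks = [rank_by_raw_score(r) for r in results]
    n = len(results)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(
                ranks[i].to_numpy(), ranks[j].reindex(ranks[i].index).to_numpy()
            ).statistic
            corr[i, j] = corr[j, i] = rho
    matrix = pd.DataFrame(corr, index=names, columns=names)
    sets = {
        r.method_name: significant_set(r, criterion, threshold, top_n)
        for r in results
    }
    return matrix, sets
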