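"""Three negative-binomial differential-expression engines.

All engines model counts as NB with variance mu + alpha * mu^2 and differ in
their dispersion philosophy, mirroring the three classic count-based
testing traditions:

* ``deseq_like``  — median-of-ratios size factors; per-gene dispersion is
  the *maximum* of the individual method-of-moments estimate and a fitted
  dispersion-mean trend (conservative).
* ``edger_like``  — TMM (trimmed mean of M-values) effective library sizes;
  per-gene dispersion is *moderated toward* the trend by a weighted
  combination of the trend and the individual estimate.
* ``bayseq_like`` — empirical Bayes model comparison: a no-difference model
  against a group-specific-means model, each scored by averaging NB
  likelihoods over an empirically sampled prior of parameter tuples, with
  model prior weights estimated by iterated expectation.

The first two engines share a two-group exact test conditional on the
pooled count; the third reports 1 - posterior probability of differential
expression in place of a p-value and, being a model-comparison method,
yields no fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammaln, logsumexp

from .io_counts import CountMatrix, GroupAssignment

__all__ = [
    "SizeFactors",
    "DispersionEstimate",
    "MethodResult",
    "size_factors_median_ratio",
    "size_factors_tmm",
    "estimate_dispersions",
    "nb_exact_test",
    "run_engine",
    "run_bayseq_like",
]

ENGINE_NAMES = ("deseq_like", "edger_like", "bayseq_like")

#: shrinkage weight of the trend in the edger_like combination,
#: expressed as equivalent residual degrees of freedom
DEFAULT_PRIOR_DF = 10.0

#: pseudocount added to group means before the log2 fold change
FC_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive scaling factors, geometric mean 1."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    def values(self) -> np.ndarray:
        return self.factors.to_numpy(dtype=float)


@dataclass(frozen=True)
class DispersionEstimate:
    """Raw, trended and final per-gene dispersions plus trend parameters.

    The trend is the parametric form alpha(mu) = a0 + a1 / mu fitted by
    nonnegative least squares; ``final`` applies the mode's rule
    (max for deseq_like, weighted moderation for edger_like).
    """

    raw: pd.Series
    trend: pd.Series
    final: pd.Series
    trend_params: tuple[float, float]
    mode: str


@dataclass(frozen=True)
class MethodResult:
    """One engine's per-gene output.

    ``table`` columns: ``log2_fold_change`` (NaN throughout for the
    engine without fold changes), ``raw_score`` in (0, 1] (a p-value for
    the exact-test engines, 1 - posterior for the empirical Bayes engine)
    and ``fdr_score``.
    """

    method_name: str
    table: pd.DataFrame
    info: dict = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.table.index]

    @property
    def has_fold_change(self) -> bool:
        return self.method_name != "bayseq_like"

    @property
    def raw_scores(self) -> pd.Series:
        return self.table["raw_score"]


# ---------------------------------------------------------------------------
# NB log-probability helpers (mean/dispersion parameterization)

def _nb_logpmf(x: np.ndarray, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """log NB(x; mean, alpha) with var = mean + alpha mean^2.

    alpha -> 0 falls back to Poisson.  Broadcasts like numpy ufuncs.
    """
    x = np.asarray(x, dtype=float)
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-10)
    alpha = np.asarray(alpha, dtype=float)
    poisson = x * np.log(mean) - mean - gammaln(x + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(alpha > 0, 1.0 / np.where(alpha > 0, alpha, 1.0), np.inf)
        logp_r = np.where(
            np.isfinite(r), r * np.log(r / (r + mean)), -mean
        )
        nb = (
            gammaln(x + r)
            - gammaln(r)
            - gammaln(x + 1.0)
            + logp_r
            + x * np.log(mean / (r + mean))
        )
    return np.where(alpha > 0, nb, poisson)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


# ---------------------------------------------------------------------------
# Size factors

def size_factors_median_ratio(
    counts: CountMatrix, fallback_total_count: bool = False
) -> SizeFactors:
    """Median-of-ratios size factors.

    factor(s) = median over genes positive in every sample of
    count(g, s) / geometric mean of gene g, rescaled to geometric mean 1.
    """
    values = counts.values().astype(float)
    eligible = (values > 0).all(axis=1)
    if not eligible.any():
        if not fallback_total_count:
            raise ValueError(
                "no gene has positive counts in every sample; use the "
                "total-count fallback (fallback_total_count=True)"
            )
        factors = values.sum(axis=0)
    else:
        sub = values[eligible]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        ratios = np.log(sub) - log_geo
        factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return SizeFactors(
        pd.Series(factors, index=counts.sample_ids), method="median_ratio"
    )


def size_factors_tmm(
    counts: CountMatrix,
    trim_logratio: float = 0.30,
    trim_abundance: float = 0.05,
) -> SizeFactors:
    """Trimmed-mean-of-M-values effective size factors.

    The reference is the sample whose upper quartile of count/library-size
    is closest to the mean upper quartile.  Each sample's factor is the
    precision-weighted mean of doubly trimmed log2 ratios to the reference,
    exponentiated and combined with library size into an effective library
    size; factors are rescaled to geometric mean 1.
    """
    values = counts.values().astype(float)
    lib = values.sum(axis=0)
    frac = values / lib
    uq = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    n_samples = values.shape[1]
    tmm = np.ones(n_samples)
    for s in range(n_samples):
        if s == ref:
            continue
        shared = (values[:, s] > 0) & (values[:, ref] > 0)
        if not shared.any():
            warnings.warn(
                f"sample {counts.sample_ids[s]} shares no expressed gene "
                "with the reference; TMM factor set to 1",
                UserWarning,
                stacklevel=2,
            )
            continue
        ys, yr = values[shared, s], values[shared, ref]
        m = np.log2((ys / lib[s]) / (yr / lib[ref]))
        a = 0.5 * np.log2((ys / lib[s]) * (yr / lib[ref]))
        n = len(m)
        lo_m, hi_m = np.quantile(m, [trim_logratio, 1 - trim_logratio])
        lo_a, hi_a = np.quantile(a, [trim_abundance, 1 - trim_abundance])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        w = 1.0 / (
            (lib[s] - ys[keep]) / (lib[s] * ys[keep])
            + (lib[ref] - yr[keep]) / (lib[ref] * yr[keep])
        )
        tmm[s] = 2.0 ** (np.sum(w * m[keep]) / np.sum(w))
    effective = lib * tmm
    factors = effective / np.exp(np.mean(np.log(effective)))
    return SizeFactors(pd.Series(factors, index=counts.sample_ids), method="tmm")


# ---------------------------------------------------------------------------
# Dispersion

def _group_moments(
    normalized: np.ndarray, groups: GroupAssignment
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene grand mean, pooled within-group variance, group means."""
    idx0, idx1 = groups.indices(0), groups.indices(1)
    y0, y1 = normalized[:, idx0], normalized[:, idx1]
    n0, n1 = len(idx0), len(idx1)
    m0, m1 = y0.mean(axis=1), y1.mean(axis=1)
    v0 = y0.var(axis=1, ddof=1)
    v1 = y1.var(axis=1, ddof=1)
    pooled_var = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    grand_mean = normalized.mean(axis=1)
    return grand_mean, pooled_var, m0, m1


def estimate_dispersions(
    counts: CountMatrix,
    groups: GroupAssignment,
    factors: SizeFactors,
    mode: str,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> DispersionEstimate:
    """Method-of-moments dispersions with a parametric mean trend.

    Raw per-gene dispersion: alpha(g) = max(0, (pooled within-group
    variance - mean) / mean^2) on size-factor-normalized counts.  The
    trend alpha(mu) = a0 + a1/mu is fitted by nonnegative least squares to
    genes with positive raw dispersion.  ``deseq_like`` takes the gene-wise
    maximum of raw and trend; ``edger_like`` moderates the raw estimate
    toward the trend with ``prior_df`` equivalent residual degrees of
    freedom against the design's residual df.
    """
    if mode not in ("deseq_like", "edger_like"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    normalized = counts.values().astype(float) / factors.values()
    mu, pooled_var, _, _ = _group_moments(normalized, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (pooled_var - mu) / np.maximum(mu, 1e-10) ** 2, 0.0)
    raw = np.maximum(raw, 0.0)

    fit_mask = (raw > 0) & (mu > 0)
    if fit_mask.sum() < 10:
        warnings.warn(
            "fewer than 10 genes with positive raw dispersion; using the "
            "median raw dispersion as a flat trend",
            UserWarning,
            stacklevel=2,
        )
        a0, a1 = float(np.median(raw[fit_mask])) if fit_mask.any() else 0.0, 0.0
    else:
        design = np.column_stack(
            [np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]]
        )
        coef, _ = nnls(design, raw[fit_mask])
        a0, a1 = float(coef[0]), float(coef[1])
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-10), 0.0)

    if mode == "deseq_like":
        final = np.maximum(raw, trend)
    else:
        resid_df = counts.n_samples - 2
        final = (prior_df * trend + resid_df * raw) / (prior_df + resid_df)
    index = counts.data.index
    return DispersionEstimate(
        raw=pd.Series(raw, index=index),
        trend=pd.Series(trend, index=index),
        final=pd.Series(final, index=index),
        trend_params=(a0, a1),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Exact test

def nb_exact_test(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    dispersion: float,
    mean_estimate: float | None = None,
) -> float:
    """Two-sided exact NB test conditional on the pooled count.

    The group sums are modeled as NB with means n_a * mu and n_b * mu and
    summed dispersions alpha / n_a and alpha / n_b; the p-value adds the
    probabilities of every split of the total no more probable than the
    observed one.  dispersion = 0 reduces to the binomial split of a
    Poisson total.  A zero total carries no evidence (p = 1).
    """
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mu = total / (n_a + n_b) if mean_estimate is None else float(mean_estimate)
    x = np.arange(total + 1)
    la = _nb_logpmf(x, n_a * mu, dispersion / n_a)
    lb = _nb_logpmf(total - x, n_b * mu, dispersion / n_b)
    lp = la + lb
    l_obs = lp[int(sum_a)]
    denom = logsumexp(lp)
    keep = lp <= l_obs + 1e-8
    p = float(np.exp(logsumexp(lp[keep]) - denom))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Engines

def _log2_fold_change(
    normalized: np.ndarray, groups: GroupAssignment
) -> np.ndarray:
    m0 = normalized[:, groups.indices(0)].mean(axis=1)
    m1 = normalized[:, groups.indices(1)].mean(axis=1)
    return np.log2((m1 + FC_PSEUDOCOUNT) / (m0 + FC_PSEUDOCOUNT))


def run_engine(
    counts: CountMatrix,
    groups: GroupAssignment,
    mode: str,
    prior_df: float = DEFAULT_PRIOR_DF,
) -> MethodResult:
    """Run one exact-test engine end to end.

    Pipeline: size factors (median-of-ratios for deseq_like, TMM for
    edger_like) -> dispersion per mode -> per-gene exact NB test on
    pseudo-counts (counts scaled to equalized libraries, rounded half-up)
    -> Benjamini-Hochberg FDR.  log2 fold change uses group means of
    normalized counts with a 0.5 pseudocount.
    """
    from .rank_aggregation import bh_adjust

    if mode == "deseq_like":
        factors = size_factors_median_ratio(counts, fallback_total_count=True)
    elif mode == "edger_like":
        factors = size_factors_tmm(counts)
    else:
        raise ValueError(f"unknown engine mode {mode!r}")
    disp = estimate_dispersions(counts, groups, factors, mode, prior_df=prior_df)
    normalized = counts.values().astype(float) / factors.values()
    pseudo = _round_half_up(normalized).astype(np.int64)
    idx0, idx1 = groups.indices(0), groups.indices(1)
    n_a, n_b = len(idx0), len(idx1)
    sums_a = pseudo[:, idx0].sum(axis=1)
    sums_b = pseudo[:, idx1].sum(axis=1)
    alpha = disp.final.to_numpy()
    pvals = np.ones(counts.n_genes)
    for g in range(counts.n_genes):
        pvals[g] = nb_exact_test(
            int(sums_a[g]), int(sums_b[g]), n_a, n_b, float(alpha[g])
        )
    table = pd.DataFrame(
        {
            "log2_fold_change": _log2_fold_change(normalized, groups),
            "raw_score": np.clip(pvals, 1e-300, 1.0),
            "fdr_score": bh_adjust(np.clip(pvals, 1e-300, 1.0)),
        },
        index=counts.data.index,
    )
    return MethodResult(
        method_name=mode,
        table=table,
        info={
            "size_factor_method": factors.method,
            "dispersion_trend": disp.trend_params,
        },
    )


def run_bayseq_like(
    counts: CountMatrix,
    groups: GroupAssignment,
    n_prior_samples: int = 1000,
    seed: int = 0,
) -> MethodResult:
    """Empirical Bayes NB model comparison (posterior-ranked engine).

    Two models per gene: a shared NB mean for all samples versus
    (unordered) group-specific means, with method-of-moments dispersions
    estimated about the shared mean.  The prior is a seeded random subset
    of per-gene parameter fits; each model's marginal likelihood is the
    average NB likelihood over the prior tuples, and the model prior
    weights are estimated by iterating expected memberships to
    convergence.  ``raw_score`` is 1 - posterior probability of the
    group-specific model; ``fdr_score`` is the running mean of raw scores
    over genes sorted by descending posterior.  No fold change is reported.
    """
    if n_prior_samples < 50:
        raise ValueError("n_prior_samples must be >= 50")
    factors = size_factors_median_ratio(counts, fallback_total_count=True)
    normalized = counts.values().astype(float) / factors.values()
    pseudo = _round_half_up(normalized)
    mu, _, m0, m1 = _group_moments(pseudo, groups)
    # dispersion about the shared mean (the no-difference model's own
    # assumption); keeps that model honestly tolerant of sample-mean noise
    total_var = pseudo.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(
            mu > 0, (total_var - mu) / np.maximum(mu, 1e-10) ** 2, 0.0
        )
    alpha = np.maximum(alpha, 1e-6)

    rng = np.random.default_rng(seed)
    expressed = np.nonzero(mu > 0)[0]
    if len(expressed) == 0:
        raise ValueError("no expressed genes; cannot build an empirical prior")
    size = min(len(expressed), n_prior_samples)
    chosen = rng.choice(expressed, size=size, replace=False)
    prior_mu = np.maximum(mu[chosen], 1e-3)
    prior_m0 = np.maximum(m0[chosen], 1e-3)
    prior_m1 = np.maximum(m1[chosen], 1e-3)
    prior_alpha = alpha[chosen]
    tuples = np.column_stack([prior_mu, prior_m0, prior_m1, prior_alpha])
    if np.allclose(tuples, tuples[0]):
        raise ValueError(
            "degenerate empirical prior (all parameter tuples identical); "
            "provide more genes"
        )

    idx0, idx1 = groups.indices(0), groups.indices(1)
    log_l0 = np.empty(counts.n_genes)
    log_l1 = np.empty(counts.n_genes)
    log_t = np.log(size)
    chunk = max(1, int(2e6 // (size * counts.n_samples)))
    for start in range(0, counts.n_genes, chunk):
        y = pseudo[start : start + chunk]  # (G, S)
        yg = y[:, None, :]
        a = prior_alpha[None, :, None]
        ll0 = _nb_logpmf(yg, prior_mu[None, :, None], a).sum(axis=2)
        # group means are unordered in the DE model: average both
        # orientations of each tuple so no direction is privileged
        l1_fwd = _nb_logpmf(
            yg[:, :, idx0], prior_m0[None, :, None], a
        ).sum(axis=2) + _nb_logpmf(
            yg[:, :, idx1], prior_m1[None, :, None], a
        ).sum(axis=2)
        l1_rev = _nb_logpmf(
            yg[:, :, idx0], prior_m1[None, :, None], a
        ).sum(axis=2) + _nb_logpmf(
            yg[:, :, idx1], prior_m0[None, :, None], a
        ).sum(axis=2)
        ll1 = np.logaddexp(l1_fwd, l1_rev) - np.log(2.0)
        log_l0[start : start + chunk] = logsumexp(ll0, axis=1) - log_t
        log_l1[start : start + chunk] = logsumexp(ll1, axis=1) - log_t

    pi1 = 0.1
    posterior = np.full(counts.n_genes, pi1)
    for _ in range(100):
        num = np.log(pi1) + log_l1
        den = np.logaddexp(np.log1p(-pi1) + log_l0, num)
        posterior = np.exp(num - den)
        new_pi1 = float(np.clip(posterior.mean(), 1e-6, 1 - 1e-6))
        if abs(new_pi1 - pi1) < 1e-4:
            pi1 = new_pi1
            break
        pi1 = new_pi1
    num = np.log(pi1) + log_l1
    den = np.logaddexp(np.log1p(-pi1) + log_l0, num)
    posterior = np.exp(num - den)

    raw = np.clip(1.0 - posterior, 1e-12, 1.0)
    order = np.argsort(-posterior, kind="stable")
    running = np.cumsum(raw[order]) / np.arange(1, len(raw) + 1)
    fdr = np.empty_like(running)
    fdr[order] = np.minimum(running, 1.0)
    table = pd.DataFrame(
        {
            "log2_fold_change": np.nan,
            "raw_score": raw,
            "fdr_score": fdr,
        },
        index=counts.data.index,
    )
    return MethodResult(
        method_name="bayseq_like",
        table=table,
        info={"prior_weight_de": pi1, "n_prior_samples": size, "seed": seed},
    )
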