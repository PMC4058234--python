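"""Seeded negative-binomial count simulator with known truth.

Counts are drawn as NB(mean, alpha) with variance mu + alpha mu^2 — the
same parameterization the engines use.  Per-gene means combine a
log-normal baseline, a per-sample library factor, a group fold change for
differentially expressed genes and an optional lane/batch shift applied to
a configurable fraction of genes (batch effects in practice hit subsets of
genes; a shift on every gene would vanish under total-count
normalization).

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so each ingredient (baselines, DE assignment, libraries, counts,
outliers) has an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_counts import CountMatrix, GroupAssignment

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_counts",
    "noise_dominated_scenario",
    "outlier_inflation_scenario",
]


@dataclass
class SimulationConfig:
    """Everything a simulation needs; defaults give a clean 3 vs 3 study.

    ``dispersion`` is either a constant alpha or an ``(a0, a1)`` pair for
    the mean-dependent trend alpha(mu) = a0 + a1/mu.  ``log2fc`` is the DE
    magnitude; signs are split at random.  ``batch_levels`` assigns one
    level per sample; levels other than the first receive
    ``batch_log2_shift`` on a random ``batch_gene_fraction`` of genes.
    ``outlier`` = (sample index, inflation factor) multiplies that sample's
    counts by the factor on every DE gene.
    """

    n_genes: int = 2000
    n_per_group: tuple[int, int] = (3, 3)
    baseline_log_mean: float = 5.0  # natural-log mean of the baseline
    baseline_log_sd: float = 1.0
    dispersion: float | tuple[float, float] = 0.1
    de_fraction: float = 0.0
    log2fc: float = 2.0
    library_size_range: tuple[float, float] = (0.7, 1.4)
    batch_levels: Sequence[str] | None = None
    batch_log2_shift: float = 0.0
    batch_gene_fraction: float = 0.3
    noise_gene_fraction: float = 0.0
    noise_dispersion: float = 0.005
    outlier: tuple[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if min(self.n_per_group) < 2:
            raise ValueError("n_per_group entries must be >= 2")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0 <= self.noise_gene_fraction <= 1:
            raise ValueError("noise_gene_fraction must lie in [0, 1]")
        alphas = (
            self.dispersion
            if isinstance(self.dispersion, tuple)
            else (self.dispersion,)
        )
        if any(a < 0 for a in alphas):
            raise ValueError("dispersion parameters must be >= 0")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_group)


@dataclass
class SyntheticTruth:
    """Ground truth: per-gene DE status/fold change/dispersion, per-sample
    library factor, group and batch level."""

    genes: pd.DataFrame  # is_de, true_log2fc, true_dispersion
    samples: pd.DataFrame  # group, library_factor, batch_level
    expected_mean: pd.DataFrame | None = None  # designed NB mean per cell

    @property
    def de_genes(self) -> list[str]:
        return self.genes.index[self.genes["is_de"]].astype(str).tolist()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB(mean, alpha) counts; alpha = 0 falls back to Poisson."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a count matrix plus its :class:`SyntheticTruth`.

    mean(g, s) = mu_g * lib_s * 2^(log2fc_g * group_s) * 2^(batch shift),
    counts NB(mean, alpha_g); fully deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_de, rng_lib, rng_counts, rng_batch = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n_genes, n_samples = config.n_genes, config.n_samples
    n0, n1 = config.n_per_group
    groups = np.repeat([0, 1], [n0, n1])

    mu = rng_base.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    if isinstance(config.dispersion, tuple):
        a0, a1 = config.dispersion
        alpha = a0 + a1 / mu
    else:
        alpha = np.full(n_genes, float(config.dispersion))

    n_noise = int(round(config.noise_gene_fraction * n_genes))
    noise_mask = np.zeros(n_genes, dtype=bool)
    noise_mask[:n_noise] = True  # leading block; gene order is arbitrary
    alpha = np.where(noise_mask, config.noise_dispersion, alpha)

    n_de = int(round(config.de_fraction * n_genes))
    candidates = np.nonzero(~noise_mask)[0]
    if n_de > len(candidates):
        raise ValueError("de_fraction exceeds the non-noise gene pool")
    de_idx = rng_de.choice(candidates, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    lfc[de_idx] = config.log2fc * rng_de.choice([-1.0, 1.0], size=n_de)

    lib = rng_lib.uniform(*config.library_size_range, size=n_samples)
    mean = (
        mu[:, None]
        * lib[None, :]
        * 2.0 ** (lfc[:, None] * groups[None, :])
    )

    levels = (
        list(config.batch_levels)
        if config.batch_levels is not None
        else ["batch0"] * n_samples
    )
    if len(levels) != n_samples:
        raise ValueError("batch_levels must have one entry per sample")
    if config.batch_log2_shift != 0.0 and len(set(levels)) > 1:
        reference = sorted(set(levels))[0]
        shifted_samples = np.array([lv != reference for lv in levels])
        n_shift_genes = int(round(config.batch_gene_fraction * n_genes))
        shift_genes = rng_batch.choice(n_genes, size=n_shift_genes, replace=False)
        shift = np.zeros((n_genes, n_samples))
        shift[np.ix_(shift_genes, np.nonzero(shifted_samples)[0])] = (
            config.batch_log2_shift
        )
        mean = mean * 2.0**shift

    counts = _nb_draw(rng_counts, mean, alpha[:, None])

    if config.outlier is not None:
        s_idx, inflation = config.outlier
        if not 0 <= s_idx < n_samples:
            raise ValueError("outlier sample index out of range")
        counts[de_idx, s_idx] = np.floor(counts[de_idx, s_idx] * inflation + 0.5)

    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    sample_ids = [
        f"{'ctrl' if g == 0 else 'case'}_{i}" for i, g in enumerate(groups)
    ]
    matrix = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(
            {
                "is_de": np.isin(np.arange(n_genes), de_idx),
                "true_log2fc": lfc,
                "true_dispersion": alpha,
            },
            index=gene_ids,
        ),
        samples=pd.DataFrame(
            {"group": groups, "library_factor": lib, "batch_level": levels},
            index=sample_ids,
        ),
        expected_mean=pd.DataFrame(mean, index=gene_ids, columns=sample_ids),
    )
    return matrix, truth


def noise_dominated_scenario(
    seed: int,
    n_genes: int = 1000,
    n_informative: int = 30,
    informative_log2fc: float = 1.8,
    noise_signature_sd: float = 0.3,
) -> tuple[CountMatrix, GroupAssignment, str]:
    """A noise-dominated 3 vs 3 study with one misleading control sample.

    Most genes (here 97%) are biologically uninformative: tight NB noise
    around a shared baseline, plus a per-gene "processing signature"
    (log2-normal multiplicative wobble) shared by the disease samples *and*
    one control.  A small informative set separates the groups, and the
    misleading control carries the correct control-level signal there.  On
    all genes, Spearman clustering drags that control into the disease
    block; after filtering to the top-5% CV genes (which isolates the
    informative set) the grouping is correct.

    Returns (counts, groups, id of the expected outlier sample).
    """
    ss = np.random.SeedSequence([seed, 0x0F1])
    rng_mu, rng_sig, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))
    n_noise = n_genes - n_informative
    groups = GroupAssignment(np.array([0, 0, 0, 1, 1, 1]))
    sample_ids = ["control_1", "control_2", "control_3",
                  "disease_1", "disease_2", "disease_3"]
    outlier = "control_1"
    # outlier control shares the signature with the disease samples
    signed = np.array([1, 0, 0, 1, 1, 1], dtype=float)

    mu_noise = rng_mu.lognormal(np.log(500.0), 0.8, n_noise)
    delta = rng_sig.normal(0.0, noise_signature_sd, n_noise)
    mean_noise = mu_noise[:, None] * 2.0 ** (delta[:, None] * signed[None, :])
    counts_noise = _nb_draw(rng_counts, mean_noise, np.full((n_noise, 1), 0.005))

    mu_inf = rng_mu.lognormal(np.log(200.0), 0.5, n_informative)
    lfc = informative_log2fc * rng_mu.choice([-1.0, 1.0], size=n_informative)
    mean_inf = mu_inf[:, None] * 2.0 ** (
        lfc[:, None] * groups.labels[None, :].astype(float)
    )
    counts_inf = _nb_draw(rng_counts, mean_inf, np.full((n_informative, 1), 0.05))

    counts = np.vstack([counts_noise, counts_inf])
    gene_ids = [f"noise_{i:04d}" for i in range(n_noise)] + [
        f"marker_{i:03d}" for i in range(n_informative)
    ]
    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids))
    return matrix, groups, outlier


def outlier_inflation_scenario(
    seed: int,
    inflate: bool = True,
    n_genes: int = 1000,
) -> tuple[CountMatrix, SyntheticTruth]:
    """A DE study whose DE genes each carry one extreme within-group count.

    Starts from a clean 10%-DE simulation (|log2FC| = 2, alpha = 0.1,
    3 vs 3) and, when ``inflate`` is set, multiplies one randomly chosen
    group-1 count per DE gene by a factor drawn in [10, 30] — the
    single-sample blow-up pattern under which count-based engines start to
    disagree.  ``inflate=False`` returns the matched clean study for paired
    comparisons.
    """
    config = SimulationConfig(
        n_genes=n_genes,
        de_fraction=0.10,
        log2fc=2.0,
        dispersion=0.1,
        seed=seed,
    )
    matrix, truth = simulate_counts(config)
    if not inflate:
        return matrix, truth
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x164]))
    counts = matrix.values().copy()
    group1 = np.nonzero(truth.samples["group"].to_numpy() == 1)[0]
    de_rows = np.nonzero(truth.genes["is_de"].to_numpy())[0]
    which = rng.choice(group1, size=len(de_rows))
    factors = rng.uniform(10.0, 30.0, size=len(de_rows))
    # blow up one group-1 count per DE gene past the group's largest count,
    # so the > 10x max/median pattern holds by construction
    group_max = np.maximum(counts[de_rows][:, group1].max(axis=1), 1.0)
    counts[de_rows, which] = np.floor(group_max * factors + 0.5)
    inflated = CountMatrix(
        pd.DataFrame(counts, index=matrix.gene_ids, columns=matrix.sample_ids)
    )
    return inflated, truth
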