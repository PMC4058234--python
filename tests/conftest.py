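import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from multirank import CountMatrix, GroupAssignment, SimulationConfig, simulate_counts


@pytest.fixture
def groups33() -> GroupAssignment:
    return GroupAssignment(np.array([0, 0, 0, 1, 1, 1]))


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Deterministic 5-gene x 6-sample matrix with visible structure."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.poisson(
            [[50], [200], [10], [500], [120]] * np.ones((5, 6)), size=(5, 6)
        ),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(6)],
    )
    return CountMatrix(data)


@pytest.fixture(scope="session")
def de_study():
    """One labeled 10%-DE study (|log2FC|=2, alpha=0.1, 3 vs 3), shared
    across tests that only read it."""
    config = SimulationConfig(
        n_genes=1000, de_fraction=0.10, log2fc=2.0, dispersion=0.1, seed=2024
    )
    return simulate_counts(config)


def mann_whitney_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-sum identity (independent of any ML library)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels, dtype=bool)
    ranks = rankdata(scores)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
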