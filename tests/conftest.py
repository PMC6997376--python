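import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import coexdiff as cd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_design() -> pd.DataFrame:
    return cd.simulate_design(cd.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated study: planted modules + DE genes + background."""
    cfg = cd.SimulationConfig(n_genes=400, seed=42)
    design = cd.simulate_design(cfg)
    counts, truth = cd.simulate_counts(design, cfg)
    return cfg, design, counts, truth


def exact_correlated_vectors(rhos: np.ndarray, n_samples: int = 8) -> np.ndarray:
    """Rows with *exact* sample Pearson correlations given by ``rhos``.

    Builds zero-mean orthonormal directions and mixes them by the Cholesky
    factor of the target correlation matrix, so np.corrcoef reproduces
    ``rhos`` to machine precision.
    """
    p = rhos.shape[0]
    assert n_samples >= p + 1
    rng = np.random.default_rng(1)
    raw = rng.normal(size=(n_samples, p))
    raw -= raw.mean(axis=0, keepdims=True)  # project out the ones direction
    q, _ = np.linalg.qr(raw)  # columns: orthonormal and exactly zero-mean
    basis = q.T
    L = np.linalg.cholesky(rhos)
    return L @ basis
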