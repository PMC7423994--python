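import numpy as np
import pandas as pd
import pytest

from polyexpr.config import SimConfig
from polyexpr.containers import CountMatrix
from polyexpr.simulate import simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """One seeded synthetic dataset shared by read-only tests."""
    return simulate_counts(SimConfig(n_loci=400, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def nb_matrix(rng, mu, phi, groups, n_loci=None):
    """NB count matrix helper: mu is per-locus, one column per sample."""
    mu = np.asarray(mu, dtype=float)
    n = len(mu) if n_loci is None else n_loci
    cols = {}
    for j, g in enumerate(groups):
        lam = rng.gamma(1.0 / phi, mu * phi)
        cols[f"s{j}"] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=[f"g{i:05d}" for i in range(n)])
    samples = pd.DataFrame({"group": list(groups)}, index=counts.columns)
    return CountMatrix(counts, samples)
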