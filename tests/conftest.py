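import numpy as np
import pandas as pd
import pytest

import peakcv as pc


def make_table(X, n_a, n_b, mz_start=400, group_a="control", group_b="case"):
    """Cohort table straight from an (n_samples x n_bins) area matrix."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    assert n == n_a + n_b
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    areas = pd.DataFrame(X, index=ids, columns=np.arange(mz_start, mz_start + m))
    samples = pd.DataFrame(
        {"group": [group_a] * n_a + [group_b] * n_b, "age": 40.0}, index=areas.index
    )
    samples.index.name = areas.index.name = "sample_id"
    return pc.CohortTable(samples, areas)


def random_table(seed, n_a=8, n_b=8, n_bins=50, shift=0.0):
    """Log-normal random cohort; optional multiplicative group-B shift."""
    rng = np.random.default_rng(seed)
    X = np.exp(rng.normal(0.0, 1.0, size=(n_a + n_b, n_bins)))
    X[n_a:] *= np.exp(shift)
    return make_table(X, n_a, n_b)


@pytest.fixture
def small_sim_config():
    """Fast synthetic cohort: 6v6 subjects on a 120-bin grid."""
    return pc.SimConfig(
        n_group_a=6,
        n_group_b=6,
        mz_min=400,
        mz_max=519,
        n_discriminatory=30,
        effect_delta=2.0,
        seed=11,
    )


@pytest.fixture
def small_table(small_sim_config):
    return pc.simulate_table(small_sim_config)


@pytest.fixture
def case_config():
    return pc.LoocvConfig(target_group="case")
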