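import numpy as np
import pandas as pd
import pytest

from stresshypo import CountMatrix, SimulationParams, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A quick planted experiment shared by read-only tests."""
    params = SimulationParams(
        n_genes=800,
        n_de=100,
        lfc_de=1.0,
        n_modules=4,
        module_size_range=(30, 60),
        n_group_shifted_modules=2,
        seed=11,
    )
    counts, sheet, truth = simulate_experiment(params)
    return params, counts, sheet, truth


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(0)
    vals = rng.integers(0, 500, size=(30, 8))
    vals[:5] += 20  # guarantee all-positive reference genes for size factors
    return CountMatrix(
        vals,
        [f"g{i:02d}" for i in range(30)],
        [f"s{j}" for j in range(8)],
    )


@pytest.fixture
def two_group_design():
    return np.array([0, 0, 0, 0, 1, 1, 1, 1])
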