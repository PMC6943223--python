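import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from difconet import CountMatrix, SimulationConfig, generate_counts

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_cm() -> CountMatrix:
    """Deterministic 6-gene x 6-sample matrix with a mix of behaviours."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(50, size=(6, 6)),
        index=[f"g{i}" for i in range(6)],
        columns=["A1", "A2", "A3", "B1", "B2", "B3"],
    )
    cond = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
    return CountMatrix(counts, cond)


@pytest.fixture
def sim_default():
    """One modest synthetic dataset with planted structure."""
    config = SimulationConfig(n_genes=400, deg_fraction=0.1, lfc_magnitude=2.0, seed=42)
    cm, truth = generate_counts(config)
    return config, cm, truth
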