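import numpy as np
import pandas as pd
import pytest

import stridemod as sm
from stridemod.config import SimulationConfig


def make_expression(values: np.ndarray, batches: int = 1,
                    log2: bool = True) -> sm.ExpressionData:
    """Wrap a plain array as ExpressionData with a minimal sample sheet."""
    P, S = values.shape
    probes = [f"g{i}" for i in range(P)]
    samples = pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(S)],
        "drug": "saline", "time_h": 1,
        "batch": [f"b{j % batches}" for j in range(S)],
        "arm": "vehicle", "replicate": range(S),
    })
    return sm.ExpressionData(
        values=pd.DataFrame(values, index=probes, columns=samples.sample_id),
        samples=samples, log2=log2)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_probes=800, n_background_promoters=60, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One simulated study shared across tests (read-only)."""
    data, truth = sm.simulate_expression(small_config)
    return data, truth


@pytest.fixture(scope="session")
def small_normalized(small_sim):
    data, _ = small_sim
    raw = sm.ExpressionData(values=2.0 ** data.values, samples=data.samples,
                            log2=False)
    return sm.standardize(
        sm.quantile_normalize(sm.log2_transform(raw)))
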