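import numpy as np
import pandas as pd
import pytest

from mirsig import (
    CtMatrix,
    impute_undetected,
    normalize_delta_ct,
    simulate_card_experiment,
)
from mirsig.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_dataset():
    """One default-config simulated card experiment (fixed seed)."""
    return simulate_card_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_delta(default_dataset):
    return normalize_delta_ct(impute_undetected(default_dataset.ct))


@pytest.fixture
def toy_ct():
    """3 probes (1 control) × 2 samples with one undetected well."""
    values = pd.DataFrame(
        {"s1": [25.0, 30.0, 20.0], "s2": [26.0, np.nan, 22.0]},
        index=["probeA", "probeB", "U6"],
    )
    detected = pd.DataFrame(
        {"s1": [True, True, True], "s2": [True, False, True]},
        index=values.index,
    )
    return CtMatrix(values=values, detected=detected, control_probe_ids=("U6",))
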