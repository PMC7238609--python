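import numpy as np
import pytest

from metsig.preprocessing_io import FoldChangeMatrix, OutcomeVector
from metsig.synthetic_data import SimulationConfig, make_dataset


def make_matrix(values, prefix_s="s", prefix_g="g"):
    values = np.asarray(values, dtype=float)
    return FoldChangeMatrix(
        values,
        [f"{prefix_s}{i}" for i in range(values.shape[0])],
        [f"{prefix_g}{j}" for j in range(values.shape[1])],
    )


def make_outcome(values):
    return OutcomeVector(np.asarray(values), [f"s{i}" for i in range(len(values))])


@pytest.fixture(scope="session")
def signal_dataset():
    """A strong-signal dataset where the true support is recoverable."""
    return make_dataset(
        SimulationConfig(n=300, p=120, n_signal=6, effect_size=1.0, seed=202)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small moderate-signal dataset for fast bootstrap runs."""
    return make_dataset(
        SimulationConfig(n=60, p=40, n_signal=4, effect_size=1.2, seed=77)
    )
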