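import numpy as np
import pandas as pd
import pytest

from tfspec import FrequencyMatrix, SyntheticTruth, random_energy_matrix


def make_random_frequency_matrix(
    rng: np.random.Generator, length: int = 3, alphabet=("A", "C", "G", "T"),
    positions=None,
) -> FrequencyMatrix:
    """Dirichlet-random probability columns; a generic test matrix."""
    probs = rng.dirichlet(np.ones(len(alphabet)), size=length)
    if positions is None:
        positions = list(range(1, length + 1))
    return FrequencyMatrix(pd.DataFrame(probs, index=positions, columns=list(alphabet)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def default_truth() -> SyntheticTruth:
    """The canonical synthetic study conditions (seed 0)."""
    return SyntheticTruth(
        truth_matrix=random_energy_matrix(seed=0),
        dg_ns_true=3.3,
        noise_sigma=0.1,
        seed=0,
    )
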