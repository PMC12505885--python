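import numpy as np
import pandas as pd
import pytest

from warmnet import DesignSpec, generate_experiment


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic experiment shared across read-only tests."""
    return generate_experiment(DesignSpec(seed=0))


@pytest.fixture(scope="session")
def topsoil_design():
    """Treatment / block layout of one 20-sample layer."""
    treatment = np.repeat([0.0, 0.8, 1.5, 3.0, 4.2], 4)
    block = np.tile([1, 2, 3, 4], 5)
    return treatment, block


def make_abundance(values, taxa=None, samples=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=taxa, columns=samples)
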