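import numpy as np
import pandas as pd
import pytest

from tadscape.simulate import SimulationParams, make_genome, simulate


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=11)


@pytest.fixture(scope="session")
def genome(default_params):
    return make_genome(default_params)


@pytest.fixture(scope="session")
def dataset(default_params):
    """Full default-scale simulated dataset shared across recovery tests."""
    return simulate(default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_tads():
    """Ten 1-Mb TADs on two chromosomes."""
    rows = []
    for c in ("chr1", "chr2"):
        for i in range(5):
            rows.append((c, i * 1_000_000, (i + 1) * 1_000_000))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["tad_id"] = [f"t{i}" for i in range(len(df))]
    return df
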