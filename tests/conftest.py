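import numpy as np
import pytest

from jointseg import (
    GenePanel,
    SimulationParams,
    make_synthetic_taxonomy,
    simulate_tissue,
)


@pytest.fixture(scope="session")
def taxonomy6():
    """Six well-separated synthetic types over a 20-gene panel."""
    return make_synthetic_taxonomy(6, 20, seed=1)


@pytest.fixture(scope="session")
def tiny_tissue(taxonomy6):
    """Small simulated tissue shared by model-level tests."""
    return simulate_tissue(
        SimulationParams(extent=(40.0, 40.0, 12.0), seed=1), taxonomy6
    )


@pytest.fixture()
def panel4():
    return GenePanel(["Gad1", "Slc17a7", "Aqp4", "Cx3cr1"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
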