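import numpy as np
import pytest

import fovpower as fp


@pytest.fixture(scope="session")
def default_params():
    return fp.SimulationParams()


@pytest.fixture(scope="session")
def small_dataset():
    """4 individuals x 2 paired samples x 6 FoVs of 30 cells."""
    design = fp.StudyDesign(n_individuals=4, n_fov=6, cells_per_fov=30)
    return fp.simulate_dataset(design, fp.SimulationParams(), seed=20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 individuals x 2 samples x 2 FoVs of 10 cells (quadrature scale)."""
    design = fp.StudyDesign(n_individuals=2, n_fov=2, cells_per_fov=10)
    return fp.simulate_dataset(design, fp.SimulationParams(), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
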