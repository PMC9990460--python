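import numpy as np
import pytest

from gliascreen.design import ScreenDesign
from gliascreen.simulate import SimulationConfig


@pytest.fixture
def small_design() -> ScreenDesign:
    """A 60-gene, single-master-plate screen: fast but structurally complete."""
    return ScreenDesign(n_genes=60, n_master_plates=1, pad_to_daughters=None)


@pytest.fixture
def small_sim(small_design) -> SimulationConfig:
    return SimulationConfig(design=small_design, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
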