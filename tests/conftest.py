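import numpy as np
import pytest

from mitomarker.simulate import default_config, simulate_panel


@pytest.fixture(scope="session")
def panel8():
    """A seeded 8-taxon synthetic panel with its ground truth."""
    cfg = default_config(n_taxa=8, seed=11)
    panel, truth = simulate_panel(cfg)
    return panel, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20230915)
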