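import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from morphoseg.phantom import PhantomConfig, generate_phantom  # noqa: E402


@pytest.fixture(scope="session")
def small_phantom():
    """A 4-cell phantom on a small grid, shared across tests."""
    cfg = PhantomConfig(n_cells=4, rng_seed=1, grid_shape=(32, 40, 48),
                        embryo_semiaxes_um=(10.0, 8.0, 6.0))
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def eight_cell_phantom():
    """The default 8-cell study condition, noiseless imaging."""
    cfg = PhantomConfig(n_cells=8, rng_seed=2, noise_sd=0.0)
    return generate_phantom(cfg)
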