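import numpy as np
import pytest

from micacardio.synthgen import PhantomSpec, make_phantom
from micacardio.types import DesignBlocks


@pytest.fixture(scope="session")
def design():
    return DesignBlocks(
        [("LBNP", 0, 300), ("Rest", 300, 600), ("LBNP", 600, 900), ("Rest", 900, 1200)]
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two well-separated noiseless sources; exact rank-2 data."""
    spec = PhantomSpec(
        k_true=2,
        noise_sd=0.0,
        run_cv=0.0,
        couplings=[],
        csf_source=False,
        centres=[(9.5, 9.5, 5.5), (13.5, 13.5, 5.5)],
        radii=[1.0, 1.0],
        n_runs=2,
        n_volumes=80,
        seed=5,
    )
    return spec, make_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201)
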