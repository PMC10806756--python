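import numpy as np
import pytest

from smrtriage.fixtures import make_fixture_bundle
from smrtriage.simulate import simulate_ld_panel


@pytest.fixture(scope="session")
def panel():
    """Shared 30-SNP AR(1) reference panel (latent rho 0.7)."""
    return simulate_ld_panel(30, 1000, 0.7, seed=42)


@pytest.fixture(scope="session")
def panel_indep():
    """Panel of (near-)independent SNPs for pruning/oracle tests."""
    return simulate_ld_panel(10, 4000, 0.0, seed=43)


@pytest.fixture()
def bundle():
    return make_fixture_bundle()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
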