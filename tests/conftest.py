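import numpy as np
import pytest

from cyanopbr import (
    AutotrophicParams,
    CultureState,
    HeterotrophicParams,
    LightConfig,
    OpticalParams,
)


@pytest.fixture(scope="session")
def optics():
    return OpticalParams()


@pytest.fixture(scope="session")
def lab_light():
    """The 1 L laboratory flat plate: 0.025 m, one lit face, 92 µmol/m²/s."""
    return LightConfig(I0=92.0, L=0.025, n_surfaces=1)


@pytest.fixture(scope="session")
def auto_params():
    return AutotrophicParams()


@pytest.fixture(scope="session")
def het_params():
    return HeterotrophicParams()


@pytest.fixture(scope="session")
def replete_state():
    """Nutrient-replete batch start used across estimation/sensitivity tests."""
    return CultureState(X=0.2, N=500.0, q=1.0, C=50.0, O2=0.0, H2=0.0)


@pytest.fixture(scope="session")
def transparent_optics():
    """No absorption, no bubbles: uniform light, analytic reference regime."""
    return OpticalParams(tau_c=0.0, alpha_g=0.0, d_b=0.002)


@pytest.fixture(scope="session")
def coarse_grid():
    return np.linspace(0.0, 150.0, 31)
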