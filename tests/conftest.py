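import numpy as np
import pytest

from vibronica import fixtures as fx
from vibronica import normal_modes as nm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def diatomic():
    """Equal-mass diatomic with a single 0.1 E_h/bohr^2 stretch."""
    mol, hess = fx.make_diatomic((1.0, 1.0), 0.1)
    return mol, hess


@pytest.fixture
def diatomic_modes(diatomic):
    mol, hess = diatomic
    return nm.compute_modes(hess, mol)


@pytest.fixture
def triatomic():
    """Bent 3-atom fixture with prescribed frequencies."""
    return fx.make_bent_triatomic(seed=0)


@pytest.fixture
def triatomic_modes(triatomic):
    mol, hess, _ = triatomic
    return nm.compute_modes(hess, mol)


@pytest.fixture
def single_mode():
    """One-mode NormalModeSet with omega = 0.01 a.u."""
    return fx.single_mode_set(omega_au=0.01)
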