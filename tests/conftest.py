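import numpy as np
import pytest

from hoprescale import AtomicSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_system(rng, n_atoms=None, zero_velocity=False):
    """Random finite system with positive masses; velocities O(1e-3) a.u."""
    if n_atoms is None:
        n_atoms = int(rng.integers(1, 7))
    masses = rng.uniform(500.0, 5000.0, size=n_atoms)
    positions = rng.normal(0.0, 2.0, size=(n_atoms, 3))
    velocities = np.zeros((n_atoms, 3)) if zero_velocity else rng.normal(0.0, 2e-3, size=(n_atoms, 3))
    labels = [f"A{i}" for i in range(n_atoms)]
    return AtomicSystem(labels, masses, positions, velocities)


@pytest.fixture
def system_factory():
    return random_system
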