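import numpy as np
import pytest

from pocketbench import fixtures as fx


@pytest.fixture(scope="session")
def positive_pair():
    """Zero-noise positive pocket pair with planted ground truth."""
    spec = fx.FixtureSpec(seed=3, n_residues=60, n_ligand_atoms=6)
    return fx.make_complex_pair(spec, "positive")


@pytest.fixture(scope="session")
def noisy_positive_pair():
    spec = fx.FixtureSpec(seed=5, n_residues=60, n_ligand_atoms=6,
                          coordinate_noise=0.3)
    return fx.make_complex_pair(spec, "positive")


@pytest.fixture(scope="session")
def negative_pair():
    spec = fx.FixtureSpec(seed=7, n_residues=60, n_ligand_atoms=6)
    return fx.make_complex_pair(spec, "negative")


@pytest.fixture(scope="session")
def small_complex():
    return fx.make_complex(fx.FixtureSpec(seed=11, n_residues=55))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
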