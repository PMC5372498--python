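import numpy as np
import pytest

import mdtrend as mt


@pytest.fixture(scope="session")
def toy_spec():
    return mt.SyntheticSpec(
        n_residues=10, ligand_atoms=6, key_residues=frozenset({4, 8}),
        n_frames=6, seed=11,
    )


@pytest.fixture(scope="session")
def toy_system(toy_spec):
    return mt.make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_traj(toy_system, toy_spec):
    return mt.simulate_trajectory(toy_system, toy_spec)


@pytest.fixture(scope="session")
def ligand_sel(toy_system):
    return mt.select(toy_system, "resname LIG")


@pytest.fixture(scope="session")
def protein_sel(toy_system):
    return mt.select(toy_system, "protein")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
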