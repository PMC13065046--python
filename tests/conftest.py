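import numpy as np
import pytest

import memflux as mf


@pytest.fixture(scope="session")
def perm_system():
    return mf.generate_permeation_system(mf.SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def wire_system():
    return mf.generate_wire_frames(mf.SyntheticSpec(seed=12))


@pytest.fixture(scope="session")
def agg_system():
    return mf.generate_aggregation_trajectory(mf.SyntheticSpec(seed=13))


@pytest.fixture(scope="session")
def cluster_system():
    return mf.generate_cluster_frames(mf.SyntheticSpec(seed=14))


def volume_for(traj, truth, cutoff=6.0):
    slab = mf.MembraneSlab(*truth.extras["slab"])
    return mf.ProteinVolume(traj.protein_heavy_indices(), slab, cutoff)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_toy_trajectory(coords, box=None, water=()):
    """Trajectory from raw coords (n_frames, n_atoms, 3); atom i is a water
    oxygen iff i in ``water``, else a protein carbon."""
    coords = np.asarray(coords, dtype=float)
    atoms = []
    for i in range(coords.shape[1]):
        if i in water:
            atoms.append(mf.AtomRecord(i, "OH2", "O", "HOH", i + 1, "W", 1, True, True))
        else:
            atoms.append(mf.AtomRecord(i, "C", "C", "DUM", i + 1, "P", 0, False, True))
    return mf.Trajectory(atoms=atoms, coords=coords, box=box)
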