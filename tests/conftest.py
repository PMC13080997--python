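"""Shared fixtures: small synthetic structures and trajectories.

Everything is generated programmatically — no binary fixtures on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from allokin import Selection, Structure, Trajectory
from allokin.synthetic_data import ca_chain_structure, ideal_helix_backbone


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def ca_structure():
    """A 10-residue Cα chain on a gently curved path."""
    t = np.linspace(0, 3, 10)
    coords = np.stack([6 * t, 4 * np.sin(t), 4 * np.cos(t)], axis=1)
    return ca_chain_structure(coords)


@pytest.fixture()
def helix():
    """Ideal 30-residue α-helix backbone, residues 1-30."""
    return ideal_helix_backbone(30)


@pytest.fixture()
def rigid_trajectory(ca_structure, rng):
    """Random rigid-body transforms of one Cα structure (distances exact)."""
    from scipy.spatial.transform import Rotation

    frames = []
    for _ in range(25):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        frames.append(ca_structure.coords @ R.T + t)
    return Trajectory(ca_structure, np.array(frames))


@pytest.fixture()
def toy_pdb(tmp_path, helix):
    """The helix written out as a single-model PDB file."""
    from allokin import write_structure

    path = tmp_path / "helix.pdb"
    write_structure(helix, path)
    return path


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
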