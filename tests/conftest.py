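"""Shared fixtures: toy topologies, small test alphabets, oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from allopath.alphabet import Alphabet, fragment_from_angles
from allopath.io import Atom, Residue, Topology, Trajectory


def make_ca_topology(n_residues: int, first_index: int = 1, chain: str = "A") -> Topology:
    """Cα-only topology with consecutive residue numbering."""
    return Topology(
        residues=[
            Residue(index=first_index + k, name="GLY", chain=chain) for k in range(n_residues)
        ],
        atoms=[Atom(name="CA", residue_index=first_index + k) for k in range(n_residues)],
    )


def make_trajectory(coords: np.ndarray, first_index: int = 1) -> Trajectory:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return Trajectory(coordinates=coords, topology=make_ca_topology(coords.shape[1], first_index))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def two_state_alphabet():
    """Helix-like vs extended-like canonical fragments."""
    return Alphabet(
        letters=["A", "B"],
        coordinates=np.stack(
            [fragment_from_angles(89.0, 89.0, 50.0), fragment_from_angles(125.0, 125.0, 180.0)]
        ),
    )


@pytest.fixture
def four_state_alphabet():
    angles = [(89.0, 92.0, 50.0), (110.0, 112.0, -60.0), (125.0, 122.0, 180.0), (100.0, 98.0, 0.0)]
    return Alphabet(
        letters=["A", "B", "C", "D"],
        coordinates=np.stack([fragment_from_angles(*a) for a in angles]),
    )
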