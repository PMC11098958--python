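"""Structural-alphabet encoding of Cα trajectories.

A protein chain of n residues is decomposed into n − 3 overlapping
fragments of four consecutive Cα atoms (fragment f_i covers residues
i..i+3; consecutive fragments share three residues).  Each fragment
conformation is summarised by three internal angles — the two pseudo-bond
angles θ1 (Cα 1-2-3) and θ2 (Cα 2-3-4) and the pseudo-torsion τ
(Cα 1-2-3-4, IUPAC sign convention, cis = 0) — and assigned the most
similar letter of a finite alphabet of canonical fragment conformations,
either by minimal RMSD after optimal superposition onto the canonical
4-point coordinates (``rmsd_local_fit``) or by nearest neighbour in
(θ1, θ2, τ) space with a periodic τ metric (``descriptor_nearest``).

Encoding a trajectory of F frames yields an F × (n − 3) matrix of letters:
the aligned structural strings whose columns feed the mutual-information
network analysis.

The shipped 25-letter default (``data/alphabet25_synthetic.json``) is a
synthetic stand-in alphabet on a deterministic angle grid, not the
canonical alphabet from the structural-alphabet literature; see the file's
own metadata.  Any alphabet with ≥ 2 states can be plugged in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Topology, Trajectory

__all__ = [
    "Fragment",
    "FragmentDescriptor",
    "Alphabet",
    "StringAlignment",
    "fragmentize",
    "fragment_descriptors",
    "fragment_from_angles",
    "load_alphabet",
    "StructuralAlphabetEncoder",
    "assign_states",
]

CA_CA_BOND = 3.8  # Å, canonical consecutive Cα distance


@dataclass(frozen=True)
class Fragment:
    """Four-residue fragment named by its first residue index."""

    index: int
    chain_id: str = "A"

    @property
    def residue_indices(self) -> tuple[int, int, int, int]:
        return (self.index, self.index + 1, self.index + 2, self.index + 3)

    @property
    def name(self) -> str:
        return f"f{self.index}"


@dataclass(frozen=True)
class FragmentDescriptor:
    theta1: float  # degrees, pseudo-bond angle Cα 1-2-3
    theta2: float  # degrees, pseudo-bond angle Cα 2-3-4
    tau: float     # degrees in (−180, 180], pseudo-torsion Cα 1-2-3-4

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.tau])


@dataclass
class Alphabet:
    """A finite set of canonical fragment conformations.

    Each letter has canonical 4 × 3 Cα coordinates (Å) and/or a canonical
    (θ1, θ2, τ) triple; coordinates are required for ``rmsd_local_fit``.
    """

    letters: list[str]
    coordinates: Optional[np.ndarray] = None  # L × 4 × 3
    angles: Optional[np.ndarray] = None       # L × 3 degrees

    def __post_init__(self) -> None:
        if len(self.letters) < 2:
            raise ValueError("alphabet needs at least 2 states")
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be unique")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (len(self.letters), 4, 3):
                raise ValueError("canonical coordinates must be L × 4 × 3")
        if self.angles is None and self.coordinates is not None:
            self.angles = np.stack(
                [fragment_descriptors(c).as_array() for c in self.coordinates]
            )
        if self.angles is not None:
            self.angles = np.asarray(self.angles, dtype=float)
            if self.angles.shape != (len(self.letters), 3):
                raise ValueError("canonical angles must be L × 3")
        if self.coordinates is None and self.angles is not None:
            self.coordinates = np.stack(
                [fragment_from_angles(*a) for a in self.angles]
            )

    @property
    def n_states(self) -> int:
        return len(self.letters)

    @classmethod
    def from_json(cls, path: str | Path) -> "Alphabet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            letters=list(payload["letters"]),
            coordinates=np.array(payload["coordinates"], dtype=float)
            if "coordinates" in payload
            else None,
            angles=np.array(payload["angles"], dtype=float) if "angles" in payload else None,
        )

    def to_json(self, path: str | Path, note: str = "") -> None:
        payload = {"letters": self.letters, "coordinates": self.coordinates.tolist()}
        if self.angles is not None:
            payload["angles"] = self.angles.tolist()
        if note:
            payload["note"] = note
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class StringAlignment:
    """Aligned structural strings: F frames × (n − 3) fragment columns."""

    fragments: list[Fragment]
    letters: np.ndarray  # F × n_fragments, unicode

    def __post_init__(self) -> None:
        self.letters = np.asarray(self.letters)
        if self.letters.ndim != 2 or self.letters.shape[1] != len(self.fragments):
            raise ValueError("letters must be F × n_fragments")

    @property
    def n_frames(self) -> int:
        return self.letters.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.letters.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.letters[:, j]

    def column_by_fragment(self, fragment_index: int) -> np.ndarray:
        for j, f in enumerate(self.fragments):
            if f.index == fragment_index:
                return self.letters[:, j]
        raise KeyError(f"no fragment f{fragment_index}")

    def to_text(self, path: str | Path) -> None:
        """One structural string per frame, fragment-index header first."""
        with open(path, "w") as fh:
            fh.write("# fragments: " + " ".join(f.name for f in self.fragments) + "\n")
            for row in self.letters:
                fh.write("".join(row) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "StringAlignment":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("# fragments:"):
            raise ValueError("missing fragment header")
        frags = [
            Fragment(index=int(tok[1:]))
            for tok in lines[0].split(":", 1)[1].split()
        ]
        rows = [list(l) for l in lines[1:] if l]
        letters = np.array(rows)
        return cls(fragments=frags, letters=letters)


def fragmentize(topology: Topology) -> list[Fragment]:
    """Overlapping 4-residue fragments per chain: n residues → n − 3 fragments.

    Fragments never span chain breaks; a chain with fewer than 4 residues
    is an error.
    """
    out: list[Fragment] = []
    for chain in topology.chains:
        residues = [r for r in topology.residues if r.chain == chain]
        if len(residues) < 4:
            raise ValueError(f"chain {chain!r} has {len(residues)} residues; need ≥ 4")
        for k in range(len(residues) - 3):
            out.append(Fragment(index=residues[k].index, chain_id=chain))
    return out


def _dihedral(p: np.ndarray) -> float:
    """IUPAC dihedral (degrees, cis = 0) of four points."""
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear triple: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    tau = -float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    return 180.0 if tau <= -180.0 else tau


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def fragment_descriptors(coords: np.ndarray) -> FragmentDescriptor:
    """Internal-angle descriptor (θ1, θ2, τ) of one 4-point Cα fragment."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (4, 3):
        raise ValueError("fragment coordinates must be 4 × 3")
    if len(np.unique(coords, axis=0)) < 4:
        raise ValueError("fragment points must be distinct")
    tau = _dihedral(coords)  # raises on collinear triples
    return FragmentDescriptor(
        theta1=_angle(coords[0], coords[1], coords[2]),
        theta2=_angle(coords[1], coords[2], coords[3]),
        tau=tau,
    )


def fragment_from_angles(
    theta1: float, theta2: float, tau: float, bond: float = CA_CA_BOND
) -> np.ndarray:
    """Build 4-point Cα coordinates realising a (θ1, θ2, τ) triple.

    Standard internal-to-Cartesian (NeRF) placement with all pseudo-bonds
    at *bond* Å.  Round-trips with :func:`fragment_descriptors`.
    """
    t1, t2, tr = np.radians([theta1, theta2, tau])
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([bond, 0.0, 0.0])
    p2 = p1 + bond * np.array([-np.cos(t1), np.sin(t1), 0.0])
    bc = p2 - p1
    bc /= np.linalg.norm(bc)
    n = np.cross(p1 - p0, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(t2), np.sin(t2) * np.cos(tr), np.sin(t2) * np.sin(tr)])
    p3 = p2 + d[0] * bc + d[1] * m + d[2] * n
    return np.stack([p0, p1, p2, p3])


# -- vectorised minimal-RMSD assignment --------------------------------------

def _pairwise_min_rmsd(obs: np.ndarray, canon: np.ndarray) -> np.ndarray:
    """RMSD after optimal proper superposition for every (observation, state).

    obs: N × 4 × 3, canon: L × 4 × 3 → N × L RMSD matrix, via the batched
    Kabsch closed form: rmsd² = (|P|² + |Q|² − 2(σ1 + σ2 ± σ3)) / 4 with the
    sign of σ3 flipped when det(H) < 0.
    """
    P = obs - obs.mean(axis=1, keepdims=True)            # N × 4 × 3
    Q = canon - canon.mean(axis=1, keepdims=True)        # L × 4 × 3
    p2 = np.einsum("nij,nij->n", P, P)                   # N
    q2 = np.einsum("lij,lij->l", Q, Q)                   # L
    H = np.einsum("nia,lib->nlab", P, Q)                 # N × L × 3 × 3
    s = np.linalg.svd(H, compute_uv=False)               # N × L × 3
    sign = np.sign(np.linalg.det(H))
    sign[sign == 0] = 1.0
    trace = s[..., 0] + s[..., 1] + sign * s[..., 2]
    msd = (p2[:, None] + q2[None, :] - 2.0 * trace) / 4.0
    return np.sqrt(np.maximum(msd, 0.0))


def _descriptor_array(obs: np.ndarray) -> np.ndarray:
    """Vectorised (θ1, θ2, τ) for N × 4 × 3 fragments (degrees)."""
    b1 = obs[:, 1] - obs[:, 0]
    b2 = obs[:, 2] - obs[:, 1]
    b3 = obs[:, 3] - obs[:, 2]

    def angle(u, v):
        cosang = np.einsum("ni,ni->n", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    theta1 = angle(-b1, b2)
    theta2 = angle(-b2, b3)
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    tau = -np.degrees(
        np.arctan2(np.einsum("ni,ni->n", m1, n2), np.einsum("ni,ni->n", n1, n2))
    )
    tau[tau <= -180.0] = 180.0
    return np.stack([theta1, theta2, tau], axis=1)


def _angular_distance(desc: np.ndarray, canon: np.ndarray) -> np.ndarray:
    """N × L distance in (θ1, θ2, τ) space; τ compared on the circle."""
    dth = desc[:, None, :2] - canon[None, :, :2]
    dtau = desc[:, None, 2] - canon[None, :, 2]
    dtau = (dtau + 180.0) % 360.0 - 180.0
    return np.sqrt(np.sum(dth**2, axis=2) + dtau**2)


class StructuralAlphabetEncoder(TransformerMixin, BaseEstimator):
    """Encode Cα trajectories as aligned structural strings.

    A stateless transformer (``fit`` only validates): each frame is encoded
    independently, so encoding a concatenation of trajectories equals the
    concatenation of encodings.

    Parameters
    ----------
    alphabet : Alphabet or None
        Canonical states; None loads the shipped 25-letter synthetic default.
    method : {"rmsd_local_fit", "descriptor_nearest"}
        Assignment rule.  ``rmsd_local_fit`` superposes every canonical
        state onto each observed fragment and takes the minimal-RMSD letter;
        ``descriptor_nearest`` is nearest neighbour in angle space.
        Ties break to the lowest letter index in both cases.
    """

    def __init__(self, alphabet: Optional[Alphabet] = None, method: str = "rmsd_local_fit"):
        self.alphabet = alphabet
        self.method = method

    def _resolved_alphabet(self) -> Alphabet:
        return self.alphabet if self.alphabet is not None else load_alphabet()

    def fit(self, X: Trajectory, y=None) -> "StructuralAlphabetEncoder":
        if self.method not in ("rmsd_local_fit", "descriptor_nearest"):
            raise ValueError(f"unknown method {self.method!r}")
        alphabet = self._resolved_alphabet()
        if self.method == "rmsd_local_fit" and alphabet.coordinates is None:
            raise ValueError("rmsd_local_fit requires canonical coordinates")
        self.alphabet_ = alphabet
        self.n_states_ = alphabet.n_states
        return self

    def transform(self, X: Trajectory) -> StringAlignment:
        if not hasattr(self, "alphabet_"):
            self.fit(X)
        traj = X
        top = traj.topology
        if top.n_atoms != top.n_residues:
            raise ValueError("trajectory must be Cα-only (use select_calpha first)")
        fragments = fragmentize(top)
        resid_pos = {r.index: k for k, r in enumerate(top.residues)}
        cols = np.array(
            [[resid_pos[i] for i in f.residue_indices] for f in fragments]
        )  # n_frag × 4
        F = traj.n_frames
        letters = np.array(self.alphabet_.letters)
        out = np.empty((F, len(fragments)), dtype=letters.dtype)
        coords = traj.coordinates
        for f in range(F):
            obs = coords[f][cols]  # n_frag × 4 × 3
            if self.method == "rmsd_local_fit":
                dist = _pairwise_min_rmsd(obs, self.alphabet_.coordinates)
            else:
                dist = _angular_distance(_descriptor_array(obs), self.alphabet_.angles)
            out[f] = letters[np.argmin(dist, axis=1)]  # argmin: lowest index on ties
        return StringAlignment(fragments=fragments, letters=out)


def assign_states(
    trajectory: Trajectory,
    alphabet: Optional[Alphabet] = None,
    method: str = "rmsd_local_fit",
) -> StringAlignment:
    """Functional form of :class:`StructuralAlphabetEncoder`."""
    return StructuralAlphabetEncoder(alphabet=alphabet, method=method).fit(
        trajectory
    ).transform(trajectory)


def load_alphabet(path: Optional[str | Path] = None) -> Alphabet:
    """Load an alphabet JSON; default is the shipped synthetic 25-state set."""
    if path is not None:
        return Alphabet.from_json(path)
    ref = resources.files("allopath") / "data" / "alphabet25_synthetic.json"
    with resources.as_file(ref) as p:
        return Alphabet.from_json(p)
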