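"""Trajectory and topology input.

Reads a PDB topology plus coordinate frames (DCD, XTC, or multi-model PDB)
into plain numpy containers, and provides the Cα-only view that the
structural-alphabet and geometry machinery consumes.  Residue numbering is
1-based and kept verbatim from the PDB so fragment names (f115 = residues
115–118) map directly onto author numbering.  Internal length unit is Å;
nm formats (XTC) are converted at the boundary by the reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "ResidueSelection",
    "read_topology",
    "read_frames",
    "select_calpha",
    "write_pdb",
    "write_frames",
]


@dataclass(frozen=True)
class Residue:
    index: int          # 1-based, as written in the PDB
    name: str           # 3-letter code
    chain: str


@dataclass(frozen=True)
class Atom:
    name: str
    residue_index: int  # refers to Residue.index


@dataclass
class Topology:
    """Ordered residues and atoms of one structure.

    Invariants: residue indices strictly increase within a chain; every
    atom maps to an existing residue.
    """

    residues: list[Residue]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        known = {r.index for r in self.residues}
        for a in self.atoms:
            if a.residue_index not in known:
                raise ValueError(f"atom {a.name} maps to unknown residue {a.residue_index}")
        by_chain: dict[str, int] = {}
        for r in self.residues:
            prev = by_chain.get(r.chain)
            if prev is not None and r.index <= prev:
                raise ValueError(
                    f"residue indices not strictly increasing in chain {r.chain!r}: "
                    f"{prev} then {r.index}"
                )
            by_chain[r.chain] = r.index

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Position (0-based) of the named atom of a residue in the atom list."""
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == atom_name:
                return i
        raise KeyError(f"residue {residue_index} has no atom {atom_name!r}")

    @property
    def ca_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.name == "CA"], dtype=int)


@dataclass
class Trajectory:
    """F × A × 3 coordinates in Å plus the topology they belong to."""

    coordinates: np.ndarray
    topology: Topology
    frame_times: Optional[np.ndarray] = None  # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be F × A × 3")
        if self.coordinates.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"atom count mismatch: topology has {self.topology.n_atoms}, "
                f"coordinates have {self.coordinates.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ResidueSelection:
    """A set of residues and the rule picking one atom from each."""

    residue_indices: Sequence[int]
    atom_rule: str = "calpha"  # "calpha" or any explicit atom name ("CG", ...)

    def atom_name(self) -> str:
        return "CA" if self.atom_rule == "calpha" else self.atom_rule


def read_topology(path: str | Path) -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Every residue must carry a CA atom; residues lacking one are reported
    in the raised error.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    residues: list[Residue] = []
    atoms: list[Atom] = []
    missing: list[str] = []
    for res in u.residues:
        chain = str(res.segid).strip() or "A"
        residues.append(Residue(index=int(res.resid), name=str(res.resname), chain=chain))
        names = [str(a.name) for a in res.atoms]
        if "CA" not in names:
            missing.append(f"{res.resname}{res.resid}")
        for n in names:
            atoms.append(Atom(name=n, residue_index=int(res.resid)))
    if missing:
        raise ValueError(f"residues without CA atom: {', '.join(missing)}")
    return Topology(residues=residues, atoms=atoms)


def read_frames(topology: Topology, path: str | Path, format: Optional[str] = None) -> Trajectory:
    """Read coordinate frames for a known topology.

    Supported formats: ``dcd``, ``xtc``, ``multi_model_pdb`` (inferred from
    the suffix when *format* is None).  Coordinates come back in Å — the
    MDAnalysis readers convert nm-based formats.
    """
    path = Path(path)
    if format is None:
        format = {".dcd": "dcd", ".xtc": "xtc", ".pdb": "multi_model_pdb"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer trajectory format from {path.name!r}")
    readers = {
        "dcd": mda.coordinates.DCD.DCDReader,
        "xtc": mda.coordinates.XTC.XTCReader,
        "multi_model_pdb": mda.coordinates.PDB.PDBReader,
    }
    if format not in readers:
        raise ValueError(f"unsupported trajectory format {format!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = readers[format](str(path))
        frames = [np.array(ts.positions, dtype=float) for ts in reader]
        reader.close()
    coords = np.stack(frames, axis=0)
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: expected {topology.n_atoms} from topology, "
            f"found {coords.shape[1]} in {path.name}"
        )
    return Trajectory(coordinates=coords, topology=topology)


def select_calpha(trajectory: Trajectory) -> Trajectory:
    """Restrict a trajectory to the CA atom of each residue (idempotent)."""
    top = trajectory.topology
    idx = top.ca_indices
    if len(idx) != top.n_residues:
        raise ValueError("not every residue has a CA atom")
    if len(idx) == top.n_atoms:
        return trajectory
    new_top = Topology(residues=list(top.residues), atoms=[top.atoms[i] for i in idx])
    return Trajectory(
        coordinates=trajectory.coordinates[:, idx, :],
        topology=new_top,
        frame_times=trajectory.frame_times,
    )


def select_atoms(trajectory: Trajectory, selection: ResidueSelection) -> tuple[np.ndarray, list[int]]:
    """Per-frame coordinates (F × k × 3) of one named atom per selected residue."""
    name = selection.atom_name()
    idx = [trajectory.topology.atom_index(r, name) for r in selection.residue_indices]
    return trajectory.coordinates[:, idx, :], list(selection.residue_indices)


# -- writers (round-trip fixtures and the `convert` CLI verb) ----------------

def _as_universe(topology: Topology, coords: np.ndarray) -> "mda.Universe":
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_atoms = topology.n_atoms
    resids = sorted({a.residue_index for a in topology.atoms})
    resid_of = {r: i for i, r in enumerate(resids)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms,
            n_residues=len(resids),
            atom_resindex=[resid_of[a.residue_index] for a in topology.atoms],
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in topology.atoms])
        u.add_TopologyAttr("resids", resids)
        names = {r.index: r.name for r in topology.residues}
        chains = {r.index: r.chain for r in topology.residues}
        u.add_TopologyAttr("resnames", [names.get(r, "GLY") for r in resids])
        u.add_TopologyAttr("segids", ["SYS"])
        u.add_TopologyAttr("chainIDs", [chains.get(a.residue_index, "A") for a in topology.atoms])
        u.add_TopologyAttr("elements", [(a.name[:1] or "C") for a in topology.atoms])
        u.load_new(coords.astype(np.float32), format=MemoryReader)
    return u


def write_pdb(path: str | Path, topology: Topology, coords: np.ndarray) -> None:
    """Write one frame (or all frames, as MODEL blocks) to a PDB file."""
    u = _as_universe(topology, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=u.trajectory.n_frames > 1) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_frames(path: str | Path, topology: Topology, coords: np.ndarray) -> None:
    """Write an F × A × 3 Å coordinate array to DCD or XTC (by suffix)."""
    u = _as_universe(topology, coords)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
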