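"""Trajectory geometry statistics.

Rigid-body superposition, per-residue RMSF, residue-pair distance time
series, and 2D occupancy density maps — the descriptive statistics used to
characterise the open/closed interconversion of a binding site (e.g. the
Ca²⁺-gating residue pair whose closed conformation sits near 15 Å and the
open conformation near 20 Å).

RMSF follows the two-pass convention: superpose every frame onto frame 0,
take the time-mean structure, re-superpose onto that mean, then measure
fluctuations about the mean.  All lengths are Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .io import ResidueSelection, Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "RmsfProfile",
    "DistanceSeries",
    "DensityMap2D",
    "kabsch",
    "superpose",
    "rmsf",
    "pair_distance_series",
    "density_map_2d",
]


@dataclass
class SuperpositionResult:
    aligned: Trajectory
    per_frame_rmsd: np.ndarray  # Å, length F


@dataclass
class RmsfProfile:
    residue_indices: list[int]
    rmsf: np.ndarray  # Å

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"residue": self.residue_indices, "rmsf_angstrom": self.rmsf})


@dataclass
class DistanceSeries:
    pair: tuple[int, int, str]  # residue_i, residue_j, atom_rule
    values: np.ndarray  # Å, length F


@dataclass
class DensityMap2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy: np.ndarray  # percent per cell; sums to 100

    # rendering saturates at this occupancy (percent); matches the common
    # publication convention of clipping the colour scale at ~21%
    saturation: float = 21.0

    def to_png(self, path, cmap: str = "nipy_spectral") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        shown = np.clip(self.occupancy.T, 0.0, self.saturation)
        ax.pcolormesh(self.x_edges, self.y_edges, shown, cmap=cmap, vmin=0.1, vmax=self.saturation)
        ax.set_xlabel("distance x (Å)")
        ax.set_ylabel("distance y (Å)")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimising
    ||(mobile @ R.T + t) - reference||, plus the resulting RMSD.

    Uses the SVD solution with the determinant correction so R is always a
    proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - cm, reference - cr
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Q) ** 2, axis=1))))
    t = cr - cm @ R.T
    return R, t, rmsd


def _check_nondegenerate(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    centered = ref - ref.mean(axis=0)
    # rank < 2 means all points collinear: rotation about the line is free
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("reference coordinates are collinear or degenerate")


def superpose(
    trajectory: Trajectory,
    reference: Union[int, np.ndarray] = 0,
) -> SuperpositionResult:
    """Least-squares superpose every frame onto a reference.

    *reference* is a frame index or an explicit A × 3 coordinate array.
    Each frame is moved by a proper rigid transform (rotation determinant
    +1), so all intra-frame distances are preserved exactly.
    """
    coords = trajectory.coordinates
    ref = coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, float)
    if ref.shape != coords.shape[1:]:
        raise ValueError("reference shape does not match trajectory atoms")
    _check_nondegenerate(ref)
    out = np.empty_like(coords)
    rmsds = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        R, t, rmsd = kabsch(coords[f], ref)
        out[f] = coords[f] @ R.T + t
        rmsds[f] = rmsd
    aligned = Trajectory(coordinates=out, topology=trajectory.topology,
                         frame_times=trajectory.frame_times)
    return SuperpositionResult(aligned=aligned, per_frame_rmsd=rmsds)


def rmsf(
    trajectory: Trajectory,
    selection: Optional[ResidueSelection] = None,
    auto_superpose: bool = True,
) -> RmsfProfile:
    """Root mean square fluctuation about the time-mean position.

    rmsf_i = sqrt(mean_f |x_i(f) − <x_i>|²), computed after the two-pass
    superposition unless *auto_superpose* is disabled (for trajectories
    already aligned).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    work = trajectory
    if auto_superpose:
        first = superpose(work, 0)
        mean = first.aligned.coordinates.mean(axis=0)
        work = superpose(first.aligned, mean).aligned
    if selection is None:
        residues = [r.index for r in trajectory.topology.residues]
        selection = ResidueSelection(residue_indices=residues)
    coords, residues = select_atoms(work, selection)
    mean = coords.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    return RmsfProfile(residue_indices=residues, rmsf=fluct)


def pair_distance_series(
    trajectory: Trajectory,
    residue_i: int,
    residue_j: int,
    atom_rule: str = "calpha",
) -> DistanceSeries:
    """Per-frame Euclidean distance between one atom of each residue."""
    sel = ResidueSelection(residue_indices=[residue_i, residue_j], atom_rule=atom_rule)
    coords, _ = select_atoms(trajectory, sel)
    d = np.linalg.norm(coords[:, 0, :] - coords[:, 1, :], axis=1)
    return DistanceSeries(pair=(residue_i, residue_j, atom_rule), values=d)


def density_map_2d(
    series_x: DistanceSeries,
    series_y: DistanceSeries,
    bin_width: float = 0.25,
    saturation: float = 21.0,
) -> DensityMap2D:
    """2D occupancy map of two distance series, in percent of frames per cell."""
    x, y = np.asarray(series_x.values), np.asarray(series_y.values)
    if len(x) != len(y):
        raise ValueError("distance series have different lengths")
    if len(x) == 0:
        raise ValueError("no frames")
    def edges(v):
        lo = np.floor(v.min() / bin_width) * bin_width
        hi = np.ceil(v.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        return np.arange(lo, hi + bin_width / 2, bin_width)
    counts, xe, ye = np.histogram2d(x, y, bins=[edges(x), edges(y)])
    return DensityMap2D(x_edges=xe, y_edges=ye, occupancy=100.0 * counts / len(x),
                        saturation=saturation)
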