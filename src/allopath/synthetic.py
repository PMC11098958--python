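"""Synthetic inputs with known ground truth for every pipeline stage.

These generators are statistical stand-ins, not physical models: a planted
chain of coupled fragment-state columns (to exercise the MI network and
path recovery), a two-state polymer whose probe residue pair interconverts
between ~15 Å (closed) and ~20 Å (open) distances, Poisson photon-count
exponential decays at 16 ps binning, and Hill-shaped FRET titrations with
Gaussian noise.  Every generator is bit-reproducible for a fixed seed and
can write a JSON ground-truth sidecar next to its fixture files.

Default parameter values state the emulated world: donor lifetime 3.52 ns,
16 ps TCSPC bins, binding constants spanning ~0.3–2 µM across four
conditions (no nucleotide / +nucleotide / +nucleotide+inhibitor /
+nucleotide+phosphomimetic), 15 Å / 20 Å closed/open probe distances, and
a 30 Å-compatible planted-chain geometry (consecutive chain fragments
25 Å apart, off-chain fragments 40 Å away).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .alphabet import Fragment, StringAlignment
from .fret import DecayHistogram, HillParams, hill_curve
from .io import Atom, Residue, Topology, Trajectory, write_frames, write_pdb

__all__ = [
    "PlantedChainSpec",
    "TwoStatePolymerSpec",
    "DecaySpec",
    "TitrationSpec",
    "gen_coupled_state_chain",
    "gen_two_state_polymer",
    "gen_decay",
    "gen_titration",
    "default_titration_spec",
    "write_chain_fixture",
    "write_polymer_fixture",
    "write_decay_fixture",
    "write_titration_fixture",
]

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXY"


# -- planted coupled chain ----------------------------------------------------

@dataclass
class PlantedChainSpec:
    """A chain of fragments copying conformational states downstream.

    The root fragment toggles between two letters with probability
    *flip_p* per frame; each subsequent chain fragment copies its upstream
    neighbour's state with probability *coupling* (γ), else draws
    uniformly from the alphabet; off-chain fragments are independent
    uniform noise.  Chain fragments sit 25 Å apart on a line (inside the
    30 Å gate only for consecutive pairs); off-chain fragments sit on a
    parallel line *offchain_offset* away.
    """

    n_fragments: int = 12
    chain: tuple = tuple(range(7))
    coupling: float = 0.9          # γ
    alphabet_size: int = 2
    n_frames: int = 2000           # T
    flip_p: float = 0.5
    chain_spacing: float = 25.0    # Å
    offchain_offset: float = 40.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must be in [0, 1]")
        if not set(self.chain) <= set(range(self.n_fragments)):
            raise ValueError("chain must be a subset of the fragments")
        if len(self.chain) < 2:
            raise ValueError("chain needs at least 2 fragments")
        if self.alphabet_size < 2 or self.alphabet_size > len(_LETTERS):
            raise ValueError("alphabet size must be in [2, 25]")


def gen_coupled_state_chain(
    spec: PlantedChainSpec,
) -> tuple[StringAlignment, np.ndarray, dict]:
    """Generate (alignment, fragment coordinates, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    T, n = spec.n_frames, spec.n_fragments
    letters = np.array(list(_LETTERS[: spec.alphabet_size]))
    states = np.empty((T, n), dtype=int)

    # off-chain fragments: independent uniform
    off = [j for j in range(n) if j not in spec.chain]
    for j in off:
        states[:, j] = rng.integers(0, spec.alphabet_size, size=T)

    # root: two-letter toggle
    root = spec.chain[0]
    flips = rng.random(T) < spec.flip_p
    seq = np.cumsum(flips) % 2
    states[:, root] = seq

    # downstream: copy upstream with probability γ, else uniform
    for up, down in zip(spec.chain[:-1], spec.chain[1:]):
        copy = rng.random(T) < spec.coupling
        noise = rng.integers(0, spec.alphabet_size, size=T)
        states[:, down] = np.where(copy, states[:, up], noise)

    coords = np.zeros((n, 3))
    for pos, j in enumerate(spec.chain):
        coords[j] = (pos * spec.chain_spacing, 0.0, 0.0)
    for pos, j in enumerate(off):
        coords[j] = (pos * spec.chain_spacing, spec.offchain_offset, 0.0)

    alignment = StringAlignment(
        fragments=[Fragment(index=j) for j in range(n)],
        letters=letters[states],
    )
    truth = {
        "chain": list(spec.chain),
        "coupling": spec.coupling,
        "alphabet_size": spec.alphabet_size,
        "n_frames": T,
        "flip_p": spec.flip_p,
        "seed": spec.seed,
    }
    return alignment, coords, truth


# -- two-state polymer --------------------------------------------------------

@dataclass
class TwoStatePolymerSpec:
    """Hinged Cα polymer interconverting between closed/open conformers.

    Residues ≥ *hinge_residue* (1-based) rigidly rotate about the hinge;
    the rotation angles are solved so the probe residue pair hits the
    closed/open target distances exactly.  State switching is a symmetric
    two-state Markov chain with per-frame switch probability *switch_p*;
    isotropic Gaussian jitter of *jitter_sigma* Å per axis is added on top.
    """

    n_residues: int = 100
    hinge_residue: int = 85
    probe_pair: tuple = (80, 90)     # 1-based residue indices
    closed_distance: float = 15.0    # Å
    open_distance: float = 20.0      # Å
    switch_p: float = 0.1
    jitter_sigma: float = 0.3        # Å per axis
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.switch_p < 1.0):
            raise ValueError("switch probability must be in (0, 1)")
        if not (4 < self.hinge_residue <= self.n_residues - 3):
            raise ValueError("hinge must leave ≥ 4 residues on each side")
        i, j = self.probe_pair
        if not (1 <= i < self.hinge_residue <= j <= self.n_residues):
            raise ValueError("probe pair must straddle the hinge")


def _zigzag(n: int) -> np.ndarray:
    """Planar zigzag Cα backbone, 3.8 Å bonds, non-collinear triples."""
    k = np.arange(n)
    return np.column_stack([3.3 * k, 1.9 * (k % 2), np.zeros(n)])


def _rotate_arm(base: np.ndarray, hinge0: int, alpha: float) -> np.ndarray:
    """Rotate residues with 0-based index ≥ hinge0 about z through hinge0−1."""
    out = base.copy()
    pivot = base[hinge0 - 1]
    c, s = np.cos(alpha), np.sin(alpha)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    out[hinge0:] = (base[hinge0:] - pivot) @ R.T + pivot
    return out


def _conformer_for_distance(spec: TwoStatePolymerSpec, target: float) -> np.ndarray:
    base = _zigzag(spec.n_residues)
    h0 = spec.hinge_residue - 1
    i0, j0 = spec.probe_pair[0] - 1, spec.probe_pair[1] - 1

    def gap(alpha):
        conf = _rotate_arm(base, h0, alpha)
        return float(np.linalg.norm(conf[i0] - conf[j0])) - target

    alphas = np.linspace(0.0, np.pi, 721)
    vals = [gap(a) for a in alphas]
    for a0, a1, v0, v1 in zip(alphas[:-1], alphas[1:], vals[:-1], vals[1:]):
        if v0 == 0.0 or v0 * v1 < 0:
            alpha = a0 if v0 == 0.0 else brentq(gap, a0, a1, xtol=1e-12)
            conf = _rotate_arm(base, h0, alpha)
            bonds = np.linalg.norm(np.diff(conf, axis=0), axis=1)
            if bonds.min() < 1.0:
                raise ValueError("conformer has clashing consecutive Cα atoms")
            return conf
    raise ValueError(f"target distance {target} Å unreachable for this geometry")


def gen_two_state_polymer(spec: TwoStatePolymerSpec) -> tuple[Trajectory, np.ndarray, dict]:
    """Generate (trajectory, per-frame state labels, ground truth).

    Labels: 0 = closed (short probe distance), 1 = open.
    """
    closed = _conformer_for_distance(spec, spec.closed_distance)
    opened = _conformer_for_distance(spec, spec.open_distance)
    rng = np.random.default_rng(spec.seed)
    labels = np.empty(spec.n_frames, dtype=int)
    labels[0] = rng.integers(0, 2)
    switches = rng.random(spec.n_frames - 1) < spec.switch_p
    for t in range(1, spec.n_frames):
        labels[t] = labels[t - 1] ^ int(switches[t - 1])
    conformers = np.stack([closed, opened])
    coords = conformers[labels] + rng.normal(
        0.0, spec.jitter_sigma, size=(spec.n_frames, spec.n_residues, 3)
    )
    topology = Topology(
        residues=[Residue(index=k + 1, name="GLY", chain="A") for k in range(spec.n_residues)],
        atoms=[Atom(name="CA", residue_index=k + 1) for k in range(spec.n_residues)],
    )
    traj = Trajectory(coordinates=coords, topology=topology)
    truth = {
        "probe_pair": list(spec.probe_pair),
        "closed_distance": spec.closed_distance,
        "open_distance": spec.open_distance,
        "switch_p": spec.switch_p,
        "jitter_sigma": spec.jitter_sigma,
        "hinge_residue": spec.hinge_residue,
        # residues with an appreciable lever arm about the hinge (the first few
        # rotating residues barely move and are excluded)
        "switch_region": list(range(spec.hinge_residue + 5, spec.n_residues + 1)),
        "seed": spec.seed,
        "labels_mean": float(labels.mean()),
    }
    return traj, labels, truth


# -- photon decays ------------------------------------------------------------

@dataclass
class DecaySpec:
    """Poisson biexponential photon-count decay, TCSPC-style."""

    components: tuple = ((0.6, 3.5), (0.4, 1.5))  # (amplitude, τ ns)
    total_photons: float = 1e6
    bin_width_ps: float = 16.0
    window_ns: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        amps = [a for a, _ in self.components]
        if any(a < 0 for a in amps) or sum(amps) <= 0:
            raise ValueError("amplitudes must be non-negative with positive sum")
        if any(tau <= 0 for _, tau in self.components):
            raise ValueError("lifetimes must be positive")


def gen_decay(spec: DecaySpec) -> DecayHistogram:
    """Per-bin Poisson draws around Σ a_k·exp(−t/τ_k), scaled to the photon budget."""
    max_tau = max(tau for _, tau in spec.components)
    if spec.window_ns < 3.0 * max_tau:
        import warnings

        warnings.warn(
            f"window {spec.window_ns} ns < 3×max τ ({max_tau} ns): truncated decay",
            stacklevel=2,
        )
    n_bins = int(round(spec.window_ns * 1e3 / spec.bin_width_ps))
    t = (np.arange(n_bins) + 0.5) * spec.bin_width_ps * 1e-3
    lam = np.zeros(n_bins)
    for a, tau in spec.components:
        lam += a * np.exp(-t / tau)
    lam *= spec.total_photons / lam.sum()
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(lam)
    return DecayHistogram(counts=counts, bin_width_ps=spec.bin_width_ps)


# -- titrations ---------------------------------------------------------------

@dataclass
class TitrationSpec:
    """Hill-shaped titration tables with Gaussian FRET noise."""

    conditions: dict = None          # name -> HillParams
    x: np.ndarray = None             # molar, log-spaced
    noise_sd: float = 0.5            # FRET %
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conditions is None:
            self.conditions = default_titration_spec()
        if self.x is None:
            self.x = np.logspace(-8, -4, 12)
        self.x = np.asarray(self.x, dtype=float)
        if np.any(self.x <= 0):
            raise ValueError("concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def default_titration_spec() -> dict:
    """Four-condition design emulating the study: shared n = 1, K spanning 0.3–2 µM."""
    return {
        "apo": HillParams(start=13.6, end=18.0, n=1.0, K=1.8e-6),
        "nucleotide": HillParams(start=15.6, end=18.0, n=1.0, K=332e-9),
        "nucleotide+inhibitor": HillParams(start=14.5, end=18.0, n=1.0, K=702e-9),
        "nucleotide+phosphomimetic": HillParams(start=15.6, end=18.0, n=1.0, K=334e-9),
    }


def gen_titration(spec: TitrationSpec) -> pd.DataFrame:
    """Tidy table: condition, x (molar), replicate, y (FRET %)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond, params in spec.conditions.items():
        clean = hill_curve(params, spec.x)
        for rep in range(spec.replicates):
            noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(spec.x))
            for xv, yv in zip(spec.x, noisy):
                rows.append({"condition": cond, "x": xv, "replicate": rep, "y": yv})
    return pd.DataFrame(rows)


# -- fixture writers ----------------------------------------------------------

def _sidecar(path: Path, truth: dict) -> None:
    path.write_text(json.dumps(truth, indent=1, sort_keys=True))


def write_chain_fixture(spec: PlantedChainSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignment, coords, truth = gen_coupled_state_chain(spec)
    alignment.to_text(outdir / "strings.txt")
    pd.DataFrame(coords, columns=["x", "y", "z"]).to_csv(outdir / "coords.csv", index=False)
    _sidecar(outdir / "truth.json", truth)
    return truth


def write_polymer_fixture(spec: TwoStatePolymerSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, labels, truth = gen_two_state_polymer(spec)
    write_pdb(outdir / "topology.pdb", traj.topology, traj.coordinates[0])
    write_frames(outdir / "trajectory.dcd", traj.topology, traj.coordinates)
    truth = dict(truth, labels=labels.tolist())
    _sidecar(outdir / "truth.json", truth)
    return truth


def write_decay_fixture(spec: DecaySpec, outdir: str | Path, name: str = "decay") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hist = gen_decay(spec)
    hist.to_text(outdir / f"{name}.txt")
    truth = {
        "components": [list(c) for c in spec.components],
        "total_photons": spec.total_photons,
        "bin_width_ps": spec.bin_width_ps,
        "window_ns": spec.window_ns,
        "seed": spec.seed,
    }
    _sidecar(outdir / f"{name}.truth.json", truth)
    return truth


def write_titration_fixture(spec: TitrationSpec, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = gen_titration(spec)
    out = df.rename(columns={"x": "ca_free_molar", "y": "fret_percent"})
    out.to_csv(outdir / "titration.csv", index=False)
    truth = {
        "conditions": {
            c: {"start": p.start, "end": p.end, "n": p.n, "K": p.K}
            for c, p in spec.conditions.items()
        },
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
        "seed": spec.seed,
    }
    _sidecar(outdir / "truth.json", truth)
    return truth
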