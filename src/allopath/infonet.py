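"""Mutual-information coupling networks and allosteric paths.

The central model: local conformational transitions of 4-residue fragments,
encoded as letter columns of a structural-string alignment, exchange
information; the normalized mutual information between two fragment columns
C_i, C_j is

    I_LLn(C_i; C_j) = (I(C_i; C_j) − ε(C_i; C_j)) / H(C_i, C_j)

with I the plug-in mutual information, H the joint entropy, and ε a
first-order finite-size bias correction (Roulston-style),

    ε = (B_ij − B_i − B_j + 1) / (2T)   [nats],

B_* the numbers of occupied joint/marginal histogram cells and T the frame
count.  I_LLn is clamped to [0, 1] and defined as 0 when the joint entropy
vanishes (constant columns).  Being a ratio, I_LLn is invariant to the
logarithm base; all entropies here are computed in nats.

Fragments become nodes of an undirected network (node position = the
time-averaged first Cα of the fragment); fragment pairs within a distance
cutoff (default 30 Å) whose I_LLn reaches a cutoff (default 33% of the
maximum off-diagonal I_LLn) are joined by an edge of weight

    w_ij = 1 − I_LLn(C_i; C_j),

so strong coupling = low traversal cost.  Allosteric paths between two
binding-site fragment sets are minimum-total-weight paths over all site
pair combinations (Dijkstra; ties broken by fewer edges, then
lexicographically smallest fragment sequence).  Node importance is the
eigenvector centrality of the strength-weighted adjacency (strength =
I_LLn), by power iteration.  A fragment's coupling to the protein's global
collective motion, I_LGn, applies the identical normalized-MI formula to
the fragment column versus a discretized series of global-motion states
(first principal component of the Cα coordinates, equal-frequency bins).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .alphabet import StringAlignment
from .io import Trajectory

__all__ = [
    "MIResult",
    "MINetwork",
    "AllostericPath",
    "CentralityScores",
    "GlobalStateSeries",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "finite_size_correction",
    "normalized_mi",
    "illn_matrix",
    "build_network",
    "shortest_allosteric_path",
    "eigenvector_centrality",
    "global_motion_states",
    "ilgn",
    "AllostericNetwork",
]


# -- information measures -----------------------------------------------------

def _codes(column: Sequence) -> np.ndarray:
    """Integer codes of a symbol column."""
    _, codes = np.unique(np.asarray(column), return_inverse=True)
    return codes


def _entropy_from_counts(counts: np.ndarray) -> float:
    T = counts.sum()
    p = counts[counts > 0] / T
    return float(-np.sum(p * np.log(p)))


def entropy(column: Sequence) -> float:
    """Plug-in (maximum-likelihood) entropy of one column, nats."""
    _, counts = np.unique(np.asarray(column), return_counts=True)
    return _entropy_from_counts(counts)


def _joint_counts(ci: Sequence, cj: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b = _codes(ci), _codes(cj)
    if len(a) != len(b):
        raise ValueError(f"column length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("columns need at least 2 observations")
    ka = int(a.max()) + 1
    joint = np.bincount(a * (int(b.max()) + 1) + b)
    return joint[joint > 0], np.bincount(a), np.bincount(b)


def joint_entropy(column_i: Sequence, column_j: Sequence) -> float:
    """Plug-in joint entropy H(C_i, C_j) of the empirical joint distribution, nats."""
    joint, _, _ = _joint_counts(column_i, column_j)
    return _entropy_from_counts(joint)


def mutual_information(column_i: Sequence, column_j: Sequence) -> float:
    """Plug-in mutual information I = H_i + H_j − H_ij, nats (symmetric, ≥ 0)."""
    joint, ca, cb = _joint_counts(column_i, column_j)
    return (
        _entropy_from_counts(ca)
        + _entropy_from_counts(cb)
        - _entropy_from_counts(joint)
    )


def finite_size_correction(column_i: Sequence, column_j: Sequence) -> float:
    """First-order finite-size bias term ε = (B_ij − B_i − B_j + 1)/(2T), nats.

    B_* count occupied joint and marginal histogram cells; the result is
    floored at 0 (it can only go negative for near-deterministic columns,
    where the plug-in bias is negligible anyway).
    """
    joint, ca, cb = _joint_counts(column_i, column_j)
    T = int(ca.sum())
    b_ij = int(np.count_nonzero(joint))
    b_i = int(np.count_nonzero(ca))
    b_j = int(np.count_nonzero(cb))
    return max(0.0, (b_ij - b_i - b_j + 1) / (2.0 * T))


@dataclass(frozen=True)
class MIResult:
    """Mutual information of one column pair with its normalization pieces."""

    I: float          # plug-in MI, nats
    H_joint: float    # joint entropy, nats
    epsilon: float    # finite-size bias term, nats (≥ 0)
    illn: float       # clamp((I − ε)/H_joint, 0, 1); 0 if H_joint = 0

    @property
    def I_bits(self) -> float:
        return self.I / np.log(2.0)


def normalized_mi(column_i: Sequence, column_j: Sequence) -> MIResult:
    """Normalized mutual information I_LLn = clamp((I − ε)/H_ij, 0, 1)."""
    joint, ca, cb = _joint_counts(column_i, column_j)
    h_i = _entropy_from_counts(ca)
    h_j = _entropy_from_counts(cb)
    h_ij = _entropy_from_counts(joint)
    I = h_i + h_j - h_ij
    T = int(ca.sum())
    eps = max(0.0, (len(joint) - np.count_nonzero(ca) - np.count_nonzero(cb) + 1) / (2.0 * T))
    if h_ij <= 0.0:
        illn = 0.0
    else:
        illn = min(1.0, max(0.0, (I - eps) / h_ij))
    return MIResult(I=I, H_joint=h_ij, epsilon=eps, illn=illn)


def illn_matrix(alignment: StringAlignment) -> np.ndarray:
    """Symmetric matrix of pairwise I_LLn over all fragment columns.

    The diagonal is set to 1 for non-constant columns (self-information) and
    0 for constant ones; cutoff statistics downstream use off-diagonal
    entries only.
    """
    n = alignment.n_fragments
    cols = [_codes(alignment.column(j)) for j in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        out[i, i] = 1.0 if len(np.unique(cols[i])) > 1 else 0.0
        for j in range(i + 1, n):
            v = normalized_mi(cols[i], cols[j]).illn
            out[i, j] = out[j, i] = v
    return out


# -- network ------------------------------------------------------------------

@dataclass
class MINetwork:
    """Fragment coupling network: nodes = fragments, w = 1 − I_LLn."""

    graph: nx.Graph                # node labels = fragment indices
    fragment_ids: list[int]
    node_coords: np.ndarray        # n × 3, Å (first-Cα representative positions)
    illn: np.ndarray               # n × n
    d_cut: float
    mi_cut: float
    mi_frac: Optional[float] = None

    @property
    def is_empty(self) -> bool:
        return self.graph.number_of_edges() == 0

    def edge_table(self):
        import pandas as pd

        rows = [
            {
                "i": i,
                "j": j,
                "illn": d["illn"],
                "weight": d["weight"],
                "distance": d["distance"],
            }
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["i", "j", "illn", "weight", "distance"])

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, x=float(d["coord"][0]), y=float(d["coord"][1]), z=float(d["coord"][2]))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=d["weight"], illn=d["illn"], distance=d["distance"])
        nx.write_graphml(g, path)


@dataclass
class AllostericPath:
    fragments: list[int]     # ordered fragment indices, site A end first
    total_weight: float
    edge_illn: list[float]


@dataclass
class CentralityScores:
    nodes: list[int]
    scores: np.ndarray       # normalized to max = 1
    percentile: np.ndarray   # percentile rank per node, 0–100

    def top_nodes(self, k_percent: float = 12.0) -> list[int]:
        """Nodes in the top k% of centrality scores (default 12%)."""
        cut = 100.0 - k_percent
        return [n for n, p in zip(self.nodes, self.percentile) if p >= cut]


def build_network(
    illn: np.ndarray,
    node_coords: np.ndarray,
    d_cut: float = 30.0,
    mi_frac: float = 0.33,
    mi_abs: Optional[float] = None,
    fragment_ids: Optional[Sequence[int]] = None,
) -> MINetwork:
    """Gate the I_LLn matrix into an undirected weighted network.

    An edge (i, j) exists iff the representative first-Cα distance is
    ≤ *d_cut* and I_LLn(i, j) ≥ the MI cutoff; the cutoff is *mi_abs* when
    given, else *mi_frac* × the maximum off-diagonal I_LLn.  Edge weight is
    1 − I_LLn.  An all-zero matrix yields a valid, empty-edged network.
    """
    illn = np.asarray(illn, dtype=float)
    n = illn.shape[0]
    if illn.shape != (n, n) or not np.allclose(illn, illn.T, atol=1e-12):
        raise ValueError("I_LLn matrix must be square and symmetric")
    node_coords = np.asarray(node_coords, dtype=float)
    if node_coords.shape != (n, 3):
        raise ValueError("need one 3D coordinate per node")
    ids = list(fragment_ids) if fragment_ids is not None else list(range(n))
    off = illn[~np.eye(n, dtype=bool)]
    mi_cut = float(mi_abs) if mi_abs is not None else float(mi_frac * off.max(initial=0.0))
    g = nx.Graph()
    for k, fid in enumerate(ids):
        g.add_node(fid, coord=node_coords[k])
    dist = np.linalg.norm(node_coords[:, None, :] - node_coords[None, :, :], axis=2)
    for a in range(n):
        for b in range(a + 1, n):
            if dist[a, b] <= d_cut and illn[a, b] >= mi_cut and illn[a, b] > 0.0:
                g.add_edge(
                    ids[a],
                    ids[b],
                    weight=1.0 - illn[a, b],
                    illn=float(illn[a, b]),
                    distance=float(dist[a, b]),
                )
    return MINetwork(
        graph=g,
        fragment_ids=ids,
        node_coords=node_coords,
        illn=illn,
        d_cut=float(d_cut),
        mi_cut=mi_cut,
        mi_frac=None if mi_abs is not None else float(mi_frac),
    )


def _dijkstra_best(graph: nx.Graph, source) -> dict:
    """Label-setting Dijkstra with deterministic tie-breaks.

    The label is the tuple (total weight, edge count, path); tuple order
    implements the contract: minimal weight, then fewest edges, then
    lexicographically smallest fragment sequence.
    """
    best: dict = {}
    heap = [(0.0, 0, (source,))]
    done = set()
    while heap:
        w, ne, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        best[node] = (w, ne, path)
        for nb, data in sorted(graph[node].items()):
            if nb in done:
                continue
            cand = (w + data["weight"], ne + 1, path + (nb,))
            heapq.heappush(heap, cand)
    return best


def shortest_allosteric_path(
    network: MINetwork,
    site_a: Sequence[int],
    site_b: Sequence[int],
) -> Optional[AllostericPath]:
    """Minimum-weight path over all (a ∈ site A, b ∈ site B) combinations.

    Returns None ("no path") when the two sites lie in different
    components — the outcome the network analysis reports for uncoupled
    binding sites.
    """
    if not site_a or not site_b:
        raise ValueError("site sets must be nonempty")
    for s in list(site_a) + list(site_b):
        if s not in network.graph:
            raise KeyError(f"site fragment f{s} is not a network node")
    candidates = []
    for a in sorted(site_a):
        best = _dijkstra_best(network.graph, a)
        for b in sorted(site_b):
            if b in best:
                candidates.append(best[b])
    if not candidates:
        return None
    w, ne, path = min(candidates)
    illn = [network.graph[u][v]["illn"] for u, v in zip(path[:-1], path[1:])]
    return AllostericPath(fragments=list(path), total_weight=w, edge_illn=illn)


def eigenvector_centrality(
    network: MINetwork,
    edge_strength: str = "illn",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> CentralityScores:
    """Principal-eigenvector node importance on the strength-weighted adjacency.

    Strength is I_LLn (high information exchange = strong tie) or 1 for
    ``unweighted``.  Power iteration with a unit diagonal shift (which
    leaves eigenvectors unchanged but guarantees convergence on bipartite
    structures); scores are normalized to max = 1 and reported with
    percentile ranks.
    """
    if edge_strength not in ("illn", "unweighted"):
        raise ValueError(f"unknown edge_strength {edge_strength!r}")
    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    pos = {v: k for k, v in enumerate(nodes)}
    S = np.zeros((n, n))
    for u, v, d in network.graph.edges(data=True):
        s = d["illn"] if edge_strength == "illn" else 1.0
        S[pos[u], pos[v]] = S[pos[v], pos[u]] = s
    if not S.any():
        scores = np.zeros(n)
    else:
        v = np.full(n, 1.0 / np.sqrt(n))
        shift = float(S.max())  # scale-matched: keeps the spectral gap relative
        residual = np.inf
        for _ in range(max_iter):
            nxt = S @ v + shift * v
            nxt /= np.linalg.norm(nxt)
            residual = float(np.max(np.abs(nxt - v)))
            v = nxt
            if residual < tol:
                break
        else:
            raise RuntimeError(f"power iteration did not converge (residual {residual:.2e})")
        scores = np.abs(v)
        scores = scores / scores.max()
    pct = (rankdata(scores, method="average") - 1) / max(n - 1, 1) * 100.0
    return CentralityScores(nodes=nodes, scores=scores, percentile=pct)


# -- global motion coupling ---------------------------------------------------

@dataclass
class GlobalStateSeries:
    states: np.ndarray  # per-frame symbols in 1..n_states
    n_states: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.min(initial=1) < 1 or self.states.max(initial=1) > self.n_states:
            raise ValueError("states out of range")


def global_motion_states(trajectory: Trajectory, n_states: int = 25) -> GlobalStateSeries:
    """Discretized global collective-motion states.

    Each (already superposed, Cα-only) frame is projected onto the first
    principal component of the coordinate covariance; the projections are
    cut into *n_states* equal-frequency bins, so every state holds
    F/n_states (± 1) frames.  The PC sign is fixed so the first frame
    projects non-positive, making the series deterministic.
    """
    F = trajectory.n_frames
    if F <= n_states:
        raise ValueError(f"need more frames ({F}) than states ({n_states})")
    X = trajectory.coordinates.reshape(F, -1)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] < 1e-8:
        raise ValueError("static (rank-deficient) trajectory: no collective motion")
    proj = U[:, 0] * s[0]
    if proj[0] > 0:
        proj = -proj
    order = np.argsort(proj, kind="stable")
    states = np.empty(F, dtype=int)
    states[order] = np.arange(F) * n_states // F + 1
    return GlobalStateSeries(states=states, n_states=n_states)


def ilgn(alignment: StringAlignment, global_states: GlobalStateSeries) -> np.ndarray:
    """Per-fragment I_LGn: normalized MI of each column with the global states."""
    if alignment.n_frames != len(global_states.states):
        raise ValueError("alignment and global state series differ in frame count")
    return np.array(
        [
            normalized_mi(alignment.column(j), global_states.states).illn
            for j in range(alignment.n_fragments)
        ]
    )


# -- estimator facade ---------------------------------------------------------

class AllostericNetwork(BaseEstimator):
    """Fit a fragment coupling network from a structural-string alignment.

    Parameters mirror the published operating point: distance cutoff 30 Å
    between representative first-Cα positions and an MI cutoff at 33% of
    the maximum off-diagonal I_LLn (an absolute override is available).

    Fitted attributes: ``illn_`` (pairwise matrix), ``mi_cut_``,
    ``network_`` (:class:`MINetwork`), ``centrality_``.
    """

    def __init__(
        self,
        d_cut: float = 30.0,
        mi_frac: float = 0.33,
        mi_abs: Optional[float] = None,
        edge_strength: str = "illn",
    ):
        self.d_cut = d_cut
        self.mi_frac = mi_frac
        self.mi_abs = mi_abs
        self.edge_strength = edge_strength

    def fit(self, X: StringAlignment, y=None, node_coords: Optional[np.ndarray] = None):
        """X: StringAlignment; node_coords: n_fragments × 3 Å (first-Cα means)."""
        if node_coords is None:
            raise ValueError("node_coords (one 3D point per fragment) is required")
        self.fragment_ids_ = [f.index for f in X.fragments]
        self.illn_ = illn_matrix(X)
        self.network_ = build_network(
            self.illn_,
            node_coords,
            d_cut=self.d_cut,
            mi_frac=self.mi_frac,
            mi_abs=self.mi_abs,
            fragment_ids=self.fragment_ids_,
        )
        self.mi_cut_ = self.network_.mi_cut
        if not self.network_.is_empty:
            self.centrality_ = eigenvector_centrality(
                self.network_, edge_strength=self.edge_strength
            )
        else:
            self.centrality_ = None
        return self

    def shortest_path(self, site_a: Sequence[int], site_b: Sequence[int]):
        return shortest_allosteric_path(self.network_, site_a, site_b)
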