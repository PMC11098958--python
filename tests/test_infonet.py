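"""Information measures, network construction, paths, centrality, I_LGn."""

import math

import networkx as nx
import numpy as np
import pytest

from allopath.alphabet import Fragment, StringAlignment
from allopath.infonet import (
    MINetwork,
    build_network,
    eigenvector_centrality,
    finite_size_correction,
    global_motion_states,
    illn_matrix,
    ilgn,
    joint_entropy,
    mutual_information,
    normalized_mi,
    shortest_allosteric_path,
)

from conftest import make_trajectory


def mi_oracle(ci, cj):
    """Definition-level MI oracle: Σ p_xy · log(p_xy / (p_x p_y))."""
    T = len(ci)
    from collections import Counter

    pxy = Counter(zip(ci, cj))
    px, py = Counter(ci), Counter(cj)
    return sum(
        (nxy / T) * math.log((nxy / T) / ((px[x] / T) * (py[y] / T)))
        for (x, y), nxy in pxy.items()
    )


def joint_entropy_oracle(ci, cj):
    from collections import Counter

    T = len(ci)
    return -sum((n / T) * math.log(n / T) for n in Counter(zip(ci, cj)).values())


def make_network(graph: nx.Graph) -> MINetwork:
    """Wrap an arbitrary weighted graph (edge attr `weight`) as an MINetwork."""
    g = graph.copy()
    for u, v, d in g.edges(data=True):
        d.setdefault("illn", 1.0 - d["weight"])
        d.setdefault("distance", 1.0)
    ids = sorted(g.nodes)
    return MINetwork(
        graph=g,
        fragment_ids=ids,
        node_coords=np.zeros((len(ids), 3)),
        illn=np.zeros((len(ids), len(ids))),
        d_cut=np.inf,
        mi_cut=0.0,
    )


def enumerate_best_path(g: nx.Graph, site_a, site_b):
    """Exhaustive simple-path oracle with the same tie-break contract."""
    best = None
    for a in site_a:
        for b in site_b:
            if a == b:
                continue
            for path in nx.all_simple_paths(g, a, b):
                w = sum(g[u][v]["weight"] for u, v in zip(path[:-1], path[1:]))
                key = (w, len(path) - 1, tuple(path))
                if best is None or key < best:
                    best = key
    return best


class TestInformationMeasures:
    def test_joint_entropy_trivial_cases(self):
        assert joint_entropy(list("AAAA"), list("XXXX")) == pytest.approx(0.0)
        assert joint_entropy(list("AABB"), list("XYXY")) == pytest.approx(math.log(4))

    def test_mi_trivial_cases(self):
        assert mutual_information(list("AABB"), list("XXYY")) == pytest.approx(math.log(2))
        assert mutual_information(list("AABB"), list("XYXY")) == pytest.approx(0.0, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(list("AB"), list("ABC"))

    def test_epsilon_closed_forms(self):
        # fully occupied 2×2 joint at T = 4
        assert finite_size_correction(list("AABB"), list("XYXY")) == pytest.approx(0.125)
        # constant columns: (1 − 1 − 1 + 1)/2T = 0
        assert finite_size_correction(list("AAAA"), list("XXXX")) == pytest.approx(0.0)

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(200):
            T = int(rng.integers(8, 128))
            k = int(rng.integers(2, 4))
            ci = rng.integers(0, k, T)
            cj = rng.integers(0, k, T)
            assert joint_entropy(ci, cj) == pytest.approx(joint_entropy_oracle(ci.tolist(), cj.tolist()), abs=1e-12)
            assert mutual_information(ci, cj) == pytest.approx(mi_oracle(ci.tolist(), cj.tolist()), abs=1e-12)

    def test_mi_bounds_and_symmetry(self, rng):
        from allopath.infonet import entropy

        for _ in range(100):
            ci = rng.integers(0, 4, 60)
            cj = rng.integers(0, 3, 60)
            I = mutual_information(ci, cj)
            assert I >= -1e-12
            assert I <= min(entropy(ci), entropy(cj)) + 1e-12
            assert I == pytest.approx(mutual_information(cj, ci), abs=1e-12)

    def test_normalized_mi_limits(self, rng):
        col = rng.integers(0, 3, 10_000)
        self_res = normalized_mi(col, col)
        assert self_res.illn == pytest.approx(1.0, abs=1e-12)
        other = rng.integers(0, 3, 10_000)
        assert normalized_mi(col, other).illn < 0.01

    def test_normalized_mi_base_invariance(self, rng):
        """The I_LLn ratio is identical computed in bits or nats."""
        ci, cj = rng.integers(0, 4, 100), rng.integers(0, 4, 100)
        res = normalized_mi(ci, cj)
        ln2 = math.log(2)
        bits_ratio = ((res.I / ln2) - (res.epsilon / ln2)) / (res.H_joint / ln2)
        assert min(1.0, max(0.0, bits_ratio)) == pytest.approx(res.illn, abs=1e-12)

    def test_constant_column_gives_zero(self):
        assert normalized_mi(list("AAAA"), list("AAAA")).illn == 0.0


class TestIllnMatrix:
    def _alignment(self, letters):
        letters = np.asarray(letters)
        return StringAlignment(
            fragments=[Fragment(index=j) for j in range(letters.shape[1])], letters=letters
        )

    def test_identical_columns_symmetric(self, rng):
        col = np.array(list("ABABBAAB"))
        aln = self._alignment(np.stack([col, col, col], axis=1))
        m = illn_matrix(aln)
        off = m[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_matches_pairwise_calls(self, rng):
        letters = rng.choice(list("ABC"), size=(40, 4))
        aln = self._alignment(letters)
        m = illn_matrix(aln)
        for i in range(4):
            for j in range(i + 1, 4):
                assert m[i, j] == pytest.approx(
                    normalized_mi(letters[:, i], letters[:, j]).illn, abs=1e-14
                )

    def test_constant_column_diagonal_zero(self):
        letters = np.stack([np.array(list("AAAA")), np.array(list("ABAB"))], axis=1)
        m = illn_matrix(self._alignment(letters))
        assert m[0, 0] == 0.0 and m[1, 1] == 1.0


class TestBuildNetwork:
    def test_cutoff_is_fraction_of_max(self):
        """Max off-diagonal 0.403 at the 33% rule → cutoff ≈ 0.133."""
        illn = np.zeros((3, 3))
        illn[0, 1] = illn[1, 0] = 0.403
        illn[1, 2] = illn[2, 1] = 0.2
        np.fill_diagonal(illn, 1.0)
        coords = np.zeros((3, 3))
        coords[1, 0], coords[2, 0] = 10.0, 20.0
        net = build_network(illn, coords, mi_frac=0.33)
        assert net.mi_cut == pytest.approx(0.133, abs=5e-4)  # printed precision
        assert net.graph.number_of_edges() == 2

    def test_distance_gate(self):
        illn = np.eye(2)
        illn[0, 1] = illn[1, 0] = 0.9
        coords = np.array([[0.0, 0, 0], [31.0, 0, 0]])
        net = build_network(illn, coords, d_cut=30.0)
        assert net.graph.number_of_edges() == 0
        assert net.is_empty

    def test_matches_brute_force_filter(self, rng):
        n = 15
        m = rng.uniform(0, 0.5, size=(n, n))
        illn = (m + m.T) / 2
        np.fill_diagonal(illn, 1.0)
        coords = rng.uniform(0, 50, size=(n, 3))
        net = build_network(illn, coords, d_cut=30.0, mi_frac=0.33)
        cut = 0.33 * illn[~np.eye(n, dtype=bool)].max()
        expected = {
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if np.linalg.norm(coords[i] - coords[j]) <= 30.0 and illn[i, j] >= cut
        }
        assert {tuple(sorted(e)) for e in net.graph.edges} == expected
        for i, j in expected:
            assert net.graph[i][j]["weight"] == pytest.approx(1.0 - illn[i, j])

    @pytest.mark.parametrize("fracs", [(0.2, 0.4), (0.33, 0.66), (0.5, 0.9)])
    def test_edges_monotone_in_mi_frac(self, rng, fracs):
        n = 12
        m = rng.uniform(0, 0.6, size=(n, n))
        illn = (m + m.T) / 2
        np.fill_diagonal(illn, 1.0)
        coords = rng.uniform(0, 40, size=(n, 3))
        lo = set(build_network(illn, coords, mi_frac=fracs[0]).graph.edges)
        hi = set(build_network(illn, coords, mi_frac=fracs[1]).graph.edges)
        assert hi <= lo

    def test_all_zero_matrix_is_valid_empty(self):
        net = build_network(np.zeros((4, 4)), np.zeros((4, 3)))
        assert net.is_empty


class TestShortestPath:
    def test_simple_chain(self):
        g = nx.Graph()
        g.add_edge("A", "x", weight=1.0)
        g.add_edge("x", "B", weight=1.0)
        p = shortest_allosteric_path(make_network(g), ["A"], ["B"])
        assert p.fragments == ["A", "x", "B"]
        assert p.total_weight == pytest.approx(2.0)

    def test_disconnected_sites_give_no_path(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.5)
        g.add_edge(2, 3, weight=0.5)
        assert shortest_allosteric_path(make_network(g), [0], [3]) is None

    def test_unknown_site_fragment_named(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.5)
        with pytest.raises(KeyError, match="f99"):
            shortest_allosteric_path(make_network(g), [0], [99])

    def test_tie_break_fewer_edges_then_lexicographic(self):
        g = nx.Graph()
        # two weight-1.0 routes 0→3: direct heavy edge vs two light edges
        g.add_edge(0, 3, weight=1.0)
        g.add_edge(0, 1, weight=0.5)
        g.add_edge(1, 3, weight=0.5)
        p = shortest_allosteric_path(make_network(g), [0], [3])
        assert p.fragments == [0, 3]  # same weight, fewer edges wins
        # lexicographic: two 2-edge routes of equal weight
        g2 = nx.Graph()
        g2.add_edge(0, 1, weight=0.5)
        g2.add_edge(1, 3, weight=0.5)
        g2.add_edge(0, 2, weight=0.5)
        g2.add_edge(2, 3, weight=0.5)
        p2 = shortest_allosteric_path(make_network(g2), [0], [3])
        assert p2.fragments == [0, 1, 3]

    def test_matches_enumeration_on_random_graphs(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            nodes = list(g.nodes)
            site_a = [nodes[0]]
            site_b = [nodes[-1]]
            got = shortest_allosteric_path(make_network(g), site_a, site_b)
            want = enumerate_best_path(g, site_a, site_b)
            if want is None:
                assert got is None
            else:
                assert got.total_weight == pytest.approx(want[0], abs=1e-12)
                assert tuple(got.fragments) == want[2]

    def test_optimality_certificate_edge_removal(self, rng):
        """Deleting any edge of the optimal path never shortens the optimum."""
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(2**31)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            p = shortest_allosteric_path(make_network(g), [0], [7])
            if p is None:
                continue
            for u, v in zip(p.fragments[:-1], p.fragments[1:]):
                g2 = g.copy()
                g2.remove_edge(u, v)
                p2 = shortest_allosteric_path(make_network(g2), [0], [7])
                assert p2 is None or p2.total_weight >= p.total_weight - 1e-12


class TestCentrality:
    def test_star_center_max(self):
        g = nx.star_graph(5)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.5
        c = eigenvector_centrality(make_network(g))
        assert c.nodes[int(np.argmax(c.scores))] == 0
        assert c.scores.max() == pytest.approx(1.0)

    def test_cycle_all_equal(self):
        g = nx.cycle_graph(7)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.4
        c = eigenvector_centrality(make_network(g))
        assert np.allclose(c.scores, 1.0, atol=1e-9)

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.5, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.0, 0.9))
            net = make_network(g)
            c = eigenvector_centrality(net)
            S = nx.to_numpy_array(net.graph, nodelist=c.nodes, weight="illn")
            vals, vecs = np.linalg.eigh(S)
            lead = np.abs(vecs[:, np.argmax(vals)])
            assert np.abs(c.scores - lead / lead.max()).max() < 1e-8

    def test_top_nodes_percentile(self):
        g = nx.star_graph(9)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.5
        c = eigenvector_centrality(make_network(g))
        assert c.top_nodes(12.0) == [0]


class TestGlobalMotion:
    def test_monotone_translation_gives_monotone_states(self):
        base = np.random.default_rng(0).normal(0, 2, size=(10, 3))
        frames = np.stack([base + np.array([0.05 * f, 0, 0]) for f in range(60)])
        gss = global_motion_states(make_trajectory(frames), n_states=6)
        diffs = np.diff(gss.states)
        assert np.all(diffs >= 0) or np.all(diffs <= 0)
        # sign convention: first frame projects negative → states ascend
        assert gss.states[0] == 1

    def test_equal_frequency_binning(self, rng):
        frames = rng.normal(0, 1, size=(103, 6, 3))
        gss = global_motion_states(make_trajectory(frames), n_states=10)
        _, counts = np.unique(gss.states, return_counts=True)
        assert counts.max() - counts.min() <= 1

    def test_two_cluster_trajectory(self, rng):
        a = rng.normal(0, 0.1, size=(6, 3))
        b = a + np.array([8.0, 0, 0])
        labels = np.array([0, 1] * 25)  # balanced: equal-frequency split is exact
        rng.shuffle(labels)
        frames = np.stack([a if l == 0 else b for l in labels]) + rng.normal(
            0, 0.05, size=(50, 6, 3)
        )
        gss = global_motion_states(make_trajectory(frames), n_states=2)
        # states must coincide with cluster labels (up to label swap)
        agree = np.mean((gss.states - 1) == labels)
        assert agree in (0.0, 1.0)

    def test_static_trajectory_rejected(self):
        frames = np.zeros((30, 5, 3))
        with pytest.raises(ValueError, match="static"):
            global_motion_states(make_trajectory(frames), n_states=4)


class TestIlgn:
    def _alignment(self, letters):
        return StringAlignment(
            fragments=[Fragment(index=j) for j in range(letters.shape[1])], letters=letters
        )

    def test_self_coupling(self, rng):
        from allopath.infonet import GlobalStateSeries

        states = rng.integers(1, 3, 500)
        letters = np.array(["AB"[s - 1] for s in states])[:, None]
        vals = ilgn(self._alignment(letters), GlobalStateSeries(states=states, n_states=2))
        res = normalized_mi(letters[:, 0], states)
        assert vals[0] == pytest.approx(res.illn)
        assert vals[0] > 0.95

    def test_independent_column_near_zero(self, rng):
        from allopath.infonet import GlobalStateSeries

        states = rng.integers(1, 3, 5000)
        letters = rng.choice(list("AB"), size=(5000, 1))
        vals = ilgn(self._alignment(letters), GlobalStateSeries(states=states, n_states=2))
        assert vals[0] < 0.01

    def test_root_fragment_drives_global_drift(self, rng):
        """A fragment whose state sets the global coordinate has maximal I_LGn."""
        from allopath.synthetic import PlantedChainSpec, gen_coupled_state_chain

        aln, _, truth = gen_coupled_state_chain(PlantedChainSpec(seed=4, n_frames=800))
        root = truth["chain"][0]
        root_col = aln.column_by_fragment(root)
        # build a toy trajectory whose first PC tracks the root state
        shift = (root_col == root_col[0]).astype(float) * 6.0
        base = rng.normal(0, 0.3, size=(800, 5, 3))
        base[:, 0, 0] += shift
        gss = global_motion_states(make_trajectory(base), n_states=2)
        vals = ilgn(aln, gss)
        assert int(np.argmax(vals)) == root

    def test_length_mismatch(self, rng):
        from allopath.infonet import GlobalStateSeries

        letters = rng.choice(list("AB"), size=(10, 2))
        with pytest.raises(ValueError, match="frame count"):
            ilgn(self._alignment(letters), GlobalStateSeries(states=np.ones(9, int), n_states=2))
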