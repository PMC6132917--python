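"""Weighted shortest paths, global efficiency, betweenness centrality,
per-subject z-scoring and the per-network summary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painnet import (
    AdjacencyMatrix,
    NodeSet,
    betweenness_centrality,
    global_efficiency,
    shortest_paths,
    summarize,
    to_lengths,
    zscore_bc,
)
from conftest import random_adjacency


# --- independent oracles -------------------------------------------------


def floyd_warshall(lengths):
    """Brute-force all-pairs shortest path lengths."""
    d = np.asarray(lengths, dtype=float).copy()
    n = d.shape[0]
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def enumerate_betweenness(weights, rtol=1e-9):
    """Exhaustive simple-path enumeration oracle for betweenness."""
    lengths = to_lengths(weights)
    n = lengths.shape[0]
    best = {}
    paths = {}

    def extend(path, cost):
        s = path[0]
        t = path[-1]
        key = (s, t)
        if np.isfinite(cost):
            prev = best.get(key, np.inf)
            if cost < prev * (1 - rtol):
                best[key] = cost
                paths[key] = [tuple(path)]
            elif abs(cost - prev) <= rtol * max(cost, prev):
                paths[key].append(tuple(path))
        for nxt in range(n):
            if nxt in path:
                continue
            step = lengths[t, nxt]
            if np.isfinite(step):
                extend(path + [nxt], cost + step)

    for s in range(n):
        for nxt in range(n):
            if nxt != s and np.isfinite(lengths[s, nxt]):
                extend([s, nxt], lengths[s, nxt])
    bc = np.zeros(n)
    for (s, t) in best:
        shortest = paths[(s, t)]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p[1:-1])
            bc[v] += through / len(shortest)
    return bc / 2.0  # ordered pairs -> unordered-pair scale


# --- to_lengths ----------------------------------------------------------


class TestToLengths:
    def test_reciprocal(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert to_lengths(w)[0, 1] == pytest.approx(2.0)

    def test_negative_policies(self):
        w = np.array([[0.0, -0.3], [-0.3, 0.0]])
        assert np.isinf(to_lengths(w, "zero")[0, 1])
        assert to_lengths(w, "abs")[0, 1] == pytest.approx(10 / 3)

    def test_all_zero_gives_infinite_lengths(self):
        lengths = to_lengths(np.zeros((3, 3)))
        off = ~np.eye(3, dtype=bool)
        assert np.isinf(lengths[off]).all()
        assert (np.diagonal(lengths) == 0).all()

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="negative_policy"):
            to_lengths(np.zeros((2, 2)), "clip")


# --- shortest paths ------------------------------------------------------


class TestShortestPaths:
    def test_indirect_beats_weak_direct_edge(self):
        w = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.9], [0.1, 0.9, 0.0]])
        d, sigma = shortest_paths(to_lengths(w))
        assert d[0, 2] == pytest.approx(2 / 0.9)
        assert sigma[0, 2] == 1

    def test_complete_uniform_graph_direct_paths(self):
        n, w = 6, 0.4
        weights = np.full((n, n), w)
        np.fill_diagonal(weights, 0.0)
        d, sigma = shortest_paths(to_lengths(weights))
        off = ~np.eye(n, dtype=bool)
        assert np.allclose(d[off], 1 / w)
        assert np.all(sigma[off] == 1)

    def test_tied_paths_are_counted(self):
        # two equal-length 2-hop routes between the poles of a 4-cycle
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[i, j] = w[j, i] = 1.0
        d, sigma = shortest_paths(to_lengths(w))
        assert d[0, 2] == pytest.approx(2.0)
        assert sigma[0, 2] == 2

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_floyd_warshall_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        w = random_adjacency(rng, int(rng.integers(4, 9)), density=0.6)
        lengths = to_lengths(w)
        d, _ = shortest_paths(lengths)
        ref = floyd_warshall(lengths)
        both = np.isfinite(d) & np.isfinite(ref)
        assert (np.isfinite(d) == np.isfinite(ref)).all()
        assert np.allclose(d[both], ref[both], atol=1e-9)


# --- global efficiency ---------------------------------------------------


class TestGlobalEfficiency:
    def test_complete_uniform_graph(self):
        w = np.full((5, 5), 0.5)
        np.fill_diagonal(w, 0.0)
        assert global_efficiency(w) == pytest.approx(0.5)

    def test_edgeless_graph(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_three_node_hand_example(self):
        w = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.9], [0.1, 0.9, 0.0]])
        assert global_efficiency(w) == pytest.approx(0.75)

    def test_rejects_single_node(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((1, 1)))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=25)
    def test_monotone_under_single_weight_increase(self, seed):
        rng = np.random.default_rng(seed)
        w = random_adjacency(rng, 6, density=0.5)
        ge0 = global_efficiency(w)
        i, j = sorted(rng.choice(6, size=2, replace=False))
        w2 = w.copy()
        w2[i, j] = w2[j, i] = w2[i, j] + rng.uniform(0.1, 1.0)
        assert global_efficiency(w2) >= ge0 - 1e-12


# --- betweenness ---------------------------------------------------------


class TestBetweenness:
    def test_complete_uniform_graph_has_no_intermediaries(self):
        w = np.full((6, 6), 0.7)
        np.fill_diagonal(w, 0.0)
        assert np.allclose(betweenness_centrality(w), 0.0)

    def test_star_center_carries_all_leaf_pairs(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 1.0
        bc = betweenness_centrality(w)
        assert bc[0] == pytest.approx(3.0)
        assert np.allclose(bc[1:], 0.0)

    def test_tied_routes_split_credit(self):
        # 4-cycle: each pole pair splits its unit of credit over two routes
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[i, j] = w[j, i] = 1.0
        bc = betweenness_centrality(w)
        assert np.allclose(bc, 0.5)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(4, 8))
        w = random_adjacency(rng, n, density=0.6)
        assert np.allclose(
            betweenness_centrality(w), enumerate_betweenness(w), atol=1e-9
        )

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_networkx_brandes(self, trial):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(3000 + trial)
        n = int(rng.integers(5, 12))
        w = random_adjacency(rng, n, density=0.7)
        lengths = to_lengths(w)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if np.isfinite(lengths[i, j]):
                    g.add_edge(i, j, weight=lengths[i, j])
        ref = nx.betweenness_centrality(g, weight="weight", normalized=False)
        assert np.allclose(
            betweenness_centrality(w),
            [ref[i] for i in range(n)],
            atol=1e-9,
        )

    def test_scale_covariance(self, rng):
        w = random_adjacency(rng, 7, density=0.6)
        c = 3.7
        assert global_efficiency(c * w) == pytest.approx(
            c * global_efficiency(w), rel=1e-12
        )
        assert np.allclose(
            betweenness_centrality(c * w), betweenness_centrality(w), atol=1e-9
        )

    def test_rejects_two_nodes(self):
        with pytest.raises(ValueError):
            betweenness_centrality(np.zeros((2, 2)))


# --- z-scoring -----------------------------------------------------------


class TestZscoreBc:
    def test_zscore_identities(self, rng):
        bc = rng.uniform(0, 5, size=10)
        z = zscore_bc(bc)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_constant_vector_zscores_to_zero(self):
        assert np.allclose(zscore_bc(np.full(5, 2.0)), 0.0)

    def test_star_population_sd_values(self):
        z = zscore_bc(np.array([0.0, 3.0, 0.0, 0.0]))
        assert z == pytest.approx([-0.577, 1.732, -0.577, -0.577], abs=1e-3)

    def test_sample_sd_variant(self):
        z = zscore_bc(np.array([0.0, 3.0, 0.0, 0.0]), ddof=1)
        assert z[1] == pytest.approx(2.25 / np.std([0, 3, 0, 0], ddof=1))


# --- per-network summary -------------------------------------------------


def block_adjacency(n=12, pain=(0, 1, 2, 3), w=0.6):
    adj = np.zeros((n, n))
    idx = np.asarray(pain)
    adj[np.ix_(idx, idx)] = w
    np.fill_diagonal(adj, 0.0)
    return adj


class TestSummarize:
    def test_whole_brain_mean_zbc_is_zero(self, rng):
        w = random_adjacency(rng, 10)
        adj = AdjacencyMatrix(w)
        wb = NodeSet("whole_brain", tuple(range(10)), 10)
        summ = summarize(adj, {"whole_brain": wb})
        assert summ.subnetworks["whole_brain"]["mean_z_bc"] == pytest.approx(
            0.0, abs=1e-12
        )
        assert summ.subnetworks["whole_brain"]["ge"] == pytest.approx(
            summ.ge_whole_brain
        )

    def test_dense_pain_block_ge_equals_weight(self):
        adj = AdjacencyMatrix(block_adjacency(w=0.6))
        pain = NodeSet("pain", (0, 1, 2, 3), 12)
        summ = summarize(adj, {"pain": pain})
        assert summ.subnetworks["pain"]["ge"] == pytest.approx(0.6)

    def test_permutation_invariance(self, rng):
        n = 10
        w = random_adjacency(rng, n)
        pain_idx = (1, 4, 7)
        summ = summarize(
            AdjacencyMatrix(w), {"pain": NodeSet("pain", pain_idx, n)}
        )
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        w_p = w[np.ix_(perm, perm)]
        pain_p = tuple(int(inv[i]) for i in pain_idx)
        summ_p = summarize(
            AdjacencyMatrix(w_p), {"pain": NodeSet("pain", pain_p, n)}
        )
        assert summ_p.ge_whole_brain == pytest.approx(summ.ge_whole_brain)
        assert summ_p.subnetworks["pain"]["ge"] == pytest.approx(
            summ.subnetworks["pain"]["ge"]
        )
        assert summ_p.subnetworks["pain"]["mean_z_bc"] == pytest.approx(
            summ.subnetworks["pain"]["mean_z_bc"]
        )

    def test_restricted_mode_uses_whole_brain_distances(self, rng):
        w = random_adjacency(rng, 9)
        adj = AdjacencyMatrix(w)
        pain = NodeSet("pain", (0, 3, 5), 9)
        induced = summarize(adj, {"pain": pain}, subnetwork_ge_mode="induced")
        restricted = summarize(
            adj, {"pain": pain}, subnetwork_ge_mode="restricted"
        )
        # whole-brain shortcuts can only shorten paths between pain nodes
        assert (
            restricted.subnetworks["pain"]["ge"]
            >= induced.subnetworks["pain"]["ge"] - 1e-12
        )

    def test_row_layout(self, rng):
        w = random_adjacency(rng, 8)
        summ = summarize(
            AdjacencyMatrix(w),
            {"pain": NodeSet("pain", (0, 1, 2), 8)},
            subject_id="s1",
            session="ON",
            n_frames_retained=77,
            mean_motion=0.12,
        )
        row = summ.to_row()
        assert set(row) == {
            "subject_id",
            "session",
            "ge_whole_brain",
            "ge_pain",
            "bc_pain",
            "mean_motion",
            "n_frames_retained",
        }


class TestGeneratorTrend:
    def test_expected_pain_ge_increases_with_planted_correlation(self):
        """Monte-Carlo: measured pain-network GE rises with the planted
        pain-block coupling."""
        from painnet import CohortDesign, simulate_subject, subject_adjacency
        from painnet.nodesets import induced_subgraph

        means = []
        for r in (0.2, 0.45, 0.7):
            vals = []
            for seed in range(8):
                d = CohortDesign(
                    n_nodes=16,
                    n_frames=150,
                    pain_nodes=tuple(range(8)),
                    pain_r_by_group={"patient": r, "control": r},
                    pain_r_sd=0.0,
                    seed=seed,
                )
                rec = simulate_subject(d, "patient", seed)
                adj, _, _ = subject_adjacency(
                    rec.time_series, rec.motion, drop_volumes=1
                )
                pain = NodeSet("pain", tuple(range(8)), 16)
                vals.append(global_efficiency(induced_subgraph(adj, pain).weights))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
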