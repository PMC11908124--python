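"""Structure networks, Girvan–Newman communities, and suboptimal paths.

Path search is checked against an independent brute-force oracle that
enumerates *all* simple paths and sorts by (length, lexicographic order);
community detection against exhaustive modularity maximization over the
recorded partition sequence, with modularity recomputed from its definition.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from allodyn.core import TrajectoryEnsemble, select
from allodyn.correlation import CorrelationMatrix, dccm
from allodyn.network import (ContactMap, build_psn, contact_map, girvan_newman,
                             node_participation, optimal_path,
                             path_length_distribution, suboptimal_paths)
from allodyn.synthetic import (EnsembleSpec, make_block_correlation,
                               make_reference_geometry, sample_ensemble)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_paths(G, source, sink, k, weight="weight"):
    out = []
    for p in nx.all_simple_paths(G, source, sink):
        L = sum(G[u][v].get(weight, 1.0) for u, v in zip(p[:-1], p[1:]))
        out.append((float(L), tuple(p)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out[:k]


def modularity_by_definition(G, partition, weight=None):
    """Q = sum_c [ in_c/m - (deg_c/2m)^2 ], written from the definition."""
    m2 = sum(d.get(weight, 1.0) for _, _, d in G.edges(data=True)) * 2.0
    q = 0.0
    for comm in partition:
        comm = set(comm)
        inside = sum(d.get(weight, 1.0) for u, v, d in G.edges(data=True)
                     if u in comm and v in comm)
        degree = sum(d.get(weight, 1.0) for u in comm
                     for _, _, d in G.edges(u, data=True))
        q += 2.0 * inside / m2 - (degree / m2) ** 2
    return q


def random_weighted_graph(rng, n, p=0.45):
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(i, j, weight=float(rng.uniform(0.1, 2.0)))
    return G


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

class TestContactMap:
    def test_five_angstrom_threshold(self):
        ref = make_reference_geometry(3, "extended-chain")  # 3.8 Å spacing
        sel = select(ref, "calpha")
        cm = contact_map(ref, sel, cutoff=5.0)
        assert cm.mask[0, 1] and cm.mask[1, 2]      # 3.8 Å ≤ 5
        assert not cm.mask[0, 2]                     # 7.6 Å > 5
        assert not cm.mask.diagonal().any()

    def test_occupancy_mode_counts_frames(self):
        ref = make_reference_geometry(2, "extended-chain")
        sel = select(ref, "calpha")
        frames = np.repeat(ref.coords[None], 10, axis=0)
        frames[:6, 1, 0] = 4.0   # within 5 Å for 60% of frames
        frames[6:, 1, 0] = 7.0
        traj = TrajectoryEnsemble(topology=ref, frames=frames)
        assert not contact_map(traj, sel, 5.0, "occupancy", 0.75).mask[0, 1]
        assert contact_map(traj, sel, 5.0, "occupancy", 0.5).mask[0, 1]

    def test_invalid_parameters(self):
        ref = make_reference_geometry(2, "extended-chain")
        sel = select(ref, "calpha")
        with pytest.raises(ValueError):
            contact_map(ref, sel, cutoff=-1.0)
        with pytest.raises(ValueError):
            contact_map(ref, sel, 5.0, "occupancy", 0.0)


# ---------------------------------------------------------------------------
# PSN construction
# ---------------------------------------------------------------------------

class TestBuildPSN:
    def _corr(self, entries, n=4):
        c = np.eye(n)
        for (i, j), v in entries.items():
            c[i, j] = c[j, i] = v
        return CorrelationMatrix(values=c)

    def _contacts(self, pairs, n=4):
        m = np.zeros((n, n), dtype=bool)
        for i, j in pairs:
            m[i, j] = m[j, i] = True
        return ContactMap(mask=m, cutoff=5.0)

    def test_weight_is_minus_log_correlation(self):
        net = build_psn(self._corr({(0, 1): 0.5}), self._contacts([(0, 1)]))
        assert net.graph[0][1]["weight"] == pytest.approx(0.6931471805599453)

    def test_perfect_coupling_has_zero_weight(self):
        net = build_psn(self._corr({(0, 1): 1.0}), self._contacts([(0, 1)]))
        assert net.graph[0][1]["weight"] == 0.0

    def test_contact_gate_blocks_high_correlation(self):
        net = build_psn(self._corr({(0, 1): 0.8}), self._contacts([(2, 3)]))
        assert not net.graph.has_edge(0, 1)

    def test_correlation_threshold_gate(self):
        corr = self._corr({(0, 1): 0.4, (2, 3): 0.6})
        net = build_psn(corr, self._contacts([(0, 1), (2, 3)]),
                        correlation_threshold=0.5)
        assert not net.graph.has_edge(0, 1)
        assert net.graph.has_edge(2, 3)

    def test_anticorrelation_uses_magnitude(self):
        net = build_psn(self._corr({(0, 1): -0.5}), self._contacts([(0, 1)]))
        assert net.graph[0][1]["weight"] == pytest.approx(np.log(2.0))

    def test_floor_drops_near_zero_correlations(self):
        net = build_psn(self._corr({(0, 1): 1e-9}), self._contacts([(0, 1)]))
        assert not net.graph.has_edge(0, 1)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_psn(self._corr({}, n=4), self._contacts([], n=5))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        c = np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (8, 8))), -1, 1)
        np.fill_diagonal(c, 1.0)
        corr = CorrelationMatrix(values=c)
        prev_edges = None
        prev_len = -np.inf
        for thr in (0.0, 0.2, 0.4, 0.6):
            net = build_psn(corr, None, correlation_threshold=thr)
            edges = set(net.graph.edges())
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges
            if net.graph.has_edge(0, 1) and nx.has_path(net.graph, 0, 7):
                _, L = optimal_path(net, 0, 7)
                assert L >= prev_len - 1e-12
                prev_len = L


# ---------------------------------------------------------------------------
# Girvan–Newman
# ---------------------------------------------------------------------------

class TestGirvanNewman:
    def test_barbell_splits_into_cliques(self):
        G = nx.Graph()
        for base in (0, 4):
            G.add_edges_from((base + i, base + j)
                             for i, j in itertools.combinations(range(4), 2))
        G.add_edge(3, 4)
        part = girvan_newman(G)
        assert part.n_communities == 2
        assert {frozenset(k for k, v in part.labels.items() if v == c)
                for c in (0, 1)} == {frozenset(range(4)), frozenset(range(4, 8))}
        # brute-force modularity over the recorded sequence agrees
        best = max(part.partitions, key=lambda p: modularity_by_definition(G, p))
        assert modularity_by_definition(G, best) == pytest.approx(part.modularity)

    def test_complete_graph_stays_single_community(self):
        G = nx.complete_graph(5)
        part = girvan_newman(G)
        qs = {len(p): modularity_by_definition(G, p) for p in part.partitions}
        assert max(qs.values()) == qs[part.n_communities]
        assert part.n_communities == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_modularity_over_partition_sequence(self, seed):
        rng = np.random.default_rng(seed)
        G = random_weighted_graph(rng, n=6, p=0.6)
        if G.number_of_edges() == 0:
            pytest.skip("degenerate empty graph")
        for u, v in G.edges():
            G[u][v]["corr"] = float(np.exp(-G[u][v]["weight"]))
        part = girvan_newman(G)
        qs = [modularity_by_definition(G, p, weight="corr") for p in part.partitions]
        assert part.modularity == pytest.approx(max(qs), abs=1e-9)
        got = {frozenset(k for k, v in part.labels.items() if v == c)
               for c in set(part.labels.values())}
        assert got == set(part.partitions[int(np.argmax(qs))])

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        R = make_block_correlation(20, [set(range(10)), set(range(10, 20))], 0.9, 0.05)
        traj = sample_ensemble(EnsembleSpec(n_residues=20, target_correlation=R,
                                            n_frames=2000, seed=1))
        c = dccm(traj, select(traj.topology, "calpha"))
        net = build_psn(c, None, correlation_threshold=0.5)
        part = girvan_newman(net)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, part.as_array(range(20))) == 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            girvan_newman(nx.Graph())


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

class TestPaths:
    def test_single_edge(self):
        G = nx.Graph()
        G.add_edge("s", "t", weight=0.69)
        path, L = optimal_path(G, "s", "t")
        assert path == ("s", "t")
        assert L == pytest.approx(0.69)

    def test_triangle_prefers_two_cheap_hops(self):
        G = nx.Graph()
        G.add_edge("s", "t", weight=2.0)
        G.add_edge("s", "m", weight=0.5)
        G.add_edge("m", "t", weight=0.5)
        path, L = optimal_path(G, "s", "t")
        assert path == ("s", "m", "t")
        assert L == pytest.approx(1.0)

    def test_disconnected_raises(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_node(2)
        with pytest.raises(ValueError, match="no path"):
            optimal_path(G, 0, 2)

    def test_source_equals_sink_rejected(self):
        G = nx.complete_graph(3)
        with pytest.raises(ValueError):
            suboptimal_paths(G, 1, 1, k=2)

    def test_k_one_equals_optimal(self):
        rng = np.random.default_rng(5)
        G = random_weighted_graph(rng, 8)
        pe = suboptimal_paths(G, 0, 7, k=1)
        assert pe.paths[0] == optimal_path(G, 0, 7)[0]

    def test_diamond_ordering(self):
        G = nx.Graph()
        G.add_edge("s", "a", weight=1.0)
        G.add_edge("a", "t", weight=1.0)
        G.add_edge("s", "b", weight=1.2)
        G.add_edge("b", "t", weight=1.2)
        pe = suboptimal_paths(G, "s", "t", k=10)
        assert pe.paths == [("s", "a", "t"), ("s", "b", "t")]
        np.testing.assert_allclose(pe.lengths, [2.0, 2.4])

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("k", [1, 5, 100])
    def test_oracle_equivalence_on_random_graphs(self, seed, k):
        rng = np.random.default_rng(100 + seed)
        G = random_weighted_graph(rng, n=int(rng.integers(6, 11)))
        if not (0 in G and nx.has_path(G, 0, max(G.nodes))):
            pytest.skip("disconnected sample")
        sink = max(G.nodes)
        expect = brute_force_paths(G, 0, sink, k)
        pe = suboptimal_paths(G, 0, sink, k=k)
        assert pe.paths == [p for _, p in expect]
        np.testing.assert_allclose(pe.lengths, [L for L, _ in expect])

    def test_planted_chain_is_optimal_path(self):
        from allodyn.synthetic import plant_chain_correlation

        chain = [2, 5, 8]
        base = make_block_correlation(10, [set(range(10))], 0.1, 0.0)
        R = plant_chain_correlation(base, chain, 0.9)
        traj = sample_ensemble(EnsembleSpec(n_residues=10, target_correlation=R,
                                            n_frames=2000, seed=1))
        c = dccm(traj, select(traj.topology, "calpha"))
        net = build_psn(c)
        path, _ = optimal_path(net, 2, 8)
        assert list(path) == chain
        # agrees with the brute-force oracle on the full induced network
        expect = brute_force_paths(net.graph, 2, 8, 1)
        assert path == expect[0][1]

    def test_raising_correlation_on_optimal_edge_never_lengthens(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=-np.log(0.5), corr=0.5)
        G.add_edge(1, 2, weight=-np.log(0.6), corr=0.6)
        G.add_edge(0, 2, weight=-np.log(0.3), corr=0.3)
        _, before = optimal_path(G, 0, 2)
        G[0][1]["weight"] = -np.log(0.9)
        _, after = optimal_path(G, 0, 2)
        assert after <= before + 1e-12


class TestPathSummaries:
    def _ensemble(self, lengths):
        paths = [tuple(["s"] + [f"m{i}"] * i + ["t"]) for i in range(len(lengths))]
        from allodyn.network import PathEnsemble

        order = np.argsort(lengths, kind="stable")
        return PathEnsemble(paths=[paths[i] for i in order],
                            lengths=np.asarray(lengths, dtype=float)[order])

    def test_single_value_distribution(self):
        d = path_length_distribution(self._ensemble([2.5, 2.5, 2.5]), bin_width=0.5)
        assert d.counts.sum() == 3
        assert d.peak == pytest.approx(2.75)
        assert d.kde_peak == pytest.approx(2.5)

    def test_counting_example(self):
        d = path_length_distribution(self._ensemble([1.0, 1.0, 1.0, 2.0]), bin_width=0.5)
        assert d.peak == pytest.approx(1.25)
        assert d.counts.sum() == 4

    def test_peak_within_range(self):
        rng = np.random.default_rng(2)
        lengths = np.sort(rng.uniform(3.0, 4.0, 50))
        d = path_length_distribution(self._ensemble(list(lengths)), bin_width=0.05)
        assert lengths.min() <= d.peak <= lengths.max() + 0.05
        assert lengths.min() - 0.05 <= d.kde_peak <= lengths.max() + 0.05

    def test_node_participation_counts(self):
        G = nx.Graph()
        G.add_edge("s", "a", weight=1.0)
        G.add_edge("a", "t", weight=1.0)
        G.add_edge("s", "b", weight=1.2)
        G.add_edge("b", "t", weight=1.2)
        pe = suboptimal_paths(G, "s", "t", k=2)
        counts = node_participation(pe)
        assert counts["s"] == counts["t"] == 2
        assert counts["a"] == counts["b"] == 1

    def test_k1_participation_is_optimal_indicator(self):
        G = nx.complete_graph(4)
        for u, v in G.edges():
            G[u][v]["weight"] = 1.0
        pe = suboptimal_paths(G, 0, 3, k=1)
        counts = node_participation(pe)
        assert set(counts) == set(pe.paths[0])
        assert all(v == 1 for v in counts.values())
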