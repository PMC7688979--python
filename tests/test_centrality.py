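import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topspread import CENTRALITY_NAMES, centrality_table, fixture
from topspread.centrality import (
    NotStronglyConnectedError,
    closeness,
    core_number,
    eigenvector,
    neighbourhood_sum,
    out_degree,
    pagerank,
    two_hop_neighbourhood_sum,
)
from topspread.graph_io import Network

from .conftest import random_digraph, random_scc


# ---------------------------------------------------------------- oracles


def brute_k_sum(net):
    deg = {u: len(net.successors(u)) for u in net.nodes}
    out = {}
    for u in net.nodes:
        total = 0
        for v in net.nodes:
            if net.has_edge(u, v):
                total += deg[v]
        out[u] = total
    return out


def brute_k_2sum(net):
    deg = {u: len(net.successors(u)) for u in net.nodes}
    out = {}
    for u in net.nodes:
        # BFS distances along out-edges
        dist = {u: 0}
        frontier = [u]
        while frontier:
            nxt = []
            for x in frontier:
                for y in net.successors(x):
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        nxt.append(y)
            frontier = nxt
        out[u] = sum(deg[v] for v, d in dist.items() if d == 2)
    return out


def brute_closeness(net):
    n = net.n_nodes
    out = {}
    for u in net.nodes:
        dist = {u: 0}
        frontier = [u]
        while frontier:
            nxt = []
            for x in frontier:
                for y in net.successors(x):
                    if y not in dist:
                        dist[y] = dist[x] + 1
                        nxt.append(y)
            frontier = nxt
        out[u] = (n - 1) / sum(dist.values())
    return out


# ------------------------------------------------------------ small cases


class TestLocalIndicators:
    def test_out_degree_star(self):
        net = fixture("star", 6)
        deg = out_degree(net)
        assert deg["n0000"] == 5
        assert all(deg[u] == 1 for u in net.nodes if u != "n0000")

    def test_out_degree_cycle_and_complete(self, cycle5, complete4):
        assert set(out_degree(cycle5).values()) == {1}
        assert set(out_degree(complete4).values()) == {3}

    def test_k_sum_path(self):
        net = Network([("a", "b"), ("b", "c")])
        assert neighbourhood_sum(net) == {"a": 1, "b": 0, "c": 0}

    def test_k_sum_cycle(self, cycle5):
        assert set(neighbourhood_sum(cycle5).values()) == {1}

    def test_k_2sum_path(self):
        net = Network([("a", "b"), ("b", "c"), ("c", "d")])
        k2 = two_hop_neighbourhood_sum(net)
        assert k2["a"] == 1  # sees c, whose out-degree is 1
        assert k2["b"] == 0  # sees d, out-degree 0
        assert k2["d"] == 0

    def test_k_2sum_star_center(self):
        net = fixture("star", 6)
        assert two_hop_neighbourhood_sum(net)["n0000"] == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_k_sum_and_k_2sum_match_brute_force(self, seed):
        net = random_digraph(30, 0.1, seed)
        assert neighbourhood_sum(net) == brute_k_sum(net)
        assert two_hop_neighbourhood_sum(net) == brute_k_2sum(net)


class TestCoreNumber:
    def test_complete_digraph_single_core(self):
        net = fixture("complete", 5)
        assert len(set(core_number(net).values())) == 1

    def test_bidirectional_cycle_uniform(self):
        edges = [(f"v{i}", f"v{(i + 1) % 6}") for i in range(6)]
        edges += [(v, u) for u, v in edges]
        net = Network(edges)
        assert len(set(core_number(net).values())) == 1

    def test_pendant_below_clique(self):
        net = fixture("complete", 4)
        edges = list(net.edges()) + [("n0000", "pend"), ("pend", "n0000")]
        net2 = Network(edges)
        cores = core_number(net2)
        assert cores["pend"] < min(cores[u] for u in net.nodes)


class TestCloseness:
    def test_complete_all_one(self, complete4):
        assert all(v == pytest.approx(1.0) for v in closeness(complete4).values())

    def test_cycle_value(self, cycle5):
        assert all(v == pytest.approx(0.4) for v in closeness(cycle5).values())

    def test_not_strongly_connected_raises(self, path4):
        with pytest.raises(NotStronglyConnectedError, match="largest_scc"):
            closeness(path4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        net = random_scc(30, 0.08, seed)
        got = closeness(net)
        want = brute_closeness(net)
        for u in net.nodes:
            assert got[u] == pytest.approx(want[u])


class TestPagerank:
    def test_complete_uniform(self, complete4):
        assert all(v == pytest.approx(0.25) for v in pagerank(complete4).values())

    def test_cycle_uniform(self, cycle5):
        assert all(v == pytest.approx(0.2) for v in pagerank(cycle5).values())

    def test_sums_to_one_and_fixed_point(self):
        net = Network([("a", "b"), ("b", "a"), ("c", "a")])
        pr = pagerank(net, damping=0.85)
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)
        # residual of the pagerank fixed-point equation (dangling-free graph)
        for u in net.nodes:
            inflow = sum(
                pr[v] / len(net.successors(v))
                for v in net.nodes
                if net.has_edge(v, u)
            )
            assert pr[u] == pytest.approx(0.15 / 3 + 0.85 * inflow, abs=1e-6)

    def test_bad_damping(self, cycle5):
        with pytest.raises(ValueError):
            pagerank(cycle5, damping=1.5)


class TestEigenvector:
    def test_complete_uniform(self, complete4):
        vals = list(eigenvector(complete4).values())
        assert np.allclose(vals, 0.5)  # unit norm over 4 nodes

    def test_star_residual_and_ratio(self):
        net = fixture("star", 10)
        ev = eigenvector(net)
        hub, leaf = ev["n0000"], ev["n0001"]
        assert leaf / hub == pytest.approx(1 / np.sqrt(9), rel=1e-6)
        # residual check: A x = lam x with lam = sqrt(n-1)
        lam = np.sqrt(9)
        assert lam * hub == pytest.approx(9 * leaf, abs=1e-8)

    def test_unit_norm(self, cycle5):
        vals = np.array(list(eigenvector(cycle5).values()))
        assert np.linalg.norm(vals) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigensolver(self, seed):
        net = random_scc(30, 0.1, seed)
        got = eigenvector(net)
        # oracle: dense eigen-decomposition of the adjacency matrix
        n = net.n_nodes
        A = np.zeros((n, n))
        for u, v in net.edges():
            A[net.index[u], net.index[v]] = 1.0
        vals, vecs = np.linalg.eig(A)
        vec = np.abs(vecs[:, np.argmax(vals.real)].real)
        vec /= np.linalg.norm(vec)
        for u in net.nodes:
            assert got[u] == pytest.approx(vec[net.index[u]], abs=1e-6)

    def test_orientation_flip_on_asymmetric_graph(self):
        net = Network([("a", "b"), ("b", "c"), ("c", "a"), ("a", "c")])
        out = eigenvector(net, orientation="out")
        inn = eigenvector(net, orientation="in")
        assert out != inn

    def test_requires_strong_connectivity(self, path4):
        with pytest.raises(NotStronglyConnectedError):
            eigenvector(path4)


class TestCentralityTable:
    def test_shape_and_columns(self, cycle5):
        table = centrality_table(cycle5)
        assert tuple(table.columns) == CENTRALITY_NAMES
        assert len(table) == 5

    def test_deterministic(self):
        net = random_scc(25, 0.1, 3)
        t1 = centrality_table(net)
        t2 = centrality_table(net)
        assert t1.equals(t2)

    @pytest.mark.parametrize("name,args", [("cycle", (7,)), ("complete", (5,))])
    def test_vertex_transitive_constant_columns(self, name, args):
        table = centrality_table(fixture(name, *args))
        for col in table.columns:
            assert table[col].round(9).nunique() == 1, col

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_oracles_on_random_graphs(self, seed):
        net = random_scc(20, 0.12, seed)
        assert neighbourhood_sum(net) == brute_k_sum(net)
        assert two_hop_neighbourhood_sum(net) == brute_k_2sum(net)
        got = closeness(net)
        want = brute_closeness(net)
        assert all(got[u] == pytest.approx(want[u]) for u in net.nodes)
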