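"""The seven node centrality indicators used as ranking scores and features.

Local indicators: out-degree, neighbourhood sum (``k_sum``), two-hop
neighbourhood sum (``k_2sum``).  Global indicators: core number, closeness,
PageRank, eigenvector centrality.  Directed-graph conventions (documented per
function) follow the information-flow reading: out-edges carry influence.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph_io import Network

__all__ = [
    "out_degree",
    "neighbourhood_sum",
    "two_hop_neighbourhood_sum",
    "core_number",
    "closeness",
    "pagerank",
    "eigenvector",
    "centrality_table",
    "CENTRALITY_NAMES",
    "NotStronglyConnectedError",
    "ConvergenceError",
]

#: canonical column order of the centrality table
CENTRALITY_NAMES = (
    "degree",
    "k_sum",
    "k_2sum",
    "core",
    "closeness",
    "pagerank",
    "eigenvector",
)

POWER_TOL = 1e-10
POWER_MAX_ITER = 10_000


class NotStronglyConnectedError(ValueError):
    """Raised by distance-based centralities on non-strongly-connected input."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""


def out_degree(net: Network) -> dict[str, int]:
    """Number of out-edges per node."""
    return {u: len(net.successors(u)) for u in net.nodes}


def neighbourhood_sum(net: Network) -> dict[str, int]:
    """``k_sum``: sum of out-degrees over each node's out-neighbours."""
    deg = out_degree(net)
    return {u: sum(deg[v] for v in net.successors(u)) for u in net.nodes}


def two_hop_neighbourhood_sum(net: Network) -> dict[str, int]:
    """``k_2sum``: sum of out-degrees over nodes at directed distance
    exactly 2 (nodes at distance 0 or 1 excluded)."""
    deg = out_degree(net)
    out: dict[str, int] = {}
    for u in net.nodes:
        first = set(net.successors(u))
        second: set[str] = set()
        for v in first:
            second.update(net.successors(v))
        second -= first
        second.discard(u)
        out[u] = sum(deg[w] for w in second)
    return out


def core_number(net: Network) -> dict[str, int]:
    """Core number from iterative shell peeling on total degree (in + out);
    bidirectional edge pairs therefore count twice, the usual convention for
    directed graphs in standard graph libraries."""
    return dict(nx.core_number(net.graph))


def closeness(net: Network, orientation: str = "out") -> dict[str, float]:
    """Closeness ``(N-1) / sum_v d(u, v)`` over directed shortest paths.

    ``orientation="out"`` (default) measures distances *from* each node along
    out-edges; ``"in"`` measures distances towards it.  Requires a strongly
    connected network so that every distance is finite.
    """
    if not net.is_strongly_connected():
        raise NotStronglyConnectedError(
            "closeness requires a strongly connected network; "
            "run largest_scc first"
        )
    if orientation not in ("out", "in"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if net.n_nodes == 1:
        return {net.nodes[0]: 0.0}
    g = net.graph if orientation == "out" else net.graph.reverse(copy=False)
    n = net.n_nodes
    out: dict[str, float] = {}
    for u in net.nodes:
        total = sum(nx.single_source_shortest_path_length(g, u).values())
        out[u] = (n - 1) / total
    return out


def pagerank(net: Network, damping: float = 0.85) -> dict[str, float]:
    """PageRank by power iteration; values sum to 1."""
    if not 0 < damping < 1:
        raise ValueError("damping must lie in (0, 1)")
    try:
        pr = nx.pagerank(
            net.graph, alpha=damping, tol=POWER_TOL, max_iter=POWER_MAX_ITER
        )
    except nx.PowerIterationFailedConvergence as exc:  # pragma: no cover
        raise ConvergenceError(f"pagerank did not converge: {exc}") from exc
    return {u: pr[u] for u in net.nodes}


def eigenvector(net: Network, orientation: str = "out") -> dict[str, float]:
    """Principal-eigenvector centrality, nonnegative with unit Euclidean norm.

    With ``orientation="out"`` a node scores highly if its *out-neighbours*
    score highly (right Perron vector of the adjacency matrix), matching
    spreading reach; ``"in"`` gives the classical prestige variant.  Requires
    strong connectivity, which guarantees a unique positive Perron vector.
    """
    if orientation not in ("out", "in"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not net.is_strongly_connected():
        raise NotStronglyConnectedError(
            "eigenvector centrality requires a strongly connected network; "
            "run largest_scc first"
        )
    if net.n_edges == 0:
        # single isolated node
        return {u: 1.0 for u in net.nodes}
    n = net.n_nodes
    indptr, indices = net.out_csr()
    data = np.ones(len(indices))
    adj = sp.csr_matrix((data, indices.copy(), indptr.copy()), shape=(n, n))
    # orientation "out": right Perron vector x with A x = lambda x
    mat = adj if orientation == "out" else adj.T
    if n <= 50:
        vals, vecs = np.linalg.eig(mat.toarray())
        lead = int(np.argmax(vals.real))
        vec = vecs[:, lead].real
    else:
        v0 = np.ones(n)
        try:
            vals, vecs = spla.eigs(
                mat.astype(float), k=1, which="LR", v0=v0,
                tol=POWER_TOL, maxiter=POWER_MAX_ITER,
            )
        except spla.ArpackNoConvergence as exc:
            raise ConvergenceError(f"eigenvector solve did not converge: {exc}") from exc
        vec = vecs[:, 0].real
    if vec.sum() < 0:
        vec = -vec
    vec = np.maximum(vec, 0.0)  # clip eigensolver noise; Perron vector is nonnegative
    vec /= np.linalg.norm(vec)
    return {u: float(vec[net.index[u]]) for u in net.nodes}


def centrality_table(
    net: Network,
    damping: float = 0.85,
    closeness_orientation: str = "out",
    eigenvector_orientation: str = "out",
) -> pd.DataFrame:
    """All seven indicators as a DataFrame indexed by node label, columns in
    :data:`CENTRALITY_NAMES` order.  Deterministic given the network."""
    cols = {
        "degree": out_degree(net),
        "k_sum": neighbourhood_sum(net),
        "k_2sum": two_hop_neighbourhood_sum(net),
        "core": core_number(net),
        "closeness": closeness(net, orientation=closeness_orientation),
        "pagerank": pagerank(net, damping=damping),
        "eigenvector": eigenvector(net, orientation=eigenvector_orientation),
    }
    table = pd.DataFrame(
        {name: [cols[name][u] for u in net.nodes] for name in CENTRALITY_NAMES},
        index=pd.Index(net.nodes, name="node"),
    )
    table["degree"] = table["degree"].astype(np.int64)
    table["k_sum"] = table["k_sum"].astype(np.int64)
    table["k_2sum"] = table["k_2sum"].astype(np.int64)
    table["core"] = table["core"].astype(np.int64)
    return table
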