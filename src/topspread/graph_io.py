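"""Reading, cleaning, and canonicalizing directed networks from edge-list files.

Supports the two common plain-text dialects found in public network
repositories: ``%``-commented KONECT files (``out.*``) and ``#``-commented
SNAP ``.txt`` files.  Extra columns (weights, timestamps, attributes) are
discarded, duplicate edges are collapsed, and self-loops are dropped, so
every :class:`Network` is a simple directed graph.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Mapping
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "EdgeListParseError",
    "EmptyNetworkError",
    "read_edge_list",
    "write_edge_list",
    "largest_scc",
    "reverse_edges",
    "DEFAULT_COMMENT_CHARS",
]

DEFAULT_COMMENT_CHARS = frozenset({"%", "#"})


class EdgeListParseError(ValueError):
    """A non-comment line could not be parsed as an edge."""


class EmptyNetworkError(ValueError):
    """The input contains no nodes."""


class Network:
    """A simple directed graph with deterministic node order.

    Node labels are kept as opaque strings; ``nodes`` is sorted
    lexicographically so that the integer re-indexing ``index`` (label ->
    0..N-1) is stable across runs regardless of input order.  Self-loops and
    duplicate edges are removed on construction.
    """

    __slots__ = ("nodes", "index", "_succ", "_graph", "_csr")

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()):
        label_set = {str(u) for u in nodes}
        cleaned: set[tuple[str, str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            label_set.add(u)
            label_set.add(v)
            if u != v:
                cleaned.add((u, v))
        if not label_set:
            raise EmptyNetworkError("network has no nodes")
        self.nodes: tuple[str, ...] = tuple(sorted(label_set))
        self.index: dict[str, int] = {u: i for i, u in enumerate(self.nodes)}
        succ: dict[str, list[str]] = {u: [] for u in self.nodes}
        for u, v in sorted(cleaned):
            succ[u].append(v)
        self._succ = succ
        self._graph: nx.DiGraph | None = None
        self._csr: tuple[np.ndarray, np.ndarray] | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(vs) for vs in self._succ.values())

    def edges(self) -> Iterable[tuple[str, str]]:
        for u in self.nodes:
            for v in self._succ[u]:
                yield (u, v)

    def successors(self, u: str) -> tuple[str, ...]:
        return tuple(self._succ[u])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._succ.get(u, ())

    @property
    def graph(self) -> nx.DiGraph:
        """The network as a :class:`networkx.DiGraph` (treat as read-only)."""
        if self._graph is None:
            g = nx.DiGraph()
            g.add_nodes_from(self.nodes)
            g.add_edges_from(self.edges())
            self._graph = g
        return self._graph

    def out_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Out-adjacency in CSR form over integer node ids (indptr, indices)."""
        if self._csr is None:
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            indices = np.empty(self.n_edges, dtype=np.int64)
            k = 0
            for i, u in enumerate(self.nodes):
                for v in self._succ[u]:
                    indices[k] = self.index[v]
                    k += 1
                indptr[i + 1] = k
            self._csr = (indptr, indices)
        return self._csr

    def is_strongly_connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        return nx.is_strongly_connected(self.graph)

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "is_strongly_connected": self.is_strongly_connected(),
        }

    # -- equality / repr ---------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self._succ == other._succ

    def __hash__(self):  # pragma: no cover - not used as dict key
        return hash((self.nodes, tuple(sorted(self.edges()))))

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def read_edge_list(
    path: str | Path,
    comment_chars: Iterable[str] = DEFAULT_COMMENT_CHARS,
    drop_extra_columns: bool = True,
    undirected: bool = False,
) -> Network:
    """Parse a whitespace-separated edge list into a :class:`Network`.

    Parameters
    ----------
    path
        Edge-list file; one edge per line, first two tokens are source and
        target, further tokens (weights, timestamps) are discarded when
        ``drop_extra_columns`` is true (otherwise they raise).
    comment_chars
        Line prefixes to skip (default ``%`` and ``#``).
    undirected
        Expand each line into both edge directions (for repositories that
        store undirected graphs one line per edge).
    """
    path = Path(path)
    prefixes = tuple(comment_chars)
    edges: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(prefixes):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            if len(tokens) > 2 and not drop_extra_columns:
                raise EdgeListParseError(
                    f"{path}:{lineno}: extra columns present and drop_extra_columns=False"
                )
            u, v = tokens[0], tokens[1]
            edges.append((u, v))
            if undirected:
                edges.append((v, u))
    if not edges:
        raise EmptyNetworkError(f"{path}: no edges found")
    return Network(edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a 2-column whitespace-separated edge list (round-trips with
    :func:`read_edge_list`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for u, v in net.edges():
            fh.write(f"{u} {v}\n")


def write_summary(net: Network, path: str | Path) -> None:
    Path(path).write_text(json.dumps(net.summary(), indent=2) + "\n", encoding="utf-8")


def largest_scc(net: Network) -> Network:
    """Induced subgraph on the largest strongly connected component.

    Ties in component size are broken deterministically by the component
    containing the lexicographically smallest node label.
    """
    components = list(nx.strongly_connected_components(net.graph))
    best = min(components, key=lambda c: (-len(c), min(c)))
    keep = set(best)
    edges = [(u, v) for u, v in net.edges() if u in keep and v in keep]
    return Network(edges, nodes=keep)


def reverse_edges(net: Network) -> Network:
    """Reverse every edge; an involution on networks."""
    return Network(((v, u) for u, v in net.edges()), nodes=net.nodes)


def subgraph(net: Network, keep: Iterable[str]) -> Network:
    keep_set = {str(u) for u in keep}
    edges = [(u, v) for u, v in net.edges() if u in keep_set and v in keep_set]
    return Network(edges, nodes=keep_set)
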