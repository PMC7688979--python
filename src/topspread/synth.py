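"""Deterministic fixtures and seeded random generators with known structure.

Besides small closed-form graphs for unit tests, this module plants a
core-periphery benchmark: a moderately dense central region surrounded by
multi-star peripheral blocks whose decoy nodes have one- and two-hop
neighbourhood sums far above any core node yet low eigenvector centrality
and low spreading power.  A clique overlaid inside the core additionally
makes eigenvector centrality over-rate part of the centre.  The true top
spreaders are core nodes that jointly maximize a local neighbourhood
centrality and a global one — the structure that makes every
single-centrality ranker fail somewhere while two-centrality classifiers
succeed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .graph_io import Network, largest_scc
from .sir import SIRConfig, exact_expected_spread, influence_all, two_stage_threshold

__all__ = [
    "fixture",
    "random_network",
    "planted_benchmark",
    "BenchmarkInstance",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("star", "cycle", "path", "complete", "barbell", "two_cliques_bridge")

_BENCH_STREAM_NET = 11
_BENCH_STREAM_THRESHOLD = 12
_BENCH_STREAM_TRUTH = 13


def _label(i: int, width: int = 4, prefix: str = "n") -> str:
    return f"{prefix}{i:0{width}d}"


def _bidir(pairs):
    for u, v in pairs:
        yield (u, v)
        yield (v, u)


def _clique_edges(labels):
    return _bidir((u, v) for i, u in enumerate(labels) for v in labels[i + 1 :])


def fixture(name: str, *sizes: int) -> Network:
    """Deterministic named graphs.  Edges are bidirectional except for
    ``cycle`` and ``path``, which are one-way.

    star(n): node 0 is the hub of n-1 leaves.
    cycle(n) / path(n): one-way ring / chain.
    complete(n): all ordered pairs.
    barbell(a, b): two cliques joined directly by one bidirectional bridge.
    two_cliques_bridge(a, b): two cliques joined through a middle node.
    """
    if name == "star":
        (n,) = sizes
        if n < 2:
            raise ValueError("star needs n >= 2")
        hub = _label(0)
        return Network(_bidir((hub, _label(i)) for i in range(1, n)))
    if name == "cycle":
        (n,) = sizes
        if n < 2:
            raise ValueError("cycle needs n >= 2")
        return Network((_label(i), _label((i + 1) % n)) for i in range(n))
    if name == "path":
        (n,) = sizes
        if n < 2:
            raise ValueError("path needs n >= 2")
        return Network((_label(i), _label(i + 1)) for i in range(n - 1))
    if name == "complete":
        (n,) = sizes
        if n < 2:
            raise ValueError("complete needs n >= 2")
        labels = [_label(i) for i in range(n)]
        return Network((u, v) for u in labels for v in labels if u != v)
    if name == "barbell":
        a, b = sizes
        left = [_label(i, prefix="a") for i in range(a)]
        right = [_label(i, prefix="b") for i in range(b)]
        edges = list(_clique_edges(left)) + list(_clique_edges(right))
        edges += [(left[-1], right[0]), (right[0], left[-1])]
        return Network(edges)
    if name == "two_cliques_bridge":
        a, b = sizes
        left = [_label(i, prefix="a") for i in range(a)]
        right = [_label(i, prefix="b") for i in range(b)]
        mid = "m000"
        edges = list(_clique_edges(left)) + list(_clique_edges(right))
        edges += list(_bidir([(left[-1], mid), (mid, right[0])]))
        return Network(edges)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _core_periphery_edges(
    rng: np.random.Generator,
    n_core: int,
    core_mean_degree: float,
    n_blocks: int,
    decoys_per_block: int,
    hubs_per_block: int,
    leaves_per_hub: int,
    leaf_clique_size: int,
    bridges_per_block: int,
    core_clique_size: int,
) -> list[tuple[str, str]]:
    """Erdos-Renyi core plus multi-star peripheral blocks.

    Each block has ``decoys_per_block`` decoy nodes wired to every one of
    ``hubs_per_block`` hubs; each hub carries its own leaves, grouped into
    small cliques.  Decoys and hubs then have neighbourhood sums (one- and
    two-hop) far above the best core nodes, yet the block's spectral radius
    stays near sqrt(hub degree) — well below the core's — so eigenvector
    centrality remains concentrated in the core.  Blocks touch the core only
    through a few leaf-to-core bridge edges.
    """
    core = [_label(i, prefix="c") for i in range(n_core)]
    p_core = core_mean_degree / (n_core - 1)
    edges: list[tuple[str, str]] = []
    for i in range(n_core):
        for j in range(i + 1, n_core):
            if rng.random() < p_core:
                edges.extend(_bidir([(core[i], core[j])]))
    if core_clique_size:
        # clique overlaid on random core nodes: eigenvector centrality
        # localizes around it, but SIR influence discounts its redundant
        # internal paths, so eigencentrality over-rates its surroundings
        chosen = rng.choice(n_core, size=core_clique_size, replace=False)
        edges.extend(_clique_edges([core[int(i)] for i in chosen]))
    for b in range(n_blocks):
        decoys = [_label(i, prefix=f"p{b:02d}d") for i in range(decoys_per_block)]
        hubs = [_label(i, prefix=f"p{b:02d}h") for i in range(hubs_per_block)]
        leaves: list[str] = []
        for h, hub in enumerate(hubs):
            hub_leaves = [
                _label(h * leaves_per_hub + i, prefix=f"p{b:02d}l")
                for i in range(leaves_per_hub)
            ]
            leaves.extend(hub_leaves)
            edges.extend(_bidir((hub, leaf) for leaf in hub_leaves))
            for start in range(0, leaves_per_hub, leaf_clique_size):
                edges.extend(_clique_edges(hub_leaves[start : start + leaf_clique_size]))
        # decoy -> hub edges are one-way: decoys inherit the hubs' large
        # out-neighbourhoods without letting an outbreak cascade hub-to-hub
        # through the decoys; one return edge per decoy closes the SCC
        edges.extend((d, hub) for d in decoys for hub in hubs)
        for i, d in enumerate(decoys):
            edges.append((hubs[i % hubs_per_block], d))
        anchors = rng.choice(n_core, size=bridges_per_block, replace=False)
        gates = rng.choice(len(leaves), size=bridges_per_block, replace=False)
        for a, g in zip(anchors, gates):
            edges.extend(_bidir([(leaves[int(g)], core[int(a)])]))
    return edges


def random_network(model: str, params: Mapping | None = None, rng_seed: int = 0) -> Network:
    """Seeded random graphs (bidirectional edges), reduced to their largest
    SCC.  Models: ``erdos_renyi`` (n, mean_degree), ``scale_free`` (n, m),
    ``core_periphery`` (see :func:`planted_benchmark` for defaults)."""
    params = dict(params or {})
    min_scc = params.pop("min_scc_fraction", 0.5)
    if model == "erdos_renyi":
        n = params.pop("n", 500)
        mean_degree = params.pop("mean_degree", 6.0)
        _reject_extras(model, params)
        g = nx.fast_gnp_random_graph(n, mean_degree / (n - 1), seed=int(rng_seed))
        edges = _bidir((_label(u), _label(v)) for u, v in g.edges())
        net = Network(edges, nodes=[_label(i) for i in range(n)])
    elif model == "scale_free":
        n = params.pop("n", 1000)
        m = params.pop("m", 2)
        _reject_extras(model, params)
        g = nx.barabasi_albert_graph(n, m, seed=int(rng_seed))
        net = Network(_bidir((_label(u), _label(v)) for u, v in g.edges()))
    elif model == "core_periphery":
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), _BENCH_STREAM_NET]))
        kwargs = dict(
            n_core=params.pop("n_core", 250),
            core_mean_degree=params.pop("core_mean_degree", 7.0),
            n_blocks=params.pop("n_blocks", 2),
            decoys_per_block=params.pop("decoys_per_block", 10),
            hubs_per_block=params.pop("hubs_per_block", 6),
            leaves_per_hub=params.pop("leaves_per_hub", 18),
            leaf_clique_size=params.pop("leaf_clique_size", 6),
            bridges_per_block=params.pop("bridges_per_block", 2),
            core_clique_size=params.pop("core_clique_size", 13),
        )
        _reject_extras(model, params)
        net = Network(_core_periphery_edges(rng, **kwargs))
    else:
        raise ValueError(f"unknown model {model!r}")
    scc = largest_scc(net)
    if scc.n_nodes < min_scc * net.n_nodes:
        raise ValueError(
            f"largest SCC has {scc.n_nodes}/{net.n_nodes} nodes; "
            "use denser parameters"
        )
    return scc


@dataclass(frozen=True)
class BenchmarkInstance:
    """A generated network with ground-truth influence at its estimated
    epidemic threshold."""

    net: Network
    influence_truth: dict[str, float]
    generator_params: dict
    rng_seed: int
    lam_c: float


def planted_benchmark(
    params: Mapping | None = None, rng_seed: int = 0
) -> BenchmarkInstance:
    """Core-periphery network plus ground-truth influence at the estimated
    threshold.

    Truth comes from the exact jump-chain expectation when the graph has at
    most 12 nodes, and otherwise from Monte Carlo on an independent random
    stream with ``truth_runs`` runs per node (default 10x the threshold-scan
    sampling effort).
    """
    params = dict(params or {})
    truth_runs = int(params.pop("truth_runs", 100_000))
    lam_scale = float(params.pop("lam_scale", 1.0))
    gen_params = {
        "n_core": int(params.pop("n_core", 250)),
        "core_mean_degree": float(params.pop("core_mean_degree", 7.0)),
        "n_blocks": int(params.pop("n_blocks", 2)),
        "decoys_per_block": int(params.pop("decoys_per_block", 10)),
        "hubs_per_block": int(params.pop("hubs_per_block", 6)),
        "leaves_per_hub": int(params.pop("leaves_per_hub", 18)),
        "leaf_clique_size": int(params.pop("leaf_clique_size", 6)),
        "bridges_per_block": int(params.pop("bridges_per_block", 2)),
        "core_clique_size": int(params.pop("core_clique_size", 13)),
    }
    if params:
        raise TypeError(f"unknown benchmark params: {sorted(params)}")
    net = random_network("core_periphery", gen_params, rng_seed=rng_seed)
    if net.n_nodes <= 12:
        lam_c = 1.0
        truth = {u: exact_expected_spread(net, u, lam_c * lam_scale) for u in net.nodes}
    else:
        scan_cfg = SIRConfig(
            lam=0.0, seed_sample_size=min(2000, net.n_nodes),
            rng_seed=(rng_seed << 4) + _BENCH_STREAM_THRESHOLD,
        )
        _, fine = two_stage_threshold(net, scan_cfg, lam_min=0.01, lam_max=1.0)
        lam_c = fine.lam_c
        truth_cfg = SIRConfig(
            lam=lam_c * lam_scale,
            runs_per_node=truth_runs,
            rng_seed=(rng_seed << 4) + _BENCH_STREAM_TRUTH,
        )
        infl = influence_all(net, truth_cfg)
        truth = infl["mean_spread"].to_dict()
    return BenchmarkInstance(
        net=net,
        influence_truth=truth,
        generator_params={**gen_params, "truth_runs": truth_runs, "lam_scale": lam_scale},
        rng_seed=rng_seed,
        lam_c=lam_c,
    )


def _reject_extras(model: str, params: Mapping) -> None:
    if params:
        raise TypeError(f"unknown params for {model}: {sorted(params)}")
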