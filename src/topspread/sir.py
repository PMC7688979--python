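"""Continuous-time SIR simulation, per-node influence, and threshold scans.

The SIR process runs in continuous time: an infectious node recovers after an
exponential(mu) holding time and, while infectious, transmits along each
out-edge to a susceptible neighbour after an independent exponential(beta)
time, with beta = lam * mu.  Because the *final* outbreak size does not
depend on the temporal ordering of events, a run is realized by comparing
the per-edge transmission clocks against the source's recovery clock during
a traversal from the seed, which is equivalent to an event-driven (Gillespie)
simulation in distribution of the final size.

Reproducibility: every stochastic routine derives its random streams from an
integer root seed via ``numpy.random.SeedSequence``, keyed per node, so
results are independent of execution order and worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .graph_io import Network

__all__ = [
    "SIRConfig",
    "ThresholdScan",
    "sir_run",
    "exact_expected_spread",
    "influence_all",
    "delta_variability",
    "epidemic_threshold",
    "two_stage_threshold",
]

EXACT_MAX_NODES = 12

# stream-domain tags keeping per-purpose substreams disjoint
_STREAM_INFLUENCE = 0
_STREAM_DELTA = 1


@dataclass(frozen=True)
class SIRConfig:
    """Parameters of the SIR experiment.

    lam is the effective transmission ratio beta/mu; mu defaults to 1 so lam
    is the single control parameter.
    """

    lam: float
    mu: float = 1.0
    runs_per_node: int = 10_000
    seed_sample_size: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.runs_per_node < 1 or self.seed_sample_size < 1:
            raise ValueError("run counts must be positive")

    def with_lam(self, lam: float) -> "SIRConfig":
        return replace(self, lam=lam)


@dataclass(frozen=True)
class ThresholdScan:
    """Result of a variability scan over a lambda grid."""

    lam_grid: tuple[float, ...]
    delta_values: tuple[float, ...]
    lam_c: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lam": self.lam_grid, "delta": self.delta_values})


def _sizes_batch_py(
    indptr: np.ndarray,
    indices: np.ndarray,
    seeds: np.ndarray,
    beta: float,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reference implementation of a batch of SIR runs (one per seed).

    Draw-for-draw identical to the compiled kernel: per infected node, one
    recovery time then one transmission time per out-edge, in CSR order.
    """
    n = indptr.shape[0] - 1
    out = np.empty(seeds.shape[0], dtype=np.int64)
    if beta == 0.0:
        out[:] = 1
        return out
    scale_r = 1.0 / mu
    scale_t = 1.0 / beta
    infected = np.zeros(n, dtype=bool)
    for k, seed_idx in enumerate(seeds):
        members = [int(seed_idx)]
        infected[seed_idx] = True
        stack = [int(seed_idx)]
        while stack:
            u = stack.pop()
            a, b = indptr[u], indptr[u + 1]
            if a == b:
                continue
            recovery = rng.exponential(scale_r)
            times = rng.exponential(scale_t, b - a)
            for v in indices[a:b][times < recovery]:
                if not infected[v]:
                    infected[v] = True
                    members.append(int(v))
                    stack.append(int(v))
        out[k] = len(members)
        for v in members:
            infected[v] = False
    return out


try:  # compiled fast path; the pure-NumPy reference stays authoritative
    import numba as _numba

    @_numba.njit(cache=True)
    def _sizes_batch_numba(indptr, indices, seeds, beta, mu, rng):  # pragma: no cover
        n = indptr.shape[0] - 1
        out = np.empty(seeds.shape[0], dtype=np.int64)
        if beta == 0.0:
            out[:] = 1
            return out
        scale_r = 1.0 / mu
        scale_t = 1.0 / beta
        infected = np.zeros(n, dtype=np.bool_)
        stack = np.empty(n, dtype=np.int64)
        members = np.empty(n, dtype=np.int64)
        for k in range(seeds.shape[0]):
            seed_idx = seeds[k]
            infected[seed_idx] = True
            stack[0] = seed_idx
            members[0] = seed_idx
            top = 1
            count = 1
            while top > 0:
                top -= 1
                u = stack[top]
                a = indptr[u]
                b = indptr[u + 1]
                if a == b:
                    continue
                recovery = rng.exponential(scale_r)
                for e in range(a, b):
                    t = rng.exponential(scale_t)
                    if t < recovery:
                        v = indices[e]
                        if not infected[v]:
                            infected[v] = True
                            members[count] = v
                            count += 1
                            stack[top] = v
                            top += 1
            out[k] = count
            for j in range(count):
                infected[members[j]] = False
        return out

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _sizes_batch(
    indptr: np.ndarray,
    indices: np.ndarray,
    seeds: np.ndarray,
    beta: float,
    mu: float,
    rng: np.random.Generator,
    backend: str = "auto",
) -> np.ndarray:
    if backend == "numba" or (backend == "auto" and HAVE_NUMBA):
        return _sizes_batch_numba(indptr, indices, np.asarray(seeds, np.int64), beta, mu, rng)
    return _sizes_batch_py(indptr, indices, np.asarray(seeds, np.int64), beta, mu, rng)


def _run_core(
    indptr: np.ndarray,
    indices: np.ndarray,
    seed_idx: int,
    beta: float,
    mu: float,
    rng: np.random.Generator,
) -> int:
    """One SIR realization; returns the ever-infected count (seed included)."""
    return int(_sizes_batch(indptr, indices, np.asarray([seed_idx]), beta, mu, rng)[0])


def sir_run(
    net: Network, seed_node: str, cfg: SIRConfig, rng: np.random.Generator
) -> int:
    """Simulate one outbreak seeded at ``seed_node``; return its final size."""
    seed_node = str(seed_node)
    if seed_node not in net.index:
        raise KeyError(f"seed node {seed_node!r} not in network")
    indptr, indices = net.out_csr()
    return _run_core(indptr, indices, net.index[seed_node], cfg.lam * cfg.mu, cfg.mu, rng)


def exact_expected_spread(net: Network, seed_node: str, lam: float) -> float:
    """Exact expected final outbreak size on small graphs (<= 12 nodes).

    Enumerates the embedded jump chain of the continuous-time process: from a
    state (susceptible set S, infectious set I) each candidate event — one
    specific transmission along an open edge, or one specific recovery —
    fires next with probability proportional to its rate.  Expectations are
    accumulated over all absorbing paths with memoization on bitmask states.
    Only the ratio lam = beta/mu matters, so mu is normalized away.
    """
    n = net.n_nodes
    if n > EXACT_MAX_NODES:
        raise ValueError(f"exact enumeration limited to {EXACT_MAX_NODES} nodes, got {n}")
    seed_node = str(seed_node)
    if seed_node not in net.index:
        raise KeyError(f"seed node {seed_node!r} not in network")
    out_mask = [0] * n
    for u in net.nodes:
        ui = net.index[u]
        for v in net.successors(u):
            out_mask[ui] |= 1 << net.index[v]
    seed = net.index[seed_node]
    full = (1 << n) - 1

    @lru_cache(maxsize=None)
    def expected(s_mask: int, i_mask: int) -> float:
        if i_mask == 0:
            return float(n - bin(s_mask).count("1"))
        n_inf = bin(i_mask).count("1")
        total_rate = float(n_inf)  # recoveries, rate mu=1 each
        open_edges: list[tuple[int, int]] = []
        m = i_mask
        while m:
            u = (m & -m).bit_length() - 1
            m &= m - 1
            targets = out_mask[u] & s_mask
            while targets:
                v = (targets & -targets).bit_length() - 1
                targets &= targets - 1
                open_edges.append((u, v))
        total_rate += lam * len(open_edges)
        acc = 0.0
        m = i_mask
        while m:
            u = (m & -m).bit_length() - 1
            m &= m - 1
            acc += expected(s_mask, i_mask & ~(1 << u))  # recovery of u
        for _, v in open_edges:
            acc_edge = expected(s_mask & ~(1 << v), i_mask | (1 << v))
            acc += lam * acc_edge
        return acc / total_rate

    if lam == 0:
        return 1.0
    return expected(full & ~(1 << seed), 1 << seed)


def _node_rng(root_seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), stream, *key]))


def _influence_one(
    indptr: np.ndarray,
    indices: np.ndarray,
    node_idx: int,
    beta: float,
    mu: float,
    runs: int,
    root_seed: int,
) -> tuple[float, float]:
    rng = _node_rng(root_seed, _STREAM_INFLUENCE, node_idx)
    seeds = np.full(runs, node_idx, dtype=np.int64)
    sizes = _sizes_batch(indptr, indices, seeds, beta, mu, rng)
    mean = float(sizes.mean())
    stderr = float(sizes.std(ddof=1) / np.sqrt(runs)) if runs > 1 else 0.0
    return mean, stderr


def influence_all(
    net: Network,
    cfg: SIRConfig,
    node_subset: Sequence[str] | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Mean SIR spread size (and Monte-Carlo standard error) per seed node.

    Runs ``cfg.runs_per_node`` independent outbreaks from each requested
    node.  Each node has its own seed-derived random stream, so the result is
    bit-identical for any ``workers`` value given the same ``rng_seed``.
    """
    if node_subset is None:
        nodes = list(net.nodes)
    else:
        nodes = [str(u) for u in node_subset]
        missing = [u for u in nodes if u not in net.index]
        if missing:
            raise KeyError(f"nodes not in network: {missing[:5]}")
    indptr, indices = net.out_csr()
    beta = cfg.lam * cfg.mu
    args = [(indptr, indices, net.index[u], beta, cfg.mu, cfg.runs_per_node, cfg.rng_seed) for u in nodes]
    if workers == 1:
        results = [_influence_one(*a) for a in args]
    else:
        results = Parallel(n_jobs=workers)(delayed(_influence_one)(*a) for a in args)
    means = [r[0] for r in results]
    errs = [r[1] for r in results]
    return pd.DataFrame(
        {"mean_spread": means, "stderr": errs, "runs": cfg.runs_per_node},
        index=pd.Index(nodes, name="node"),
    )


def delta_variability(
    net: Network, lam: float, cfg: SIRConfig, rng: np.random.Generator
) -> float:
    """Coefficient of variation Delta = std(rho) / mean(rho) of outbreak
    sizes, one run each from a uniform random sample (without replacement) of
    min(seed_sample_size, N) seed nodes."""
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    n = net.n_nodes
    m = min(cfg.seed_sample_size, n)
    if m < 2:
        raise ValueError("need at least 2 seed samples to estimate variability")
    seeds = rng.choice(n, size=m, replace=False)
    indptr, indices = net.out_csr()
    beta = lam * cfg.mu
    sizes = _sizes_batch(indptr, indices, seeds, beta, cfg.mu, rng)
    mean = sizes.mean()
    return float(np.sqrt(np.maximum(np.mean(sizes.astype(float) ** 2) - mean**2, 0.0)) / mean)


def epidemic_threshold(
    net: Network, lam_grid: Sequence[float], cfg: SIRConfig
) -> ThresholdScan:
    """Scan Delta over a lambda grid; the threshold estimate ``lam_c`` is the
    grid argmax (ties -> smallest lambda)."""
    grid = [float(x) for x in lam_grid]
    if len(grid) < 3:
        raise ValueError("lam grid needs at least 3 points")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("lam grid must be strictly increasing")
    deltas = []
    for i, lam in enumerate(grid):
        rng = _node_rng(cfg.rng_seed, _STREAM_DELTA, i)
        deltas.append(delta_variability(net, lam, cfg, rng))
    lam_c = grid[int(np.argmax(deltas))]
    return ThresholdScan(tuple(grid), tuple(deltas), lam_c)


def two_stage_threshold(
    net: Network,
    cfg: SIRConfig,
    lam_min: float,
    lam_max: float,
    coarse_points: int = 10,
    fine_points: int = 11,
) -> tuple[ThresholdScan, ThresholdScan]:
    """Coarse geometric scan over [lam_min, lam_max], then a fine linear scan
    bracketing the coarse peak.  Returns (coarse, fine); use ``fine.lam_c``."""
    if not 0 < lam_min < lam_max:
        raise ValueError("need 0 < lam_min < lam_max")
    coarse_grid = np.geomspace(lam_min, lam_max, coarse_points)
    coarse = epidemic_threshold(net, coarse_grid, cfg)
    i = list(coarse.lam_grid).index(coarse.lam_c)
    lo = coarse.lam_grid[max(i - 1, 0)]
    hi = coarse.lam_grid[min(i + 1, len(coarse.lam_grid) - 1)]
    if lo == hi:  # degenerate single-point bracket
        lo, hi = 0.5 * lo, 1.5 * hi
    fine_grid = np.linspace(lo, hi, fine_points)
    fine = epidemic_threshold(net, fine_grid, cfg)
    return coarse, fine
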