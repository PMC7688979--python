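"""Single-centrality ranking of candidate spreaders and its evaluation.

A ranker predicts the top fraction f of nodes by one centrality score; ties
at the selection boundary are resolved by a uniform random draw.  Evaluation
uses the recognition rate r(f) (a recall over the true top-f set by
influence) and the precision function p(f) (ratio of mean influences,
capped at 1), with bootstrap means and 95% percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "RankEval",
    "quota",
    "top_fraction",
    "recognition_rate",
    "precision_function",
    "bootstrap_rank_eval",
]


@dataclass(frozen=True)
class RankEval:
    f: float
    centrality_name: str
    r_mean: float
    r_ci95: tuple[float, float]
    p_mean: float
    p_ci95: tuple[float, float]
    bootstrap_B: int


def quota(f: float, n: int) -> int:
    """Top-set size: round-half-up of f*n, floored at 1."""
    if not 0 < f <= 1:
        raise ValueError("f must lie in (0, 1]")
    return max(1, int(np.floor(f * n + 0.5)))


def _ordered(scores: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    labels = sorted(scores)
    return labels, np.asarray([scores[u] for u in labels], dtype=float)


def top_fraction(
    scores: Mapping[str, float], f: float, rng: np.random.Generator
) -> set[str]:
    """The round(f*N) highest-scoring nodes; boundary ties filled uniformly
    at random from the tied nodes."""
    if not scores:
        raise ValueError("scores must be nonempty")
    labels, values = _ordered(scores)
    k = quota(f, len(labels))
    order = np.argsort(-values, kind="stable")
    boundary = values[order[k - 1]]
    above = [labels[i] for i in order if values[i] > boundary]
    tied = [labels[i] for i in order if values[i] == boundary]
    fill = k - len(above)
    chosen = list(above)
    if fill > 0:
        chosen.extend(rng.choice(np.asarray(tied, dtype=object), size=fill, replace=False))
    return set(map(str, chosen))


def deterministic_top(scores: Mapping[str, float], f: float) -> set[str]:
    """Top-f set with ties broken by node label (used for influence ground
    truth, where Monte-Carlo means make ties measure-zero anyway)."""
    labels = sorted(scores)
    k = quota(f, len(labels))
    order = sorted(labels, key=lambda u: (-scores[u], u))
    return set(order[:k])


def recognition_rate(true_top: set[str], predicted: set[str]) -> float:
    """|true ∩ predicted| / |true|."""
    if not true_top:
        raise ValueError("true_top must be nonempty")
    return len(true_top & predicted) / len(true_top)


def precision_function(
    true_top: set[str], predicted: set[str], influence: Mapping[str, float]
) -> float:
    """Mean influence of predicted over mean influence of the true top,
    capped at 1.0."""
    if not true_top or not predicted:
        raise ValueError("both node sets must be nonempty")
    num = float(np.mean([influence[u] for u in predicted]))
    den = float(np.mean([influence[u] for u in true_top]))
    return min(num / den, 1.0)


def bootstrap_rank_eval(
    scores: Mapping[str, float],
    influence: Mapping[str, float],
    f: float,
    centrality_name: str = "",
    B: int = 100,
    rng: np.random.Generator | None = None,
    mode: str = "within",
) -> RankEval:
    """Bootstrap evaluation of a single-centrality ranker.

    B times, N node labels are drawn uniformly with replacement and
    deduplicated; with ``mode="within"`` (default) the ranker and the true
    top-f set are re-derived inside each unique-node resample, while
    ``mode="global"`` intersects fixed full-network top sets with the
    resample.  Reports means and empirical 2.5/97.5 percentiles.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if mode not in ("within", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    labels = np.asarray(sorted(scores), dtype=object)
    n = len(labels)
    if mode == "global":
        global_pred = top_fraction(scores, f, rng)
        global_true = deterministic_top(influence, f)
    r_vals = np.empty(B)
    p_vals = np.empty(B)
    for b in range(B):
        sample = rng.choice(labels, size=n, replace=True)
        unique = sorted(set(map(str, sample)))
        if mode == "within":
            sub_scores = {u: scores[u] for u in unique}
            sub_infl = {u: influence[u] for u in unique}
            pred = top_fraction(sub_scores, f, rng)
            true = deterministic_top(sub_infl, f)
        else:
            uset = set(unique)
            pred = global_pred & uset
            true = global_true & uset
            if not true or not pred:
                # resample missed the whole top set; count as a total miss
                r_vals[b] = 0.0
                p_vals[b] = 0.0
                continue
        r_vals[b] = recognition_rate(true, pred)
        p_vals[b] = precision_function(true, pred, influence)
    return RankEval(
        f=f,
        centrality_name=centrality_name,
        r_mean=float(r_vals.mean()),
        r_ci95=(float(np.percentile(r_vals, 2.5)), float(np.percentile(r_vals, 97.5))),
        p_mean=float(p_vals.mean()),
        p_ci95=(float(np.percentile(p_vals, 2.5)), float(np.percentile(p_vals, 97.5))),
        bootstrap_B=B,
    )
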