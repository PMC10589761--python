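"""Per-trial processing measures derived from predicted form and meaning vectors.

Five measures, all computed from the state of the mappings *before* any
trial-level update:

* semantic density — mean cosine similarity of the predicted semantic vector
  to its n closest lexical semantic vectors (default n = 10);
* form-driven semantic relatedness — length of the shortest closed tour (in
  Euclidean distance) through the predicted semantic vectors of the stimulus
  and its Coltheart neighbours;
* c-precision — Pearson correlation between the original cue vector and the
  form vector regenerated through the production feedback loop;
* cue activation diversity — L1 norm of the regenerated form vector;
* yes-activation — scalar support for a "word" response, ``c @ D``
  (meaningful only in simulations with learning, since D starts at zero).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

#: measures default to the paper-style 10 nearest semantic neighbours
DEFAULT_DENSITY_TOP = 10
#: exact Held-Karp tour search up to this many points, heuristic beyond
DEFAULT_TOUR_BUDGET = 12


class UndefinedMeasureError(ValueError):
    """Raised when a measure is mathematically undefined for its input."""


def semantic_density(s_hat: np.ndarray, S: np.ndarray, n_top: int = DEFAULT_DENSITY_TOP) -> float:
    """Mean of the ``n_top`` largest cosine similarities of ``s_hat`` to rows of S."""
    s_hat = np.asarray(s_hat, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if not 1 <= n_top <= S.shape[0]:
        raise ValueError(f"n_top={n_top} out of range for {S.shape[0]} rows")
    norm = np.linalg.norm(s_hat)
    if norm == 0.0:
        raise UndefinedMeasureError("cosine undefined for zero predicted vector")
    row_norms = np.linalg.norm(S, axis=1)
    if np.any(row_norms == 0.0):
        raise UndefinedMeasureError("cosine undefined for zero semantic vectors")
    cos = (S @ s_hat) / (row_norms * norm)
    if n_top == S.shape[0]:
        return float(cos.mean())
    top = np.partition(cos, len(cos) - n_top)[-n_top:]
    return float(top.mean())


def _held_karp_cycle(dist: np.ndarray) -> float:
    """Exact shortest closed tour through all points (dynamic programming)."""
    m = dist.shape[0]
    if m == 1:
        return 0.0
    if m == 2:
        return float(2.0 * dist[0, 1])
    # dp[mask][j]: shortest path from node 0 visiting 'mask' and ending at j
    full = 1 << (m - 1)  # masks over nodes 1..m-1
    dp = np.full((full, m - 1), np.inf)
    for j in range(m - 1):
        dp[1 << j, j] = dist[0, j + 1]
    for mask in range(full):
        row = dp[mask]
        for j in range(m - 1):
            cur = row[j]
            if not np.isfinite(cur) or not mask & (1 << j):
                continue
            for k in range(m - 1):
                if mask & (1 << k):
                    continue
                nxt = mask | (1 << k)
                cand = cur + dist[j + 1, k + 1]
                if cand < dp[nxt, k]:
                    dp[nxt, k] = cand
    last = dp[full - 1] + dist[1:, 0]
    return float(last.min())


def _heuristic_cycle(dist: np.ndarray) -> float:
    """Nearest-neighbour construction plus 2-opt improvement (upper bound)."""
    m = dist.shape[0]
    unvisited = set(range(1, m))
    tour = [0]
    while unvisited:
        j = min(unvisited, key=lambda k: dist[tour[-1], k])
        tour.append(j)
        unvisited.remove(j)
    improved = True
    while improved:
        improved = False
        for i, j in itertools.combinations(range(1, m), 2):
            a, b = tour[i - 1], tour[i]
            c, d = tour[j], tour[(j + 1) % m]
            if dist[a, c] + dist[b, d] < dist[a, b] + dist[c, d] - 1e-12:
                tour[i : j + 1] = tour[i : j + 1][::-1]
                improved = True
    return float(sum(dist[tour[i], tour[(i + 1) % m]] for i in range(m)))


def form_driven_semantic_relatedness(
    s_hat_target: np.ndarray,
    s_hat_neighbours: np.ndarray | None,
    closed: bool = True,
    exact_budget: int = DEFAULT_TOUR_BUDGET,
) -> tuple[float, int]:
    """Shortest tour length through the target and neighbour predicted vectors.

    Returns ``(length, has_neighbours_path)``.  With no orthographic
    neighbours there is no path: ``(0.0, 0)``.  The tour is closed (returns
    to its start) by default; ``closed=False`` evaluates the open-path
    variant instead.  Instances up to ``exact_budget`` points are solved
    exactly by Held-Karp dynamic programming; larger ones fall back to a
    nearest-neighbour + 2-opt heuristic (logged).
    """
    if s_hat_neighbours is None or len(s_hat_neighbours) == 0:
        return 0.0, 0
    pts = np.vstack([np.atleast_2d(s_hat_target), np.atleast_2d(s_hat_neighbours)])
    m = pts.shape[0]
    dist = squareform(pdist(pts))
    if not closed:
        return _shortest_open_path(dist), 1
    if m <= exact_budget:
        return _held_karp_cycle(dist), 1
    logger.warning("tour with %d points exceeds exact budget %d; using heuristic", m, exact_budget)
    return _heuristic_cycle(dist), 1


def _shortest_open_path(dist: np.ndarray) -> float:
    """Exact shortest open Hamiltonian path (brute force; small inputs only)."""
    m = dist.shape[0]
    if m == 1:
        return 0.0
    best = np.inf
    for perm in itertools.permutations(range(1, m)):
        order = (0,) + perm
        length = sum(dist[order[i], order[i + 1]] for i in range(m - 1))
        best = min(best, length)
    return float(best)


def c_precision(c: np.ndarray, c_hat: np.ndarray) -> float:
    """Pearson correlation between the cue vector and its feedback reconstruction."""
    c = np.asarray(c, dtype=np.float64)
    c_hat = np.asarray(c_hat, dtype=np.float64)
    if c.shape != c_hat.shape or c.size < 2:
        raise ValueError("equal-length vectors of size >= 2 required")
    if np.ptp(c) == 0.0 or np.ptp(c_hat) == 0.0:
        raise UndefinedMeasureError("correlation undefined for constant vector")
    return float(pearsonr(c, c_hat).statistic)


def cue_activation_diversity(c_hat: np.ndarray) -> float:
    """L1 norm of the predicted form vector; gauges its uncertainty."""
    return float(np.abs(np.asarray(c_hat, dtype=np.float64)).sum())


def yes_activation(c: np.ndarray, D: np.ndarray) -> float:
    """Bottom-up support for a "word" outcome: ``c @ D``."""
    c = np.asarray(c, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    if c.shape != D.shape:
        raise ValueError(f"shape mismatch: {c.shape} vs {D.shape}")
    return float(c @ D)
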