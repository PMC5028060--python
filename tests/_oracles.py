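"""Independent brute-force oracles for path-based centrality indices.

Enumerates every simple path between each ordered node pair (at most 16 per
pair on a 5-node digraph), so shortest distances, minimal-path counts,
closeness and fractional betweenness follow by exhaustive inspection --
entirely independent of the Dijkstra/Brandes implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_paths(D: np.ndarray, s: int, t: int) -> list[tuple[float, tuple]]:
    """All finite-length simple paths s -> t as (distance, node tuple)."""
    n = D.shape[0]
    inner = [v for v in range(n) if v not in (s, t)]
    paths = []
    for k in range(len(inner) + 1):
        for mid in itertools.permutations(inner, k):
            nodes = (s, *mid, t)
            d = 0.0
            for a, b in zip(nodes, nodes[1:]):
                d += D[a, b]
                if not np.isfinite(d):
                    break
            if np.isfinite(d):
                paths.append((d, nodes))
    return paths


def brute_force_centrality(D: np.ndarray, tol: float = 1e-9):
    """(distances, path counts, closeness, betweenness) by full enumeration."""
    n = D.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = enumerate_paths(D, s, t)
            if not paths:
                continue
            dmin = min(d for d, _ in paths)
            minimal = [nodes for d, nodes in paths if d <= dmin + tol]
            dist[s, t] = dmin
            counts[s, t] = len(minimal)
            for nodes in minimal:
                for v in nodes[1:-1]:
                    bc[v] += 1.0 / len(minimal)
    clos = np.zeros(n)
    for v in range(n):
        others = np.delete(dist[v], v)
        total = others.sum()
        clos[v] = 0.0 if np.isinf(total) else 1.0 / total
    return dist, counts, clos, bc


def random_weight_matrix(rng: np.random.Generator, n: int = 5,
                         zero_frac: float = 0.3) -> np.ndarray:
    """Random signed weights U(-1, 1) with a fraction zeroed (no edge)."""
    W = rng.uniform(-1.0, 1.0, size=(n, n))
    W[rng.random((n, n)) < zero_frac] = 0.0
    return W
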