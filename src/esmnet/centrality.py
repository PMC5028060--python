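"""Centrality indices for weighted directed symptom networks with self-loops.

Strength indices sum absolute edge weights: the inward strength of a node is
the sum of weights into it, the outward strength the sum of weights out of
it, and node strength their total -- the self-loop belongs to both, so it
counts twice in node strength.  Path-based indices use the distance
``d = 1 / |w|`` per edge (strong edges are short); self-loops never
participate in paths.  Closeness of a node is the inverse of the summed
shortest distances from it to all other nodes (0 if any node is
unreachable); betweenness is the fractional (Brandes) count of shortest
paths between other node pairs passing through the node, with ties in path
length detected to a 1e-12 tolerance.

Edge signs (networks contain negative coefficients) are kept for display but
all centrality computations use magnitudes; a weight of exactly 0 -- or below
an optional threshold -- means "no edge".
"""

from __future__ import annotations

import heapq
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SYMPTOMS, EsmError

_TIE_TOL = 1e-12


def _as_matrix(network) -> np.ndarray:
    """Accept a SymptomNetwork or a square array; W[i][j] = edge j -> i."""
    W = getattr(network, "W", network)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise EsmError("adjacency must be a square matrix")
    if not np.isfinite(W).all():
        raise EsmError("adjacency contains non-finite entries")
    return W


def _labels(n: int) -> list[str]:
    return list(SYMPTOMS) if n == len(SYMPTOMS) else [str(i) for i in range(n)]


def strengths(network) -> pd.DataFrame:
    """Inward, outward and node strength per node (absolute weights).

    inward(v) = sum_u |W[v][u]| and outward(v) = sum_u |W[u][v]|, both
    including the self-loop, so node strength counts it twice.
    """
    W = np.abs(_as_matrix(network))
    inward = W.sum(axis=1)
    outward = W.sum(axis=0)
    return pd.DataFrame(
        {
            "inward_strength": inward,
            "outward_strength": outward,
            "node_strength": inward + outward,
        },
        index=_labels(W.shape[0]),
    )


def distance_matrix(network, threshold: float = 0.0) -> np.ndarray:
    """Edge distances D[source][target] = 1/|W[target][source]|.

    Self-loops are excluded; absent edges (|w| = 0, or |w| <= threshold when
    a positive threshold is given) are +inf.
    """
    W = np.abs(_as_matrix(network))
    with np.errstate(divide="ignore"):
        D = 1.0 / W.T  # transpose: rows become sources
    D[W.T <= threshold] = np.inf
    np.fill_diagonal(D, np.inf)
    return D


def _dijkstra(D: np.ndarray, source: int,
              tol: float = _TIE_TOL) -> tuple[np.ndarray, np.ndarray,
                                              list[list[int]], list[int]]:
    """Single-source shortest paths with minimal-path counting.

    Returns (distances, path counts, predecessor lists, settle order).
    Distances must be positive (guards corrupted input).
    """
    n = D.shape[0]
    finite = D[np.isfinite(D)]
    if finite.size and (finite <= 0).any():
        raise EsmError("edge distances must be positive")
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[source] = 0.0
    sigma[source] = 1.0
    settled = np.zeros(n, dtype=bool)
    order: list[int] = []
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if settled[u] or d > dist[u] + tol:
            continue
        settled[u] = True
        order.append(u)
        for v in range(n):
            w = D[u, v]
            if not np.isfinite(w) or settled[v]:
                continue
            nd = d + w
            if nd < dist[v] - tol:
                dist[v] = nd
                sigma[v] = sigma[u]
                preds[v] = [u]
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= tol:
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def shortest_paths(D: np.ndarray,
                   tol: float = _TIE_TOL) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest distances and minimal-path multiplicities.

    ``D`` is an edge-distance matrix as from :func:`distance_matrix`;
    unreachable pairs have distance +inf and multiplicity 0.
    """
    n = D.shape[0]
    dists = np.empty((n, n))
    counts = np.empty((n, n))
    for s in range(n):
        d, sigma, _, _ = _dijkstra(D, s, tol)
        dists[s] = d
        counts[s] = sigma
    return dists, counts


def closeness(network, threshold: float = 0.0) -> pd.Series:
    """Inverse summed shortest outgoing distance to all other nodes.

    A node from which any other node is unreachable gets closeness 0 (the
    inverse of an infinite distance sum).
    """
    D = distance_matrix(network, threshold)
    n = D.shape[0]
    out = np.zeros(n)
    for v in range(n):
        d, _, _, _ = _dijkstra(D, v)
        others = np.delete(d, v)
        total = others.sum()
        out[v] = 0.0 if np.isinf(total) else 1.0 / total
    return pd.Series(out, index=_labels(n), name="closeness")


def betweenness(network, threshold: float = 0.0,
                tol: float = _TIE_TOL) -> pd.Series:
    """Fractional count of shortest paths through each node (Brandes).

    Counts ordered pairs (s, t) with s, t both different from the node;
    when several minimal paths tie (to within ``tol``), the count is split
    across them.  Self-loops are ignored.
    """
    D = distance_matrix(network, threshold)
    n = D.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        _, sigma, preds, order = _dijkstra(D, s, tol)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return pd.Series(bc, index=_labels(n), name="betweenness")


def centrality_table(network, threshold: float = 0.0) -> pd.DataFrame:
    """All five centrality indices per symptom, in canonical order.

    Columns: betweenness, closeness, inward_strength, outward_strength,
    node_strength.
    """
    st = strengths(network)
    table = pd.DataFrame({
        "betweenness": betweenness(network, threshold),
        "closeness": closeness(network, threshold),
        "inward_strength": st["inward_strength"],
        "outward_strength": st["outward_strength"],
        "node_strength": st["node_strength"],
    })
    table.index.name = "symptom"
    return table
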