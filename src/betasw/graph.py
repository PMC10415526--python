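"""Weighted graph metrics and the surrogate-normalized small-world index.

For a symmetric nonnegative weighted adjacency matrix W the module computes

* ``C_brain`` — mean weighted clustering coefficient (Onnela geometric-mean
  form, on weights normalized by the matrix maximum),
* ``L_brain`` — weighted characteristic path length with edge lengths 1/w,
* ``C_random``, ``L_random`` — means of the same quantities over an ensemble
  of surrogate random networks that preserve the node count, the binary
  degree sequence and the multiset of edge weights,

and from these the normalized ratios ``Cw = C_brain / C_random``,
``Lw = L_brain / L_random`` and the small-world index ``Sw = Cw / Lw``.
``Sw ~ 1`` indicates a random-like network; ``Sw > 1`` indicates strong local
clustering combined with short global paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "NetworkMetrics",
    "weighted_clustering",
    "weighted_path_length",
    "surrogate_ensemble",
    "small_worldness",
]


@dataclass(frozen=True)
class NetworkMetrics:
    """Per-network graph summary: raw, surrogate-null and normalized values."""

    C_brain: float
    L_brain: float
    C_random: float
    L_random: float
    Cw: float
    Lw: float
    Sw: float
    n_surrogates: int
    seed: int
    surrogate_mode: str = "degree_weight"


def _validate_adjacency(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(W < 0):
        raise ValueError("adjacency weights must be nonnegative")
    if np.any(np.diag(W) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return W


def weighted_clustering(W: np.ndarray) -> float:
    """Mean Onnela weighted clustering coefficient.

    Weights are normalized by the matrix maximum; the per-node coefficient is
    the mean geometric intensity of the triangles around the node,

        C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w_ij w_jh w_hi)^(1/3),

    with k_i the binary degree.  Nodes with degree < 2 contribute 0.
    """
    W = _validate_adjacency(W)
    n = W.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 nodes (no triangles otherwise)")
    wmax = W.max()
    if wmax == 0:
        return 0.0
    cr = np.cbrt(W / wmax)
    triangles = np.diagonal(cr @ cr @ cr)  # = sum_{j,h} w^1/3 products, both orders
    k = np.count_nonzero(W, axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)
    return float(c.mean())


def weighted_path_length(W: np.ndarray) -> float:
    """Weighted characteristic path length with edge lengths 1/weight.

    All-pairs shortest paths on the length graph; L is the mean over ordered
    pairs of distinct nodes.  A disconnected graph raises, naming the
    components, rather than silently averaging infinite distances.
    """
    W = _validate_adjacency(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    graph = csr_matrix(lengths)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise ValueError(f"graph is disconnected; components (node indices): {comps}")
    D = shortest_path(graph, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    return float(D[off].mean())


# ---------------------------------------------------------------------------
# surrogate null model
# ---------------------------------------------------------------------------


def _maslov_sneppen_rewire(adj: np.ndarray, rng: np.random.Generator,
                           swaps_per_edge: int = 10) -> np.ndarray:
    """Degree-preserving rewiring of a binary undirected adjacency.

    Attempts ``swaps_per_edge * n_edges`` double-edge swaps; swaps that would
    create self-loops or duplicate edges are discarded.  On graphs that admit
    no swap (e.g. complete graphs) the topology is returned unchanged.
    """
    A = adj.copy()
    edges = np.argwhere(np.triu(A, 1))
    m = len(edges)
    if m < 2:
        return A
    n_attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.integers(0, 2, size=n_attempts)
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        # proposed new edges: (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = 0
        A[c, d] = A[d, c] = 0
        A[a, d] = A[d, a] = 1
        A[c, b] = A[b, c] = 1
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    return A


def _make_surrogates(W: np.ndarray, n_surrogates: int, rng: np.random.Generator,
                     mode: str) -> np.ndarray:
    """Stack of surrogate adjacency matrices, shape (n_surrogates, n, n).

    ``degree_weight``: Maslov-Sneppen swaps on the binary topology, then the
    original edge-weight multiset randomly reassigned to the surviving edges.
    ``weight_shuffle``: topology kept fixed, weights permuted over the
    existing edges.  Both preserve node count and the edge-weight multiset.
    """
    if mode not in ("degree_weight", "weight_shuffle"):
        raise ValueError(f"unknown surrogate mode {mode!r}")
    n = W.shape[0]
    iu = np.triu_indices(n, 1)
    weights = W[iu]
    present = weights > 0
    wvals = weights[present]
    adj = (W > 0).astype(np.int8)
    complete = bool(present.all())
    out = np.zeros((n_surrogates, n, n))
    if complete or mode == "weight_shuffle":
        # topology is fixed (complete graphs admit no degree-preserving
        # swap), so surrogates differ only in the weight arrangement
        su, sv = iu[0][present], iu[1][present]
        perm = np.argsort(rng.random((n_surrogates, len(wvals))), axis=1)
        out[:, su, sv] = wvals[perm]
        out += out.transpose(0, 2, 1)
        return out
    for s in range(n_surrogates):
        A = _maslov_sneppen_rewire(adj, rng)
        S = np.zeros((n, n))
        su, sv = np.nonzero(np.triu(A, 1))
        S[su, sv] = rng.permutation(wvals)
        out[s] = S + S.T
    return out


def _batch_clustering(Ws: np.ndarray) -> np.ndarray:
    """Onnela clustering for a stack of adjacencies, vectorized."""
    wmax = Ws.max(axis=(1, 2), keepdims=True)
    wmax = np.where(wmax > 0, wmax, 1.0)
    cr = np.cbrt(Ws / wmax)
    tri = np.einsum("bij,bjk,bki->bi", cr, cr, cr)
    k = np.count_nonzero(Ws, axis=2)
    denom = k * (k - 1)
    c = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    return c.mean(axis=1)


def _batch_path_length(Ws: np.ndarray) -> np.ndarray:
    """Characteristic path length for a stack, via batched Floyd-Warshall."""
    B, n, _ = Ws.shape
    with np.errstate(divide="ignore"):
        D = np.where(Ws > 0, 1.0 / np.where(Ws > 0, Ws, 1.0), np.inf)
    D[:, np.arange(n), np.arange(n)] = 0.0
    for k in range(n):
        D = np.minimum(D, D[:, :, k, None] + D[:, None, k, :])
    off = ~np.eye(n, dtype=bool)
    return D[:, off].mean(axis=1)


def surrogate_ensemble(W: np.ndarray, n_surrogates: int = 100, seed: int = 0,
                       mode: str = "degree_weight") -> tuple[float, float]:
    """Mean clustering and path length of an ensemble of surrogate networks.

    Surrogates preserve the node count, the binary degree sequence (in
    ``degree_weight`` mode) and the exact multiset of edge weights.
    Disconnected surrogates are redrawn (up to 20 attempts each); for dense
    connectivity matrices this never triggers.  Deterministic given ``seed``.
    """
    W = _validate_adjacency(W)
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    surr = _make_surrogates(W, n_surrogates, rng, mode)
    L = _batch_path_length(surr)
    bad = ~np.isfinite(L)
    attempts = 0
    while bad.any() and attempts < 20:
        redo = _make_surrogates(W, int(bad.sum()), rng, mode)
        surr[bad] = redo
        L[bad] = _batch_path_length(redo)
        bad = ~np.isfinite(L)
        attempts += 1
    if bad.any():
        raise ValueError("could not draw connected surrogates for this graph")
    C = _batch_clustering(surr)
    return float(C.mean()), float(L.mean())


def small_worldness(W: np.ndarray, n_surrogates: int = 100, seed: int = 0,
                    mode: str = "degree_weight") -> NetworkMetrics:
    """Full small-world record for one connectivity matrix.

    ``Sw = (C_brain / C_random) / (L_brain / L_random)``.
    """
    W = _validate_adjacency(W)
    C_brain = weighted_clustering(W)
    L_brain = weighted_path_length(W)
    C_random, L_random = surrogate_ensemble(W, n_surrogates, seed, mode)
    if C_random == 0:
        warnings.warn("surrogate clustering is 0; Cw undefined, reported as nan")
        Cw = float("nan")
    else:
        Cw = C_brain / C_random
    Lw = L_brain / L_random
    return NetworkMetrics(
        C_brain=C_brain, L_brain=L_brain,
        C_random=C_random, L_random=L_random,
        Cw=Cw, Lw=Lw, Sw=Cw / Lw,
        n_surrogates=n_surrogates, seed=seed, surrogate_mode=mode,
    )
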