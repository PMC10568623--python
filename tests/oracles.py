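"""Independent brute-force oracles used to check graph metrics and spectra."""

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on a dense length matrix (0 = no edge)."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_bf(adj: np.ndarray, mode: str) -> float:
    d = floyd_warshall(_lengths(adj, mode))
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def char_path_length_bf(adj: np.ndarray, mode: str) -> float:
    d = floyd_warshall(_lengths(adj, mode))
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("inf")


def nodal_efficiency_bf(adj: np.ndarray, mode: str) -> np.ndarray:
    d = floyd_warshall(_lengths(adj, mode))
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def _lengths(adj: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        return (adj > 0).astype(float)
    with np.errstate(divide="ignore"):
        return np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)


def binary_clustering_bf(adj: np.ndarray) -> np.ndarray:
    """Triangles / possible triangles per node on the binarized graph."""
    a = (adj > 0).astype(int)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0
        for x in range(k):
            for y in range(x + 1, k):
                tri += a[nbrs[x], nbrs[y]]
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def weighted_clustering_bf(adj: np.ndarray) -> np.ndarray:
    """Onnela geometric-mean weighted clustering coefficient."""
    w = adj / adj.max() if adj.max() > 0 else adj
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for x in range(k):
            for y in range(k):
                if x == y:
                    continue
                j, h = nbrs[x], nbrs[y]
                if adj[j, h] > 0:
                    s += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        out[i] = s / (k * (k - 1))
    return out


def modularity_bf(adj: np.ndarray, partition, mode: str) -> float:
    """Direct evaluation of Q for a given partition."""
    a = (adj > 0).astype(float) if mode == "binary" else adj
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    community = {}
    for c, nodes in enumerate(partition):
        for v in nodes:
            community[v] = c
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if community[i] == community[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m
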