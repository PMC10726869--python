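"""Independent brute-force oracles for the multiplex measures and modularity.

Everything here is written as plain loops straight from the definitions, on
purpose: these functions are the ground truth the vectorized implementations
are checked against, and must not share code with them.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


def oracle_degree_overlap(w: np.ndarray) -> np.ndarray:
    """w: (M, N, N). Neighbors present in every layer, counted per node."""
    m, n, _ = w.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if j != i and all(w[a, i, j] > 0 for a in range(m)):
                out[i] += 1
    return out


def oracle_overlapping_degree(w: np.ndarray) -> np.ndarray:
    m, n, _ = w.shape
    out = np.zeros(n)
    for i in range(n):
        for a in range(m):
            for j in range(n):
                if w[a, i, j] > 0:
                    out[i] += 1
    return out


def oracle_overlapping_strength(w: np.ndarray) -> np.ndarray:
    m, n, _ = w.shape
    out = np.zeros(n)
    for i in range(n):
        for a in range(m):
            for j in range(n):
                out[i] += w[a, i, j]
    return out


def _oracle_participation(per_layer: list[list[float]]) -> np.ndarray:
    m = len(per_layer)
    n = len(per_layer[0])
    out = np.zeros(n)
    for i in range(n):
        total = sum(per_layer[a][i] for a in range(m))
        if total == 0:
            continue
        ssq = sum((per_layer[a][i] / total) ** 2 for a in range(m))
        out[i] = (m / (m - 1)) * (1.0 - ssq)
    return out


def oracle_multiplex_participation(w: np.ndarray) -> np.ndarray:
    m, n, _ = w.shape
    k = [[sum(1 for j in range(n) if w[a, i, j] > 0) for i in range(n)] for a in range(m)]
    return _oracle_participation(k)


def oracle_weighted_participation(w: np.ndarray) -> np.ndarray:
    m, n, _ = w.shape
    s = [[sum(w[a, i, j] for j in range(n)) for i in range(n)] for a in range(m)]
    return _oracle_participation(s)


def oracle_multiplex_clustering(w: np.ndarray) -> np.ndarray:
    """Interlayer triangles with cube-root weight products, triple loop."""
    m, n, _ = w.shape
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        for a in range(m):
            for b in range(m):
                if a == b:
                    continue
                for j in range(n):
                    for q in range(n):
                        if j == i or q == i or j == q:
                            continue
                        num += (w[a, i, j] * w[b, j, q] * w[a, q, i]) ** (1.0 / 3.0)
        den = 0.0
        for a in range(m):
            k = sum(1 for j in range(n) if w[a, i, j] > 0)
            den += k * (k - 1)
        den *= m - 1
        out[i] = num / den if den > 0 else 0.0
    return out


def oracle_quality(w: np.ndarray, labels: np.ndarray, gamma: float, omega: float) -> float:
    """Multilayer modularity evaluated term by term from the definition."""
    m, n, _ = w.shape
    totals = [w[a].sum() for a in range(m)]  # 2m_a
    two_mu = sum(totals) + n * m * (m - 1) * omega
    q = 0.0
    for a in range(m):
        s = [w[a, i].sum() for i in range(n)]
        for i in range(n):
            for j in range(n):
                if labels[a, i] == labels[a, j]:
                    q += w[a, i, j] - gamma * s[i] * s[j] / totals[a]
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            for i in range(n):
                if labels[a, i] == labels[b, i]:
                    q += omega
    return q / two_mu


def all_partition_labels(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of n items as restricted-growth label strings."""

    def rec(prefix: list[int], mx: int) -> Iterator[tuple[int, ...]]:
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))

    yield from rec([0], 0)


def exhaustive_max_quality(w: np.ndarray, gamma: float, omega: float) -> float:
    """Exact maximum of the quality function over all node-layer partitions.

    Enumerates restricted-growth strings over the N*M supra-nodes and
    evaluates Q in chunked einsum form for speed; the modularity matrix is
    rebuilt here from the definition, independently of the implementation.
    """
    m, n, _ = w.shape
    nm = n * m
    totals = [w[a].sum() for a in range(m)]
    two_mu = sum(totals) + n * m * (m - 1) * omega
    b = np.zeros((nm, nm))
    for a in range(m):
        s = w[a].sum(axis=1)
        for i in range(n):
            for j in range(n):
                b[a * n + i, a * n + j] = w[a, i, j] - gamma * s[i] * s[j] / totals[a]
    for a in range(m):
        for c in range(m):
            if a != c:
                for i in range(n):
                    b[a * n + i, c * n + i] += omega
    best = -np.inf
    chunk: list[tuple[int, ...]] = []

    def flush(chunk: list[tuple[int, ...]], best: float) -> float:
        if not chunk:
            return best
        g = np.array(chunk)
        same = g[:, :, None] == g[:, None, :]
        qs = np.einsum("kij,ij->k", same, b) / two_mu
        return max(best, float(qs.max()))

    for labels in all_partition_labels(nm):
        chunk.append(labels)
        if len(chunk) >= 8192:
            best = flush(chunk, best)
            chunk = []
    return flush(chunk, best)
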