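"""Multilayer community structure: modularity, generalized Louvain,
flexibility and persistence.

The quality function is the standard multilayer (Mucha-style) modularity for
a categorical multiplex.  With node-layer labels g_{ia}, layer totals
2m_a = sum_ij w_ij^[a], resolution gamma and interlayer coupling omega,

    Q = (1/2mu) * sum_{ij,a,a'} [ (w_ij^[a] - gamma s_i^[a] s_j^[a] / 2m_a) d_aa'
                                  + d_ij * omega * (1 - d_aa') ] d(g_ia, g_ja')

where 2mu = sum_a 2m_a + N * M * (M-1) * omega (intra-layer weight plus the
interlayer coupling counted over ordered layer pairs).  Diagonal null-model
terms (i = j within a layer) are included, so the singleton partition has
Q = -(1/2mu) sum_a sum_i gamma (s_i^[a])^2 / 2m_a.

The optimizer is a generalized Louvain ascent on the supra-modularity matrix
of the N*M node-layer copies: greedy node moves to the best neighboring
community until no gain, then aggregation, iterated to a local optimum; the
best of ``restarts`` randomized restarts is returned.  Randomness (node
visit order) is fully controlled by ``seed``.

Partition-derived measures: flexibility of a node is the fraction of
adjacent layer pairs in which its community label changes; persistence is
the normalized count of labels retained.  For M = 2 the average flexibility
and persistence sum to 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import MultiplexNetwork


@dataclass
class CommunityPartition:
    """Community labels per (layer, node) plus the quality of the partition."""

    labels: np.ndarray  # shape (M, N), non-negative integers
    quality: float
    gamma: float = 1.0
    omega: float = 1.0
    restarts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be an (M, N) array")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative integers")
        self.labels = lab.astype(int)


def _layer_totals(net: MultiplexNetwork) -> np.ndarray:
    totals = net.weight_arrays().sum(axis=(1, 2))  # 2m_a
    if np.any(totals == 0):
        empty = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(f"layer {empty} has no edges; modularity undefined")
    return totals


def coupling_total(net: MultiplexNetwork, omega: float) -> float:
    """Interlayer coupling mass over ordered layer pairs: N*M*(M-1)*omega."""
    return net.n_nodes * net.n_layers * (net.n_layers - 1) * omega


def multilayer_quality(
    net: MultiplexNetwork,
    labels: np.ndarray,
    gamma: float = 1.0,
    omega: float = 1.0,
) -> float:
    """Evaluate the multilayer quality function at the given labels."""
    labels = np.asarray(labels)
    if labels.shape != (net.n_layers, net.n_nodes):
        raise ValueError(
            f"labels shape {labels.shape} does not match "
            f"(M, N) = ({net.n_layers}, {net.n_nodes})"
        )
    w = net.weight_arrays()
    totals = _layer_totals(net)
    two_mu = totals.sum() + coupling_total(net, omega)
    q = 0.0
    for a in range(net.n_layers):
        s = w[a].sum(axis=1)
        null = gamma * np.outer(s, s) / totals[a]
        same = labels[a][:, None] == labels[a][None, :]
        q += ((w[a] - null) * same).sum()
    if omega:
        for a in range(net.n_layers):
            for b in range(net.n_layers):
                if a != b:
                    q += omega * (labels[a] == labels[b]).sum()
    return float(q / two_mu)


def supra_modularity_matrix(
    net: MultiplexNetwork, gamma: float = 1.0, omega: float = 1.0
) -> np.ndarray:
    """Dense (N*M) x (N*M) modularity matrix B; supra index u = a*N + i.

    Q(labels) = (1/2mu) sum_{uv} B_uv d(g_u, g_v), including u = v terms.
    """
    w = net.weight_arrays()
    totals = _layer_totals(net)
    n, m = net.n_nodes, net.n_layers
    b = np.zeros((n * m, n * m))
    for a in range(m):
        s = w[a].sum(axis=1)
        blk = w[a] - gamma * np.outer(s, s) / totals[a]
        b[a * n : (a + 1) * n, a * n : (a + 1) * n] = blk
    if omega:
        eye = omega * np.eye(n)
        for a in range(m):
            for c in range(m):
                if a != c:
                    b[a * n : (a + 1) * n, c * n : (c + 1) * n] += eye
    return b


def _one_level(
    b: np.ndarray,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
    tol: float = 1e-12,
) -> np.ndarray:
    """Greedy node moves on modularity matrix ``b`` until a local optimum.

    Starts from singletons, or from ``init`` when refining an existing
    assignment; an unused label id is always available so a node can leave
    for its own singleton when that is the best move.
    """
    n = b.shape[0]
    if init is None:
        comm = np.arange(n)
    else:
        _, comm = np.unique(init, return_inverse=True)
    moved = True
    while moved:
        moved = False
        for u in rng.permutation(n):
            size = comm.max() + 2  # leave room for a fresh singleton id
            gains = np.bincount(comm, weights=b[u], minlength=size)
            gains[comm[u]] -= b[u, u]  # exclude the node's own diagonal
            best = int(np.argmax(gains))  # an empty id has gain 0 = go solo
            if gains[best] > gains[comm[u]] + tol and best != comm[u]:
                comm[u] = best
                moved = True
    _, comm = np.unique(comm, return_inverse=True)
    return comm


def _quality_unscaled(b: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float((b * same).sum())


def _louvain(b: np.ndarray, rng: np.random.Generator, tol: float = 1e-12) -> np.ndarray:
    """Louvain ascent on modularity matrix b: greedy moves, aggregation,
    then leaf-level refinement, iterated while the quality improves.

    The refinement pass re-runs node moves on the original nodes starting
    from the aggregated solution; it can split nodes that aggregation has
    locked together, which plain Louvain cannot.
    """
    assign = _one_level(b, rng)
    best_q = _quality_unscaled(b, assign)
    while True:
        # aggregate and merge communities until the coarse level is stable
        while True:
            n_comm = assign.max() + 1
            onehot = np.zeros((b.shape[0], n_comm))
            onehot[np.arange(b.shape[0]), assign] = 1.0
            bagg = onehot.T @ b @ onehot
            comm = _one_level(bagg, rng)
            if comm.max() + 1 == n_comm:
                break
            assign = comm[assign]
        refined = _one_level(b, rng, init=assign)
        q = _quality_unscaled(b, refined)
        if q > best_q + tol:
            assign, best_q = refined, q
        else:
            return assign


def optimize_partition(
    net: MultiplexNetwork,
    gamma: float = 1.0,
    omega: float = 1.0,
    restarts: int = 10,
    seed: int = 0,
) -> CommunityPartition:
    """Best-of-restarts generalized Louvain partition of the multiplex."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if restarts < 1:
        raise ValueError("need at least one restart")
    b = supra_modularity_matrix(net, gamma, omega)
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite weights in multiplex")
    n, m = net.n_nodes, net.n_layers
    two_mu = _layer_totals(net).sum() + coupling_total(net, omega)
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(restarts)]
    best_q, best_labels = -np.inf, None
    for rng in rngs:
        flat = _louvain(b, rng)
        same = flat[:, None] == flat[None, :]
        q = float((b * same).sum() / two_mu)
        if q > best_q + 1e-15:
            best_q, best_labels = q, flat
    labels = best_labels.reshape(m, n)
    quality = multilayer_quality(net, labels, gamma, omega)  # self-consistency
    return CommunityPartition(
        labels=labels, quality=quality, gamma=gamma, omega=omega,
        restarts=restarts, seed=seed,
    )


def flexibility(partition: CommunityPartition) -> np.ndarray:
    """Per node, fraction of adjacent layer pairs with a label change."""
    lab = partition.labels
    if lab.shape[0] < 2:
        raise ValueError("flexibility needs at least two layers")
    changes = (lab[:-1] != lab[1:]).sum(axis=0)
    return changes / (lab.shape[0] - 1)


def persistence(partition: CommunityPartition) -> float:
    """Normalized count of node-layer transitions that keep their label."""
    lab = partition.labels
    if lab.shape[0] < 2:
        raise ValueError("persistence needs at least two layers")
    kept = (lab[:-1] == lab[1:]).sum()
    return float(kept / (lab.shape[1] * (lab.shape[0] - 1)))
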