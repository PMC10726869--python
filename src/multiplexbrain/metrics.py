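"""Nodal and global multiplex graph measures.

Conventions, for a multiplex with M layers over N shared nodes and
non-negative weights w_ij^[a] in [0, 1]:

* binary adjacency        a_ij^[a] = 1 iff w_ij^[a] > 0
* binary degree           k_i^[a]  = sum_j a_ij^[a]
* strength                s_i^[a]  = sum_j w_ij^[a]
* degree overlap          o_i = #{ j != i : a_ij^[a] = 1 for every layer a }
* overlapping degree      O_i = sum_a k_i^[a]
* overlapping strength    S_i = sum_a s_i^[a]
* multiplex participation P_i = M/(M-1) * (1 - sum_a (k_i^[a]/O_i)^2),
  and its weighted twin with s and S in place of k and O.  P_i = 1 when a
  node's connectivity is spread evenly over the layers, 0 when confined to
  one layer; defined as 0 for isolated nodes.
* multiplex clustering    interlayer triangles with Onnela-style cube-root
  weight products: C_i = num_i / den_i with
      num_i = sum_{a != a'} sum_{j != m, both != i}
              (w_ij^[a] * w_jm^[a'] * w_mi^[a])^(1/3)
      den_i = (M-1) * sum_a k_i^[a] (k_i^[a] - 1)
  which reduces to the binary multiplex clustering coefficient on 0/1
  weights and stays in [0, 1] under the [0, 1] weight contract.

All ratio measures are defined as 0 where their denominator is 0 so that
isolated nodes do not poison global averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layers import MultiplexNetwork

#: nodal measures compared between groups at the node level
NODAL_MEASURES = (
    "multilayer_clustering",
    "multiplex_participation",
    "overlapping_strength",
    "weighted_multiplex_participation",
)


def layer_degrees(net: MultiplexNetwork) -> np.ndarray:
    """Binary degrees, shape (M, N)."""
    return (net.weight_arrays() > 0).sum(axis=2)


def layer_strengths(net: MultiplexNetwork) -> np.ndarray:
    """Weighted strengths, shape (M, N)."""
    return net.weight_arrays().sum(axis=2)


def degree_overlap(net: MultiplexNetwork) -> np.ndarray:
    """Per node, the number of neighbors present in every layer."""
    adj = net.weight_arrays() > 0
    return adj.all(axis=0).sum(axis=1).astype(float)


def overlapping_degree(net: MultiplexNetwork) -> np.ndarray:
    return layer_degrees(net).sum(axis=0).astype(float)


def overlapping_strength(net: MultiplexNetwork) -> np.ndarray:
    return layer_strengths(net).sum(axis=0)


def _participation(per_layer: np.ndarray) -> np.ndarray:
    m = per_layer.shape[0]
    total = per_layer.sum(axis=0)
    out = np.zeros(per_layer.shape[1])
    ok = total > 0
    frac = per_layer[:, ok] / total[ok]
    out[ok] = (m / (m - 1)) * (1.0 - (frac**2).sum(axis=0))
    # clamp tiny negative round-off at perfectly homogeneous nodes
    return np.clip(out, 0.0, 1.0)


def multiplex_participation(net: MultiplexNetwork) -> np.ndarray:
    """Evenness of a node's binary degree across layers, in [0, 1]."""
    return _participation(layer_degrees(net).astype(float))


def weighted_multiplex_participation(net: MultiplexNetwork) -> np.ndarray:
    """Evenness of a node's strength across layers, in [0, 1]."""
    return _participation(layer_strengths(net))


def multiplex_clustering(net: MultiplexNetwork) -> np.ndarray:
    """Interlayer clustering coefficient per node (see module docstring).

    For M = 2 the numerator is diag(W1^ W2^ W1^) + diag(W2^ W1^ W2^) with
    W^ the element-wise cube root of each layer; j = m terms vanish because
    diagonals are zero.
    """
    w = net.weight_arrays()
    if w.max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError(
            "multiplex clustering requires layer weights in [0, 1]; "
            "normalize layers first"
        )
    cbrt = np.cbrt(w)
    m, n = w.shape[0], w.shape[1]
    num = np.zeros(n)
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            num += np.einsum("ij,jm,mi->i", cbrt[a], cbrt[b], cbrt[a])
    k = layer_degrees(net)
    den = (m - 1) * (k * (k - 1)).sum(axis=0)
    out = np.zeros(n)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def global_average(values: np.ndarray) -> float:
    """Arithmetic mean over all nodes."""
    return float(np.mean(values))


def nodal_metrics(net: MultiplexNetwork) -> pd.DataFrame:
    """All nodal measure vectors as a DataFrame (one column per measure)."""
    return pd.DataFrame(
        {
            "degree_overlap": degree_overlap(net),
            "overlapping_degree": overlapping_degree(net),
            "overlapping_strength": overlapping_strength(net),
            "multiplex_participation": multiplex_participation(net),
            "weighted_multiplex_participation": weighted_multiplex_participation(net),
            "multilayer_clustering": multiplex_clustering(net),
        }
    )
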