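"""Layer matrices and multiplex assembly.

A layer is a symmetric, non-negative, zero-diagonal weighted adjacency matrix
on the shared parcellation node set.  The two layers of the pipeline are the
gray-matter morphometric similarity network (edge weights are clipped Pearson
correlations, already in [0, 1]) and the white-matter structural connectivity
layer (streamline counts, rescaled here to [0, 1] by division by the maximum
entry so that strength- and clustering-type measures treat both layers on a
common scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: asymmetry up to this magnitude is silently symmetrized as (A + A.T) / 2;
#: anything larger signals a corrupted input file and raises.
SYMMETRY_TOL = 1e-8


@dataclass
class LayerMatrix:
    """One weighted layer on the shared node set.

    ``weights`` is validated on construction: it must be square, finite and
    symmetric within :data:`SYMMETRY_TOL`; the stored matrix is exactly
    symmetric with a zero diagonal (self-connections are excluded by
    convention).
    """

    weights: np.ndarray
    label: str = "gray"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"layer matrix must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("layer matrix contains non-finite entries")
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"layer matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class MultiplexNetwork:
    """Ordered pair of layers (gray, white) over a common node set."""

    layers: list[LayerMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a multiplex network needs at least two layers")
        ns = {layer.n_nodes for layer in self.layers}
        if len(ns) != 1:
            raise ValueError(f"layers disagree on node count: {sorted(ns)}")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def weight_arrays(self) -> np.ndarray:
        """Stack of layer weight matrices, shape (M, N, N)."""
        return np.stack([layer.weights for layer in self.layers])


def normalize_layer(raw: LayerMatrix) -> LayerMatrix:
    """Rescale a non-negative layer to [0, 1] by its maximum entry.

    An all-zero layer is passed through unchanged with a warning.  Negative
    entries are rejected: streamline counts and clipped correlations are
    non-negative by contract.
    """
    w = raw.weights
    if (w < 0).any():
        raise ValueError(f"negative entries in {raw.label!r} layer; cannot normalize")
    top = w.max() if w.size else 0.0
    if top == 0.0:
        warnings.warn(f"layer {raw.label!r} is all-zero; normalization is a no-op")
        return LayerMatrix(w.copy(), label=raw.label)
    return LayerMatrix(w / top, label=raw.label)


def assemble_multiplex(gray: LayerMatrix, white: LayerMatrix) -> MultiplexNetwork:
    """Pair the gray- and white-matter layers into a two-layer multiplex."""
    if gray.n_nodes != white.n_nodes:
        raise ValueError(
            f"layer dimension mismatch: gray {gray.n_nodes} vs white {white.n_nodes}"
        )
    return MultiplexNetwork([gray, white])
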