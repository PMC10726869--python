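"""Gray-matter layer: the morphometric similarity network (MSN).

Each cortical region carries a vector of morphometric features (cortical
thickness, surface area, mean curvature, Gaussian curvature, folding index,
curvature index, gray matter volume).  Features are z-scored across regions
— otherwise large-magnitude features such as area and volume dominate — and
the MSN edge between two regions is the Pearson correlation of their
z-scored feature vectors.  Negative correlations are clipped to zero so that
both layers of the multiplex are non-negative weighted graphs, which the
strength/participation/clustering formulas assume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layers import LayerMatrix

DEFAULT_FEATURES = (
    "thickness",
    "surface_area",
    "mean_curvature",
    "gaussian_curvature",
    "folding_index",
    "curvature_index",
    "gray_matter_volume",
)


def _as_frame(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    arr = np.asarray(table, dtype=float)
    cols = list(DEFAULT_FEATURES[: arr.shape[1]])
    if arr.shape[1] > len(cols):
        cols += [f"feature_{k}" for k in range(len(cols), arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def zscore_features(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Z-score every feature column across regions (sample sd, ddof=1).

    Raises on NaN and on constant columns, for which the z-score is
    undefined.
    """
    df = _as_frame(table)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("morphometric table contains NaN")
    if values.shape[0] < 2:
        raise ValueError("need at least two regions to z-score")
    sd = values.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [str(df.columns[k]) for k in degenerate]
        raise ValueError(f"constant feature column(s), z-score undefined: {names}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def build_msn(table: pd.DataFrame | np.ndarray) -> LayerMatrix:
    """Morphometric similarity network from a region x feature table.

    The table is z-scored internally; entry (i, j) is the Pearson
    correlation across features of region i's and region j's z-scored
    vectors, negatives clipped to 0, diagonal 0.
    """
    z = zscore_features(table).to_numpy()
    row_sd = z.std(axis=1)
    flat = np.flatnonzero(row_sd == 0)
    if flat.size:
        idx = [int(i) for i in flat]
        raise ValueError(
            f"region(s) {idx} have a constant z-scored feature vector; "
            "pairwise correlation is undefined"
        )
    r = np.corrcoef(z)
    np.clip(r, 0.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return LayerMatrix(r, label="gray")
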