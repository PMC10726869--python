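"""Parcellation definition and all file I/O for the pipeline.

The default atlas is a 62-region cortical parcellation in the
Desikan-Killiany style: 31 regions per hemisphere, fixed order.  That order
is the single source of node indexing — every matrix the pipeline touches is
index-aligned to it.

Formats are deliberately plain text: atlas and manifest are TSV, adjacency
matrices are dense CSV with a header row of region names, comparison reports
are TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .layers import SYMMETRY_TOL, LayerMatrix

HEMISPHERES = ("left", "right")
MANIFEST_COLUMNS = ("subject_id", "group", "age", "sex")
GROUPS = ("patient", "control")
SEXES = ("male", "female")


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered region set; ``roi_id`` is the position, 0..N-1."""

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.hemispheres):
            raise ValueError("names and hemispheres must have equal length")
        if len(self.names) == 0:
            raise ValueError("atlas is empty")
        dup = pd.Index(self.names)[pd.Index(self.names).duplicated()]
        if len(dup):
            raise ValueError(f"duplicate ROI names in atlas: {sorted(set(dup))}")
        bad = set(self.hemispheres) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")
        if set(self.hemispheres) != set(HEMISPHERES):
            raise ValueError("atlas must contain regions from both hemispheres")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)


def load_atlas(path: str | Path) -> ROIAtlas:
    """Read an atlas TSV with columns roi_id, name, hemisphere (file order kept)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(("roi_id", "name", "hemisphere")) - set(df.columns)
    if missing:
        raise ValueError(f"atlas file {path} missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"atlas file {path} is empty")
    expected = np.arange(len(df))
    if not np.array_equal(df["roi_id"].to_numpy(), expected):
        bad = int(np.flatnonzero(df["roi_id"].to_numpy() != expected)[0])
        raise ValueError(
            f"atlas file {path}: roi_id must run 0..N-1 in file order "
            f"(first offending row index {bad})"
        )
    dups = df.loc[df["name"].duplicated(), "name"]
    if len(dups):
        row = int(dups.index[0])
        raise ValueError(f"atlas file {path}: duplicate ROI name {dups.iloc[0]!r} at row {row}")
    return ROIAtlas(tuple(df["name"]), tuple(df["hemisphere"]))


def default_atlas() -> ROIAtlas:
    """The packaged 62-region (31 per hemisphere) cortical atlas."""
    ref = resources.files(__package__) / "data" / "atlas_dk62.tsv"
    with resources.as_file(ref) as path:
        return load_atlas(path)


# ---------------------------------------------------------------- manifest

def validate_manifest(df: pd.DataFrame, require_both_groups: bool = True) -> pd.DataFrame:
    """Validate a subject manifest (subject_id, group, age, sex)."""
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id in manifest: {dup!r}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {sorted(bad_group)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
    if (df["age"].to_numpy(dtype=float) <= 0).any():
        raise ValueError("manifest ages must be positive")
    if require_both_groups and set(df["group"]) != set(GROUPS):
        raise ValueError("manifest must contain both patients and controls")
    return df.reset_index(drop=True)


def load_manifest(path: str | Path, require_both_groups: bool = True) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t"), require_both_groups)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(manifest, require_both_groups=False)
    manifest.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- matrices

def read_matrix(
    path: str | Path,
    atlas: ROIAtlas,
    label: str = "gray",
    nonnegative: bool = False,
) -> LayerMatrix:
    """Read a dense N x N CSV whose header matches the atlas order.

    The matrix is symmetrized as (A + A.T)/2 if the asymmetry is below
    ``SYMMETRY_TOL`` (larger asymmetry raises), and the diagonal is forced
    to zero.  With ``nonnegative=True`` (structural streamline counts)
    negative entries are an error.
    """
    df = pd.read_csv(path)
    if tuple(df.columns) != atlas.names:
        if len(df.columns) != atlas.n_rois:
            raise ValueError(
                f"matrix {path}: expected {atlas.n_rois} columns, got {len(df.columns)}"
            )
        raise ValueError(f"matrix {path}: header does not match atlas ROI order")
    if len(df) != atlas.n_rois:
        raise ValueError(f"matrix {path}: expected {atlas.n_rois} rows, got {len(df)}")
    w = df.to_numpy(dtype=float)
    if np.isnan(w).any():
        i, j = np.argwhere(np.isnan(w))[0]
        raise ValueError(f"matrix {path}: NaN at ({atlas.names[i]}, {atlas.names[j]})")
    if nonnegative and (w < 0).any():
        i, j = np.argwhere(w < 0)[0]
        raise ValueError(
            f"matrix {path}: negative count at ({atlas.names[i]}, {atlas.names[j]})"
        )
    return LayerMatrix(w, label=label)  # symmetry/diagonal enforced there


def write_matrix(layer: LayerMatrix, atlas: ROIAtlas, path: str | Path) -> None:
    """Write a layer as dense CSV, full double precision (round-trips to 1e-12)."""
    if layer.n_nodes != atlas.n_rois:
        raise ValueError("layer does not match atlas size")
    pd.DataFrame(layer.weights, columns=list(atlas.names)).to_csv(
        path, index=False, float_format="%.17g"
    )


# ----------------------------------------------------------------- reports

def write_comparison_report(results: Sequence, path: str | Path) -> None:
    """Write comparison results as TSV, one row per measure (global) or per
    node x measure (nodal).

    Column layout mirrors the standard group-comparison table: measure
    (plus node for nodal rows), group means, difference (control - patient),
    95% permutation interval bounds, and the p-value; Bonferroni-significant
    rows carry a ``*`` prefix on the p-value, as such tables conventionally
    print them.
    """
    if not results:
        raise ValueError("no comparison results to write")
    nodal = any(r.node != "global" for r in results)
    rows = []
    for r in results:
        row = {"measure": r.measure_name}
        if nodal:
            row["node"] = r.node
        row.update(
            mean_patient=f"{r.mean_patient:.6g}",
            mean_control=f"{r.mean_control:.6g}",
            difference=f"{r.difference:.6g}",
            ci_low=f"{r.ci_low:.6g}",
            ci_high=f"{r.ci_high:.6g}",
            p_value=("*" if r.significant_after_bonferroni else "") + f"{r.p_value:.4f}",
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
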