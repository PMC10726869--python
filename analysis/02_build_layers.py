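#!/usr/bin/env python
"""Build each subject's two layers from the simulated cohort.

Gray layer: morphometric similarity network (Pearson correlation of
z-scored feature vectors, negatives clipped).  White layer: streamline
counts max-normalized to [0, 1].  Layers go to scratch/layers; a per-group
density/weight summary goes to results/layer_summary.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from multiplexbrain import LayerMatrix, build_msn, default_atlas, normalize_layer
from multiplexbrain.atlas import load_manifest, write_matrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "scratch" / "cohort"
    out = ROOT / "scratch" / "layers"
    out.mkdir(parents=True, exist_ok=True)
    atlas = default_atlas()
    manifest = load_manifest(cohort / "manifest.tsv")
    rows = []
    for sid, group in zip(manifest["subject_id"], manifest["group"]):
        table = pd.read_csv(cohort / f"{sid}_features.csv", index_col=0)
        counts = pd.read_csv(cohort / f"{sid}_counts.csv").to_numpy()
        gray = build_msn(table)
        white = normalize_layer(LayerMatrix(counts, label="white"))
        write_matrix(gray, atlas, out / f"{sid}_gray.csv")
        write_matrix(white, atlas, out / f"{sid}_white.csv")
        for layer in (gray, white):
            w = layer.weights
            off = ~np.eye(len(w), dtype=bool)
            rows.append({
                "subject_id": sid, "group": group, "layer": layer.label,
                "density": (w[off] > 0).mean(), "mean_weight": w[off].mean(),
            })
    summary = (
        pd.DataFrame(rows).groupby(["group", "layer"])[["density", "mean_weight"]]
        .mean().round(4)
    )
    summary.to_csv(ROOT / "results" / "layer_summary.tsv", sep="\t")
    print(summary)
    print(f"layers for {len(manifest)} subjects -> {out}")


if __name__ == "__main__":
    main()
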