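"""End-to-end glue: cohort inputs -> per-subject multiplex networks -> comparison.

Also hosts the null-calibration harness used to check that the permutation
test is well calibrated on exchangeable synthetic cohorts.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import metrics
from .compare import ComparisonConfig, permutation_test, residualize, run_full_comparison
from .layers import LayerMatrix, MultiplexNetwork, assemble_multiplex, normalize_layer
from .msn import build_msn
from .synthetic import CohortSpec, GroupEffect, simulate_cohort


def subject_network(table: pd.DataFrame, counts: np.ndarray) -> MultiplexNetwork:
    """Build one subject's two-layer multiplex from raw inputs."""
    gray = build_msn(table)
    white = normalize_layer(LayerMatrix(counts, label="white"))
    return assemble_multiplex(gray, white)


def networks_from_cohort(
    tables: Mapping[str, pd.DataFrame], counts: Mapping[str, np.ndarray]
) -> dict[str, MultiplexNetwork]:
    if set(tables) != set(counts):
        raise ValueError("morphometric tables and count matrices name different subjects")
    return {sid: subject_network(tables[sid], counts[sid]) for sid in tables}


def simulate_and_compare(
    spec: CohortSpec, config: ComparisonConfig | None = None
):
    """Simulate a cohort, build every subject's multiplex and compare groups."""
    manifest, tables, counts = simulate_cohort(spec)
    networks = networks_from_cohort(tables, counts)
    results = run_full_comparison(networks, manifest, config)
    return manifest, networks, results


def null_calibration(
    n_replicates: int = 500,
    n_per_group: int = 20,
    n_perm: int = 200,
    seed: int = 0,
    adjust_covariates: bool = True,
) -> np.ndarray:
    """Permutation p-values over replicated null cohorts (identity effect).

    Each replicate simulates an exchangeable cohort, computes one pipeline
    statistic per subject — the average overlapping strength of the
    subject's multiplex — adjusts it for age and sex, and runs the
    permutation test.  Under the null the returned p-values are uniform on
    the add-one grid {1,...,n_perm+1}/(n_perm+1).
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % 2**31
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        spec = CohortSpec(
            n_patients=n_per_group, n_controls=n_per_group,
            seed=int(rep_seeds[2 * r]), effect=GroupEffect(),
        )
        manifest, tables, counts = simulate_cohort(spec)
        values = np.array([
            metrics.global_average(
                metrics.overlapping_strength(subject_network(tables[s], counts[s]))
            )
            for s in manifest["subject_id"]
        ])
        if adjust_covariates:
            values = residualize(values, manifest)
        is_patient = (manifest["group"] == "patient").to_numpy()
        res = permutation_test(
            values[is_patient], values[~is_patient],
            n_perm=n_perm, seed=int(rep_seeds[2 * r + 1]),
            measure_name="average_overlapping_strength",
        )
        pvals[r] = res.p_value
    return pvals
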