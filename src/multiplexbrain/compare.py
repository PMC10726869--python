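"""Group comparison: covariate adjustment, permutation tests, Bonferroni.

Every measure is compared between patients and controls with a
nonparametric permutation test: the observed difference of group means
(control - patient, the conventional table sign), a null distribution of
the same difference under random relabelings of the subjects (group sizes
preserved), a two-sided add-one p-value

    p = (#{ |D*| >= |D| } + 1) / (n_perm + 1)

which is bounded below by 1/(n_perm + 1), and the 2.5th/97.5th percentiles
of the permuted differences as a 95% interval.  Age and sex are adjusted
for by residualizing each measure on [1, age, sex] over the pooled sample
before permuting group labels (a Freedman-Lane-style convention).

Family-wise error is controlled per family with Bonferroni: alpha/9 over
the nine global measures and alpha/62 within each nodal measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .community import flexibility, optimize_partition, persistence
from .layers import MultiplexNetwork

GLOBAL_MEASURES = (
    "average_degree_overlap",
    "average_flexibility",
    "multilayer_modularity",
    "average_multilayer_clustering",
    "average_multiplex_participation",
    "average_overlapping_degree",
    "average_overlapping_strength",
    "persistence",
    "average_weighted_multiplex_participation",
)

NODAL_MEASURES = metrics.NODAL_MEASURES


@dataclass
class ComparisonResult:
    measure_name: str
    node: int | str  # ROI index, or "global"
    mean_patient: float
    mean_control: float
    difference: float  # control - patient
    ci_low: float
    ci_high: float
    p_value: float
    significant_after_bonferroni: bool


@dataclass
class ComparisonConfig:
    n_perm: int = 1000
    alpha: float = 0.05
    n_global_measures: int = 9
    n_nodes: int | None = None  # None: infer from the data
    seed: int = 0
    adjust_covariates: bool = True
    # community-detection settings used when deriving per-subject measures
    gamma: float = 1.0
    omega: float = 1.0
    restarts: int = 10

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def render_threshold(threshold: float) -> str:
    """4-decimal rendering of a threshold, truncated (0.05/9 -> '0.0055')."""
    return f"{np.floor(threshold * 1e4) / 1e4:.4f}"


# ----------------------------------------------------------- residualization

def _design(manifest: pd.DataFrame) -> np.ndarray:
    age = manifest["age"].to_numpy(dtype=float)
    sex = (manifest["sex"] == "male").to_numpy(dtype=float)
    return np.column_stack([np.ones(len(manifest)), age, sex])


def residualize_matrix(values: np.ndarray, manifest: pd.DataFrame) -> np.ndarray:
    """OLS residuals of each column on [1, age, sex], plus the grand mean.

    A collinear design (e.g. a single-sex, single-age cohort) skips
    adjustment with a warning rather than failing.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[0] == 1:
        v = v.T
    if v.shape[0] != len(manifest):
        raise ValueError("values and manifest disagree on subject count")
    if v.shape[0] < 3:
        raise ValueError("need at least 3 subjects to adjust for age and sex")
    x = _design(manifest)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        warnings.warn("collinear age/sex design; covariate adjustment skipped")
        return v.copy()
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta + v.mean(axis=0)


def residualize(values: Sequence[float], manifest: pd.DataFrame) -> np.ndarray:
    """Residualize a single per-subject measure on age and sex."""
    return residualize_matrix(np.asarray(values, dtype=float), manifest)[:, 0]


# -------------------------------------------------------- permutation engine

def _permuted_differences(
    values: np.ndarray, is_control: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted control-minus-patient mean differences.

    ``values`` is (n_subjects, K); returns (observed (K,), deltas (n_perm, K)).
    """
    n = values.shape[0]
    n_c = int(is_control.sum())
    n_p = n - n_c
    if n_c < 2 or n_p < 2:
        raise ValueError("both groups need at least 2 subjects")
    observed = values[is_control].mean(axis=0) - values[~is_control].mean(axis=0)
    total = values.sum(axis=0)
    deltas = np.empty((n_perm, values.shape[1]))
    for b in range(n_perm):
        rows = rng.permutation(n)[:n_c]
        s_c = values[rows].sum(axis=0)
        deltas[b] = s_c / n_c - (total - s_c) / n_p
    return observed, deltas


def _p_and_ci(observed: np.ndarray, deltas: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_perm = deltas.shape[0]
    # >= with a hair of tolerance so exact ties (e.g. observed 0) count
    thresh = np.abs(observed) - 1e-12 * np.maximum(1.0, np.abs(observed))
    exceed = (np.abs(deltas) >= thresh).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)
    lo, hi = np.percentile(deltas, [2.5, 97.5], axis=0)
    return p, lo, hi


def permutation_test(
    patient_values: Sequence[float],
    control_values: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
    measure_name: str = "measure",
    node: int | str = "global",
    rng: np.random.Generator | None = None,
) -> ComparisonResult:
    """Two-sided permutation comparison of one measure between groups."""
    pat = np.asarray(patient_values, dtype=float)
    con = np.asarray(control_values, dtype=float)
    values = np.concatenate([pat, con])[:, None]
    is_control = np.concatenate([np.zeros(len(pat), bool), np.ones(len(con), bool)])
    if rng is None:
        rng = np.random.default_rng(seed)
    observed, deltas = _permuted_differences(values, is_control, n_perm, rng)
    p, lo, hi = _p_and_ci(observed, deltas)
    return ComparisonResult(
        measure_name=measure_name,
        node=node,
        mean_patient=float(pat.mean()),
        mean_control=float(con.mean()),
        difference=float(observed[0]),
        ci_low=float(lo[0]),
        ci_high=float(hi[0]),
        p_value=float(p[0]),
        significant_after_bonferroni=bool(p[0] < threshold),
    )


# ------------------------------------------------------- per-subject measures

def subject_measures(
    net: MultiplexNetwork,
    gamma: float = 1.0,
    omega: float = 1.0,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """All nine global measures and the four nodal measure vectors for one
    subject's multiplex."""
    nodal = {
        "multilayer_clustering": metrics.multiplex_clustering(net),
        "multiplex_participation": metrics.multiplex_participation(net),
        "overlapping_strength": metrics.overlapping_strength(net),
        "weighted_multiplex_participation": metrics.weighted_multiplex_participation(net),
    }
    part = optimize_partition(net, gamma=gamma, omega=omega, restarts=restarts, seed=seed)
    glob = {
        "average_degree_overlap": metrics.global_average(metrics.degree_overlap(net)),
        "average_flexibility": metrics.global_average(flexibility(part)),
        "multilayer_modularity": part.quality,
        "average_multilayer_clustering": metrics.global_average(nodal["multilayer_clustering"]),
        "average_multiplex_participation": metrics.global_average(nodal["multiplex_participation"]),
        "average_overlapping_degree": metrics.global_average(metrics.overlapping_degree(net)),
        "average_overlapping_strength": metrics.global_average(nodal["overlapping_strength"]),
        "persistence": persistence(part),
        "average_weighted_multiplex_participation": metrics.global_average(
            nodal["weighted_multiplex_participation"]
        ),
    }
    return glob, nodal


# ------------------------------------------------------------ full comparison

def run_full_comparison(
    networks: Mapping[str, MultiplexNetwork],
    manifest: pd.DataFrame,
    config: ComparisonConfig | None = None,
) -> list[ComparisonResult]:
    """Compare every global and nodal measure between patients and controls.

    Returns nine global results (Bonferroni over the 9-measure family)
    followed by, for each of the four nodal measures, one result per node
    (Bonferroni over the N-node family within each measure).  One shared
    set of seeded label permutations is used for every measure.
    """
    if config is None:
        config = ComparisonConfig()
    missing = set(manifest["subject_id"]) - set(networks)
    if missing:
        raise ValueError(f"missing networks for subjects: {sorted(missing)[:5]}")
    subjects = list(manifest["subject_id"])
    n_nodes = networks[subjects[0]].n_nodes
    if any(networks[s].n_nodes != n_nodes for s in subjects):
        raise ValueError("subjects disagree on node count")

    glob_mat = np.empty((len(subjects), len(GLOBAL_MEASURES)))
    nodal_mat = np.empty((len(subjects), len(NODAL_MEASURES) * n_nodes))
    for row, sid in enumerate(subjects):
        sub_seed = int(np.random.SeedSequence([config.seed, row]).generate_state(1)[0] % 2**31)
        glob, nodal = subject_measures(
            networks[sid], gamma=config.gamma, omega=config.omega,
            restarts=config.restarts, seed=sub_seed,
        )
        glob_mat[row] = [glob[m] for m in GLOBAL_MEASURES]
        nodal_mat[row] = np.concatenate([nodal[m] for m in NODAL_MEASURES])

    if config.adjust_covariates:
        glob_mat = residualize_matrix(glob_mat, manifest)
        nodal_mat = residualize_matrix(nodal_mat, manifest)

    is_control = (manifest["group"] == "control").to_numpy()
    rng = np.random.default_rng(config.seed)
    values = np.concatenate([glob_mat, nodal_mat], axis=1)
    observed, deltas = _permuted_differences(values, is_control, config.n_perm, rng)
    p, lo, hi = _p_and_ci(observed, deltas)

    mean_p = values[~is_control].mean(axis=0)
    mean_c = values[is_control].mean(axis=0)

    thr_global = bonferroni_threshold(config.alpha, config.n_global_measures)
    thr_nodal = bonferroni_threshold(config.alpha, config.n_nodes or n_nodes)

    results: list[ComparisonResult] = []
    for k, name in enumerate(GLOBAL_MEASURES):
        results.append(ComparisonResult(
            measure_name=name, node="global",
            mean_patient=float(mean_p[k]), mean_control=float(mean_c[k]),
            difference=float(observed[k]), ci_low=float(lo[k]), ci_high=float(hi[k]),
            p_value=float(p[k]),
            significant_after_bonferroni=bool(p[k] < thr_global),
        ))
    offset = len(GLOBAL_MEASURES)
    for m, name in enumerate(NODAL_MEASURES):
        for node in range(n_nodes):
            k = offset + m * n_nodes + node
            results.append(ComparisonResult(
                measure_name=name, node=node,
                mean_patient=float(mean_p[k]), mean_control=float(mean_c[k]),
                difference=float(observed[k]), ci_low=float(lo[k]), ci_high=float(hi[k]),
                p_value=float(p[k]),
                significant_after_bonferroni=bool(p[k] < thr_nodal),
            ))
    return results
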