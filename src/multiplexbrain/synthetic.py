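"""Synthetic cohorts with the statistical structure the analysis assumes.

Real inputs to the pipeline are per-subject morphometric tables (7 features
over 62 cortical regions) and symmetric non-negative streamline-count
matrices from deterministic tractography, plus a subject manifest (group,
age, sex).  This module emulates those inputs so every downstream stage is
testable without MRI data:

* structural counts are drawn as truncated-normal noise around a planted
  modular template (4 modules over 62 nodes by default), giving block
  structure with within-module weights well above between-module weights;
* morphometric features share a population mean profile with its own
  (different) modular organization, plus subject-level noise, so
  morphometric-similarity edges are non-degenerate and the two layers'
  community structures only partly agree;
* ages ~ Normal(30, 8) truncated positive and sex ~ Bernoulli(0.18 male),
  the shape of the study cohort;
* group effects are applied to the patient group only, controls being the
  reference process.  With the identity :class:`GroupEffect` the two groups
  are exchangeable by construction.

The three effect knobs and their intended downstream directions:

* ``strength_scale`` < 1 multiplies each patient structural edge by an
  independent factor with mean ``strength_scale`` (heterogeneous streamline
  loss).  The raw matrix total scales by ``strength_scale`` in expectation
  while the maximum entry shrinks much less, so overlapping strength drops
  even after layer-wise max normalization.
* ``intra_module_rewiring`` moves a fraction of between-module edges onto
  within-module pairs, raising modularity.
* ``clustering_damp`` opens a fraction of closed triangles (removing each
  sampled triangle's weakest edge), lowering the clustering coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layers import LayerMatrix
from .msn import DEFAULT_FEATURES

# per-feature location/scale used to dress z-scale feature values in
# realistic units (mm, mm^2, mm^3, ...); the MSN is invariant to these.
FEATURE_LOC = np.array([2.5, 700.0, 0.12, 0.02, 15.0, 5.0, 2000.0])
FEATURE_SCALE = np.array([0.15, 120.0, 0.02, 0.006, 3.0, 1.2, 350.0])


@dataclass(frozen=True)
class GroupEffect:
    """Patient-group perturbations; identity factors give a null cohort."""

    strength_scale: float = 1.0
    intra_module_rewiring: float = 0.0
    clustering_damp: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.strength_scale <= 1.0):
            raise ValueError("strength_scale must be in (0, 1]")
        for name in ("intra_module_rewiring", "clustering_damp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (
            self.strength_scale == 1.0
            and self.intra_module_rewiring == 0.0
            and self.clustering_damp == 0.0
        )


@dataclass(frozen=True)
class CohortSpec:
    """Cohort shape and generator settings; defaults reproduce the study shape
    (82 patients, 53 controls, 62 regions, 7 features)."""

    n_patients: int = 82
    n_controls: int = 53
    n_rois: int = 62
    n_features: int = 7
    seed: int = 0
    effect: GroupEffect = field(default_factory=GroupEffect)
    confound_age_sex: bool = True
    n_modules: int = 4

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_rois", "n_features", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def module_assignments(n_rois: int, n_modules: int) -> np.ndarray:
    """Contiguous near-equal blocks of nodes, module id per node."""
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    return (np.arange(n_rois) * n_modules) // n_rois


def planted_template(
    n_rois: int,
    n_modules: int,
    seed: int,
    within_mean: float = 150.0,
    between_mean: float = 50.0,
    within_sd: float = 30.0,
    between_sd: float = 15.0,
    between_density: float = 0.5,
) -> LayerMatrix:
    """Block-structured streamline-count template.

    Within-module pairs always carry an edge (mean ``within_mean``); a
    fraction ``between_density`` of between-module pairs carry a weaker edge
    (mean ``between_mean``).  Symmetric, zero diagonal, reproducible from
    ``seed``.
    """
    modules = module_assignments(n_rois, n_modules)
    rng = np.random.default_rng(seed)
    same = modules[:, None] == modules[None, :]
    w = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    same_u = same[iu]
    w_u = np.where(
        same_u,
        np.clip(rng.normal(within_mean, within_sd, iu[0].size), 0.0, None),
        np.clip(rng.normal(between_mean, between_sd, iu[0].size), 0.0, None)
        * (rng.random(iu[0].size) < between_density),
    )
    w[iu] = w_u
    w = w + w.T
    return LayerMatrix(np.round(w), label="white")


# ------------------------------------------------------------ group effects

def _rewire_within(counts: np.ndarray, modules: np.ndarray, frac: float,
                   rng: np.random.Generator) -> None:
    """Move a fraction of between-module edge weights onto within-module pairs."""
    iu = np.triu_indices(counts.shape[0], k=1)
    between = np.flatnonzero((modules[iu[0]] != modules[iu[1]]) & (counts[iu] > 0))
    n_move = int(round(frac * between.size))
    if n_move == 0:
        return
    chosen = rng.choice(between, size=n_move, replace=False)
    for e in chosen:
        i, j = iu[0][e], iu[1][e]
        home = modules[i] if rng.random() < 0.5 else modules[j]
        anchor = i if modules[i] == home else j
        mates = np.flatnonzero((modules == home) & (np.arange(counts.shape[0]) != anchor))
        target = int(rng.choice(mates))
        counts[anchor, target] += counts[i, j]
        counts[target, anchor] = counts[anchor, target]
        counts[i, j] = counts[j, i] = 0.0


def _open_triangles(counts: np.ndarray, frac: float, rng: np.random.Generator) -> None:
    """Remove the weakest edge of a sampled fraction of closed triangles."""
    a = counts > 0
    n = counts.shape[0]
    tri = np.argwhere(
        a[:, :, None] & a[:, None, :] & a[None, :, :]
    )  # ordered triples (i, j, k) with all three edges
    tri = tri[(tri[:, 0] < tri[:, 1]) & (tri[:, 1] < tri[:, 2])]
    n_open = int(round(frac * len(tri)))
    if n_open == 0:
        return
    chosen = tri[rng.choice(len(tri), size=n_open, replace=False)]
    for i, j, k in chosen:
        edges = [(i, j), (j, k), (i, k)]
        weights = [counts[e] for e in edges]
        if min(weights) == 0.0:
            continue  # triangle already opened by an earlier removal
        u, v = edges[int(np.argmin(weights))]
        counts[u, v] = counts[v, u] = 0.0


def _scale_strength(counts: np.ndarray, scale: float, rng: np.random.Generator) -> None:
    """Heterogeneous edge-wise attenuation with mean ``scale``."""
    if scale >= 1.0:
        return
    lo = max(0.0, 2.0 * scale - 1.0)
    hi = 2.0 * scale - lo
    iu = np.triu_indices(counts.shape[0], k=1)
    factors = rng.uniform(lo, hi, iu[0].size)
    counts[iu] = np.round(counts[iu] * factors)
    counts.T[iu] = counts[iu]


def apply_group_effect(counts: np.ndarray, modules: np.ndarray, effect: GroupEffect,
                       rng: np.random.Generator) -> np.ndarray:
    """Patient-group transform of a raw structural count matrix."""
    out = counts.astype(float).copy()
    if effect.intra_module_rewiring > 0:
        _rewire_within(out, modules, effect.intra_module_rewiring, rng)
    if effect.clustering_damp > 0:
        _open_triangles(out, effect.clustering_damp, rng)
    if effect.strength_scale < 1.0:
        _scale_strength(out, effect.strength_scale, rng)
    return out


# ------------------------------------------------------------- the cohort

def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, np.ndarray]]:
    """Generate (manifest, morphometric tables, raw structural count matrices).

    Fully reproducible from ``spec.seed``.  Subject ids are ``sub-P###`` for
    patients and ``sub-C###`` for controls; tables are region x feature
    DataFrames; count matrices are symmetric, non-negative, zero-diagonal
    float arrays of integer-valued counts.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_template, ss_pop, ss_subjects = root.spawn(3)
    pop_rng = np.random.default_rng(ss_pop)

    template = planted_template(spec.n_rois, spec.n_modules, seed=ss_template)
    modules = module_assignments(spec.n_rois, spec.n_modules)

    # gray-matter population profile with its own modular organization so the
    # two layers' community structures only partly agree (mid-range
    # flexibility), emulating distinct morphometric vs tractographic axes.
    gray_modules = pop_rng.permutation(modules)
    centroids = pop_rng.normal(0.0, 1.0, (spec.n_modules, spec.n_features))
    mu = centroids[gray_modules] + pop_rng.normal(0.0, 0.6, (spec.n_rois, spec.n_features))

    feat_names = list(DEFAULT_FEATURES[: spec.n_features]) + [
        f"feature_{k}" for k in range(len(DEFAULT_FEATURES), spec.n_features)
    ]
    loc = np.resize(FEATURE_LOC, spec.n_features)
    scale = np.resize(FEATURE_SCALE, spec.n_features)
    if spec.n_rois == 62:
        from .atlas import default_atlas  # deferred: atlas pulls in pandas I/O

        roi_names = list(default_atlas().names)
    else:
        roi_names = [f"roi_{i:03d}" for i in range(spec.n_rois)]

    n_total = spec.n_patients + spec.n_controls
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    subject_ids = [f"sub-P{i:03d}" for i in range(spec.n_patients)] + [
        f"sub-C{i:03d}" for i in range(spec.n_controls)
    ]

    manifest_rows = []
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, np.ndarray] = {}
    for sid, group, child in zip(subject_ids, groups, ss_subjects.spawn(n_total)):
        rng = np.random.default_rng(child)
        age = 0.0
        while age <= 0.0:
            age = rng.normal(30.0, 8.0)
        sex = "male" if rng.random() < 0.18 else "female"

        z = mu + rng.normal(0.0, 0.5, (spec.n_rois, spec.n_features))
        tables[sid] = pd.DataFrame(loc + scale * z, index=roi_names, columns=feat_names)

        c = np.clip(
            template.weights + _sym_noise(spec.n_rois, 15.0, rng), 0.0, None
        )
        c[template.weights == 0] = 0.0
        _drop_edges(c, 0.05, rng)
        if spec.confound_age_sex:
            q = min(max(0.002 * (age - 30.0), 0.0), 0.15) + (0.01 if sex == "male" else 0.0)
            _drop_edges(c, q, rng)
        c = np.round(c)
        if group == "patient" and not spec.effect.is_identity:
            c = apply_group_effect(c, modules, spec.effect, rng)
        np.fill_diagonal(c, 0.0)
        counts[sid] = c
        manifest_rows.append({"subject_id": sid, "group": group, "age": age, "sex": sex})

    manifest = pd.DataFrame(manifest_rows)
    return manifest, tables, counts


def _sym_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    noise = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    noise[iu] = rng.normal(0.0, sd, iu[0].size)
    return noise + noise.T


def _drop_edges(counts: np.ndarray, prob: float, rng: np.random.Generator) -> None:
    """Zero each present edge independently with probability ``prob``."""
    if prob <= 0:
        return
    iu = np.triu_indices(counts.shape[0], k=1)
    drop = (rng.random(iu[0].size) < prob) & (counts[iu] > 0)
    vals = counts[iu]
    vals[drop] = 0.0
    counts[iu] = vals
    counts.T[iu] = vals
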