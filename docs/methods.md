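# Methods

## Pipeline overview

Each subject contributes a two-layer multiplex over a fixed 62-region
cortical parcellation (31 regions per hemisphere, Desikan-Killiany style;
the packaged atlas order is the single source of node indexing). The gray
layer is a morphometric similarity network; the white layer is a
max-normalized structural connectivity matrix. All multilayer measures are
computed per subject, then compared between groups with covariate-adjusted
permutation tests.

## Layer construction

**Morphometric similarity.** The 7 features are z-scored across the 62
regions (sample sd, ddof = 1) before correlating; without this, surface
area and volume dominate by sheer magnitude. The MSN edge is the Pearson
correlation across the 7 z-scored features of a region pair. Correlations
over 7 points are noisy by construction; that is a property of the design,
not something the package smooths away. Negative correlations are clipped
to 0 rather than taken in absolute value: anti-similarity is not evidence
of a connection, and clipping keeps both layers non-negative as the
strength/participation/clustering formulas assume.

**Structural layer.** Raw streamline counts are symmetric, non-negative
and zero-diagonal (asymmetry above 1e-8 is treated as file corruption and
rejected; smaller asymmetry is averaged away). Each subject's matrix is
divided by its maximum entry. This puts the white layer on the same [0, 1]
scale as the correlation-valued gray layer — otherwise counts in the
hundreds would dominate every strength-type measure — and makes all
weighted measures invariant to global scaling of counts. No density
threshold is applied: thresholding would introduce a free parameter the
weighted pipeline does not need. The normalization is recorded in run
metadata.

## Measures

Degree-type measures use the binary support of each layer; strength-type
measures use the weights. Two deliberately distinct "overlap" notions are
exposed: *degree overlap* counts neighbors present in **every** layer
(an intersection), while *overlapping degree* sums a node's degrees
**across** layers. The interlayer clustering coefficient uses cube-root
weight products over cross-layer triangles (the path layer alternates
a→a'→a) normalized by (M−1)·Σ_a k(k−1); on 0/1 weights it reduces exactly
to the binary multiplex clustering coefficient, and under the [0, 1]
weight contract it stays in [0, 1]. Every ratio measure is defined as 0
when its denominator is 0, so isolated nodes contribute zeros rather than
NaNs to global averages.

## Community structure

Multilayer modularity follows the standard categorical-multiplex quality
function with a weighted Newman-Girvan null model per layer and uniform
interlayer coupling ω between a node's copies; the normalization
2μ = Σ_a 2m_a + N·M·(M−1)·ω counts intra-layer weight plus coupling over
ordered layer pairs, and diagonal null-model terms are included (so the
singleton partition has a simple closed form used as a test oracle).

Defaults γ = 1, ω = 1: these are the common defaults of multilayer
community detection and are exposed in configuration and recorded in
output metadata. Flexibility and persistence are computed from the same
optimized partition that supplies Q — one pipeline, one partition.

The optimizer is a generalized Louvain on the supra-modularity matrix of
the N·M node-layer copies: randomized greedy node moves to the best
community (a fresh singleton always being an option), aggregation, and a
**leaf-level refinement** pass that re-runs node moves on the original
supra-nodes starting from the aggregated solution. The refinement can
split nodes that aggregation has locked together, a known failure mode of
plain Louvain; with it, the best of 10 seeded restarts (the default)
reaches the exhaustive-enumeration optimum on every small random multiplex
in the test suite (checked with 32 restarts there). All randomness (visit
order, restarts) derives from a single integer seed; runs are
bit-reproducible. Returned quality is recomputed from the labels with the
quality function, so the two are self-consistent by construction.

## Group comparison

Each measure is residualized by OLS on [1, age, sex] over the pooled
sample, keeping the grand mean; group labels of the residuals are then
permuted (a Freedman-Lane-style convention — only "adjusted for age and
sex" is assumed, not a particular toolbox's internals). A collinear design
(single-sex or single-age cohort) skips adjustment with a warning. The
two-sided p-value uses the add-one estimator
p = (#{|Δ*| ≥ |Δ|} + 1)/(n_perm + 1), which cannot be smaller than
1/(n_perm+1); the permutation 2.5th/97.5th percentiles are reported as the
95% interval. One shared set of seeded permutations serves all measures of
a run. The difference is reported as control − patient.

Bonferroni families follow the reporting structure: α/9 across the nine
global measures, α/62 within each nodal measure (not pooled across the
four). Thresholds are rendered truncated to 4 decimals (0.05/9 → 0.0055,
0.05/62 → 0.0008), matching how such tables conventionally print them.
Note a structural consequence of the add-one estimator: at the default
1000 permutations the smallest attainable p is 1/1001 ≈ 0.000999, which
exceeds the nodal threshold 0.05/62 ≈ 0.000806 — nodal Bonferroni
significance requires n_perm ≥ 1250 (e.g. 2000). The default stays at 1000
permutations, the study-standard setting, and the limitation is stated
here rather than silently "fixed" by a different estimator.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not the biophysics. Defaults reproduce the study shape: 82 patients, 53
controls, ages ~ Normal(30, 8) truncated positive, 18% male, 62 regions,
7 features.

* **Structural counts**: truncated-normal noise (sd 15) around a planted
  4-module block template (within-module mean 150, between 50 with 50%
  density), 5% random edge dropout per subject, rounded to integer counts.
  Four modules give mid-range modularity and a non-trivial community
  structure for flexibility/persistence.
* **Morphometric features**: a shared population profile whose modular
  organization is a *permuted* version of the structural one, plus subject
  noise, dressed in realistic per-feature units (the MSN is invariant to
  those). The partial disagreement between the two layers' community
  structures is intentional: it produces non-degenerate flexibility, as in
  real gray/white matter data.
* **Covariate confounding** (on by default): edge dropout mildly increases
  with age and male sex, so covariate adjustment has something real to do.
  Confounds apply identically to both groups, preserving exchangeability
  under the identity effect.
* **Group effects** apply to patients only; controls are the reference
  process. `intra_module_rewiring` moves between-module edges inside
  modules (modularity ↑); `clustering_damp` removes the weakest edge of a
  fraction of closed triangles (clustering ↓); `strength_scale` attenuates
  each edge by an independent Uniform factor with mean equal to the scale
  (heterogeneous streamline loss). The heterogeneity matters: expected raw
  totals scale by the factor, while the matrix maximum shrinks much less,
  so the deficit survives per-subject max normalization — a uniform scale
  would be normalized away exactly. Effect magnitudes are free calibration
  knobs, not estimates of any real cohort.

What passing tests on these cohorts shows: the measures, optimizer and
statistics behave correctly on data with the assumed structure
(modular weighted layers, partially aligned across layers, mild covariate
effects). What it does not show: robustness to acquisition artifacts,
parcellation misregistration, non-modular topologies, or real
morphometry-tractography coupling.

## Numerical conventions and problem sizes

Tolerances: matrix round-trips hold to 1e-12; oracle equivalence for all
measures and for the modularity quality function is asserted at 1e-12;
optimizer-vs-exhaustive agreement at 1e-10. Louvain move gains use a 1e-12
tie tolerance (ties keep the current community). Degenerate inputs:
constant feature columns, constant z-scored region vectors, empty layers
and negative counts all raise errors naming the offender; an all-zero
layer normalizes to itself with a warning.

Simulation sizes used by the checked-in analyses and acceptance run: the
full 82+53 cohort for the worked example; 30+30 at strength scale 0.6 for
direction recovery; 500 replicates of 20+20 with 200 permutations for
null calibration; exhaustive modularity checks on multiplexes of up to 5
nodes (Bell(10) = 115,975 partitions, enumerated in chunks). These sizes
give stable conclusions while keeping any single run in the seconds-to-
a-minute range.

## Known limitations

* Pearson over 7 features makes individual MSN edges noisy; group-level
  statistics absorb this but single-edge inference would not.
* The clipped-negative convention discards anti-correlation information.
* The exact optimizer variant and coupling normalization differ across
  multilayer toolboxes; absolute Q values may differ in the third decimal
  between implementations, which is why exhaustive enumeration on small
  inputs — not another toolbox — is the ground truth here.
* Nodal Bonferroni significance is unattainable at the default 1000
  permutations (see above); raise `n_perm` for nodal inference.
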