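# multiplexbrain

Two-layer multiplex analysis of structural brain networks: a gray-matter
**morphometric similarity network** (MSN) and a white-matter **structural
connectivity** layer over a shared 62-region cortical parcellation,
multilayer graph measures on the resulting multiplex, and covariate-adjusted
permutation comparison of two cohorts (e.g. patients vs healthy controls)
under Bonferroni control.

It is aimed at neuroimaging groups who already have per-subject FreeSurfer
morphometry (7 features per region: cortical thickness, surface area, mean
curvature, Gaussian curvature, folding index, curvature index, gray matter
volume) and tractography streamline-count matrices, and want the multilayer
measure suite and group statistics without a GUI toolbox. A synthetic-cohort
generator emulates both inputs, so the entire pipeline is testable — and is
exercised end to end in this repository — without MRI data.

## The model

Each subject yields a two-layer multiplex over the same N = 62 nodes:

* **Gray layer.** Features are z-scored across regions; the MSN edge
  `w_ij = max(0, corr(z_i, z_j))` is the Pearson correlation of regions'
  z-scored feature vectors, negatives clipped so both layers are
  non-negative.
* **White layer.** Streamline counts, max-normalized to [0, 1] so both
  layers live on a common scale (all weighted measures are then invariant
  to global count scaling).

On the multiplex (M = 2 layers, binary degrees `k_i^[a]`, strengths
`s_i^[a]`) the package computes, per node and as global averages:
overlapping degree `O_i = Σ_a k_i^[a]`, overlapping strength
`S_i = Σ_a s_i^[a]`, degree overlap (neighbors present in *every* layer),
multiplex participation `P_i = M/(M−1)·(1 − Σ_a (k_i^[a]/O_i)²)` and its
strength-weighted twin, and an interlayer clustering coefficient with
Onnela-style cube-root weight products over cross-layer triangles.

Community structure uses the multilayer modularity quality function

    Q = (1/2μ) Σ_{ij,a,a'} [ (w_ij^[a] − γ s_i^[a] s_j^[a] / 2m_a) δ_aa'
                             + δ_ij ω (1 − δ_aa') ] δ(g_ia, g_ja')

optimized by a generalized Louvain ascent on the supra-modularity matrix
(greedy moves + aggregation + leaf-level refinement, best of seeded
restarts). From the optimized partition come multilayer modularity Q, nodal
**flexibility** (fraction of layer transitions changing community) and
**persistence** (fraction keeping it); for M = 2 their averages sum to 1.

Group comparison: each measure is residualized on age and sex over the
pooled cohort, then tested with a label-permutation test (difference of
group means, control − patient; two-sided add-one p-value, so
p ≥ 1/(n_perm+1)). Bonferroni control is applied per family: α/9 over the
nine global measures, α/62 within each of the four nodal measures.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort of 82 patients and 53 controls whose patient networks carry a
planted strength deficit, intra-module rewiring and triangle opening:

```
python analysis/01_simulate_cohort.py
python analysis/02_build_layers.py
python analysis/03_compute_measures.py
python analysis/04_compare_groups.py
python analysis/05_null_calibration.py
```

Step 04 prints the global comparison table (1000 permutations, α/9):

```
measure                                         pat      con     diff        p  sig
average_degree_overlap                        9.090   16.454    7.363   0.0010  *
average_flexibility                           0.611    0.623    0.012   0.0749
multilayer_modularity                         0.419    0.397   -0.022   0.0010  *
average_multilayer_clustering                 0.106    0.158    0.052   0.0010  *
average_multiplex_participation               0.954    0.982    0.028   0.0010  *
average_overlapping_degree                   47.879   63.982   16.103   0.0010  *
average_overlapping_strength                 16.764   23.503    6.738   0.0010  *
persistence                                   0.389    0.377   -0.012   0.0749
average_weighted_multiplex_participation      0.919    0.984    0.065   0.0010  *
```

Reading it: `diff` is control − patient after age/sex adjustment, so the
planted effects surface with the intended signs — multilayer modularity is
*higher* in patients (negative difference) while clustering, overlapping
strength and weighted participation are *lower*; flexibility and
persistence do not differ. `p = 0.0010` is the add-one floor at 1000
permutations. Step 05 confirms calibration on null cohorts (rejection rate
0.062 at α = 0.05 over 500 replicates, KS uniformity p = 0.28).

A `multiplexbrain` CLI offers the same stages for on-disk data
(`simulate`, `build-msn`, `build-layers`, `metrics`, `compare`, `run-all`);
see `multiplexbrain --help`.

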