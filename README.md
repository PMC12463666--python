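# surfmorph

Surface-mesh morphometry of nested tissue layers — built for vertex-wise
analysis of abdominal subcutaneous adipose tissue (ASAT) thickness, the fat
layer between the skin and the abdominal body cavity, as studied in
population MRI cohorts.

Volumetric fat measures collapse a 3D organ into one number. `surfmorph`
instead treats the tissue as a surface-indexed field: every subject's outer
tissue envelope is put into vertex-wise correspondence with a template mesh,
thickness is measured at each vertex, and the cohort becomes a
subjects × vertices matrix on which spatial statistics run. The package
covers the full chain:

1. **geometry** — binary segmentation masks (NIfTI) → smoothed triangle
   meshes (marching cubes + umbrella Laplacian), vertex adjacency, vertex
   areas, plane-based cropping, exact point-to-triangle closest-point queries.
2. **correspondence** — ICP rigid/affine registration with SVD-Procrustes
   steps, mean-shape template construction, and template propagation by
   closest-point projection so all subjects share one vertex indexing.
3. **thickness** — per-vertex thickness `T_i(v) = min_{x ∈ S_inner} ‖p_v − x‖`
   (exact closest-point distance to the inner surface), per-subject-maximum
   QC (study ceiling 154 mm), the sex-specific fat-to-muscle-ratio rule for
   the lipodystrophy indicator (FMR > 1.2 in women, > 1.7 in men), and
   cohort stacking.
4. **spm** — statistical parametric maps: per-vertex OLS
   `y_v = Xβ_v + ε` on standardised data, threshold-free cluster enhancement
   `TFCE(v) = Σ_h e_v(h)^E · h^H · dh` (E = 0.5, H = 2), Freedman–Lane
   permutation p values per association sign, Benjamini–Hochberg FDR over
   vertices, and summaries as median β̂ (IQR) with signed significance areas.
5. **longitudinal** — per-vertex random-intercept linear mixed models
   `y_iv = x_ivᵀβ + b_i + ε_iv` fit by REML (1-D profile over
   ρ = σ_b²/σ²), visit × disease interactions, FDR-controlled change maps.
6. **ssa** — robust sparse PCA of the thickness matrix (median centring,
   alternating soft-threshold regression, projection deflation; the
   sparsity-0 limit is exactly classical PCA), shape scores, and ±3 SD
   shape reconstructions per component.
7. **survival** — Cox proportional-hazards comparison of a *volume model*
   (adjustments + total tissue volume) against a *thickness model*
   (adjustments + leading PC scores), reported as HRs with 95% CIs, FDR-
   adjusted p values, AIC and Harrell's c-index.
8. **synthetic** — a cohort generator (ellipsoid layers, angular bump
   effect regions, declared covariate distributions, proportional-hazards
   outcomes) whose analytic radial thickness function makes every planted
   quantity recoverable, so the whole chain is testable without restricted
   cohort data.

## Worked example

`examples/03_statistical_parametric_map.py` plants a +0.5 mm-per-SD age
effect on 20% of a 2,562-vertex template, fits the SPM chain with 500
permutations, and prints:

```
covariate sign  median_beta  iqr_beta  significance_area_pct  n_significant
      age  neg          NaN       NaN                  0.000              0
      age  pos        0.494     0.116                 22.404            574
   hgs_kg  neg          NaN       NaN                  0.000              0
   hgs_kg  pos          NaN       NaN                  0.000              0

Dice overlap of detected vs planted region: 0.95
median coefficient over detected region: 0.494 mm/SD
```

The detected positive area (22.4% of vertices) matches the planted cap, the
recovered median coefficient sits at the planted 0.5 mm per SD of age, and
the null covariate (grip strength) shows no significant area at q = 0.05.
The other examples walk mask→mesh→thickness (01), template correspondence
(02), longitudinal change maps (04), and shape scores + survival (05).

A thin CLI exists for shell-driven reruns of whole studies:

```bash
surfmorph simulate --spec cfg.json --out study/ --seed 17
surfmorph run --config cfg.json --out study/          # all stages
```

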