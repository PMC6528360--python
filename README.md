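# ontomorph

Geometric morphometrics of ontogenetic shape change in 2D landmark data.

`ontomorph` is built for evolutionary and developmental biologists studying
how body shape changes across life stages in cross-sectional samples — the
motivating case is demersal fishes with a bipartite life history (pelagic
juveniles, benthic adults) sampled as several species across several
centroid-size-defined ontogenetic stages.  It implements the full analysis
chain such a study needs:

- **Generalized Procrustes Analysis (GPA)** with translation, unit
  centroid-size scaling, and proper rotations, including
  bending-energy-minimizing **sliding semilandmarks**;
- **thin-plate-spline machinery**: the bending-energy matrix of the
  consensus, principal warps `BE_j`, partial-warp scores, and the uniform
  (affine) component;
- **shape PCA** of the aligned coordinates;
- **Procrustes ANOVA** with sequential (type-I) sums of squares and a
  **residual randomization permutation procedure (RRPP)** for p-values and
  Z effect sizes;
- **allometric-slope comparison**: pairwise angles between per-group
  multivariate regression vectors of shape on log centroid size, tested by
  RRPP under the common-slope model;
- **phenotypic trajectory analysis**: magnitude (path length), direction
  (angle between principal axes of stage means, θ ∈ [0°, 90°]), and shape
  (Procrustes distance D between stage-mean configurations) of ontogenetic
  trajectories, with permutation tests;
- **morphological disparity** as Procrustes variance (trace of the group
  covariance matrix, divisor *n*) with pairwise permutation tests;
- **modularity and integration**: the covariance ratio **CR** (between- vs
  within-module squared covariances, random-landmark-partition null) and
  the global integration slope **GI** (OLS of ln partial-warp variance on
  ln bending energy; −1 = self-similar, < −1 integrated, > −1
  disintegrated);
- a **synthetic-data generator** that emulates the whole study design
  (species mean offsets, piecewise-linear trajectories with stagewise
  convergence and adult divergence, species-specific allometric vectors,
  head vs trunk+tail block covariance) with a full ground-truth record, so
  every stage of the pipeline has a recovery test.

Data enter as TPS landmark files (with `CURVES`/`POINTS` semilandmark
blocks), classifier CSV/TSV tables, and optional slider/partition tables;
juveniles are binned into ontogenetic stages by per-species centroid-size
tertiles.

## Worked example

```python
import ontomorph as om

cfg = om.four_species_scenario()            # 4 species x 4 stages, 390 specimens
configs, metadata, truth = om.generate_dataset(cfg)
aligned = om.gpa_align(configs, slide=True, metadata=metadata)

tab = om.procrustes_anova(aligned, "species + life_stage", n_perm=999, seed=1)
print(tab.to_frame()[["term", "df", "SS", "F", "Z", "p"]].head(2).to_string(index=False))

traj = om.compare_trajectories(aligned, n_perm=999, seed=2)
print(traj.table[["pair", "theta", "P_theta"]].head(3).to_string(index=False))
```

prints (seed-exact):

```
      term  df       SS          F        Z     p
   species   3 0.467400  20.094783 6.432223 0.001
life_stage   1 2.102047 271.118064 8.776668 0.001
```

```
                    pair     theta  P_theta
D_annularis - D_puntazzo 45.967164    0.001
  D_annularis - D_sargus 56.770298    0.001
D_annularis - D_vulgaris 54.799556    0.001
```

Reading: the life-stage effect on shape (F ≈ 271) dwarfs the species
effect (F ≈ 20) — ontogeny dominates the morphospace — while every pair of
species still differs significantly in the *direction* its trajectory
takes through shape space (all θ large, all p at the permutation floor).

The same graph runs from the shell:

```sh
ontomorph simulate --seed 1 --out sim/
ontomorph all --tps sim/landmarks.tps --classifiers sim/classifiers.csv \
    --partition sim/partition.csv --n-perm 999 --seed 1 --out results/
```

writing aligned coordinates, PCA scores/variances, ANOVA tables, the
slope-angle matrix, trajectory comparisons, disparity tables, per-cell
CR/GI, and a run manifest; reruns with the same seed are byte-identical.

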