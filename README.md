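# mglia

Quantitative profiling of microglia for neurodegeneration studies:
single-cell **morphometry** from binary masks, **statistical learning** on
the resulting feature tables, and **bulk transcriptomics** of sorted
microglia — with seeded synthetic generators so the whole pipeline can be
exercised and validated without any imaging or sequencing data.

Microglia shift from a ramified, surveillant shape toward de-ramified,
compact morphologies as they activate, and this shift is accompanied by
transcriptional reprogramming. The package implements the complete
analysis chain used to characterize that shift in a mouse model of
Machado–Joseph disease (spinocerebellar ataxia type 3), but every stage is
generic.

## What it computes

**Morphometry** (`mglia.morphometry`, `mglia.skeleton`). For each cell
mask (one 8-connected component, μm/px calibration, default 0.31):

- 10 skeleton features from a Zhang–Suen thinning classified into
  endpoint / slab / junction pixels and decomposed into branches:
  branch count, voxel-class counts, average/max/total branch length
  (1/√2 step metric), the chord of the longest branch ("Euclidean
  distance"), and triple/quadruple points.
- 15 shape features: box-counting fractal dimension, gliding-box
  lacunarity Λ = (σ/μ)², convex-hull area/perimeter/circularity over
  pixel centers, minimum bounding circle, centroid radii statistics,
  maximum hull span, hull density, cell area/perimeter (calibrated Moore
  contour) and circularity 4πA/P².
- Culture and tissue metrics: transformation index P²/(4πA), Feret
  diameter, bead-weighted phagocytic efficiency, and Iba-1 cell density
  per area and volume.

**Morphology statistics** (`mglia.morpho_stats`): per-feature Student
t-tests, PCA, k-means with the cluster count chosen from the MSE-vs-k
elbow (log-knee or largest-drop rule), cluster × genotype composition, and
a nested 5×5 cross-validated gradient-boosted-tree classifier with
total-gain feature importance.

**Transcriptomics** (`mglia.transcriptomics`): reads-per-million
normalization; differential expression on log2(RPM+1) with empirical-Bayes
variance moderation (prior df and scale estimated from the variance
ensemble; posterior s² = (d₀s₀² + d·s²)/(d₀+d)); the DEG filter
|FC| > 1 ∧ p < 0.05 ∧ FDR < 0.1 with signed linear fold changes; exact
Fisher overlap tests with Baptista–Pike odds-ratio intervals and
directional concordance counts; marker-panel purity; qPCR 2^−ΔΔCT.

**Synthetic data** (`mglia.synthetic`): a random-walk cell-growth model
spanning ramified → activated morphologies, multivariate-normal feature
tables with planted effect sizes, gamma–Poisson count matrices with
planted up/down genes, and direction-annotated gene sets with exact
planted overlap — all pure functions of their spec and seed.

## Worked example

```python
from mglia.synthetic import ramified_preset, activated_preset, simulate_cell_mask
from mglia.morphometry import cell_feature_vector

for preset in (ramified_preset, activated_preset):
    mask, truth = simulate_cell_mask(preset(seed=7))
    f = cell_feature_vector(mask)
    print(truth["label"], {k: round(f[k], 2) for k in
          ("n_branches", "total_branch_length", "convex_hull_area",
           "density", "cell_circularity")})
```

```
ramified {'n_branches': 28.0, 'total_branch_length': 176.63, 'convex_hull_area': 396.56, 'density': 0.15, 'cell_circularity': 0.02}
activated {'n_branches': 5.0, 'total_branch_length': 20.84, 'convex_hull_area': 84.86, 'density': 0.65, 'cell_circularity': 0.28}
```

The activated cell has far fewer/shorter branches and a smaller hull but
higher density and circularity — the canonical activation signature
(lengths in μm, areas in μm²).

Directional overlap of two gene lists (101 and 1000 genes with 27 shared,
17 of them concordant, in a 23,930-gene universe):

```python
from mglia.synthetic import simulate_overlap_gene_sets
from mglia.transcriptomics import fisher_overlap

a, b, _ = simulate_overlap_gene_sets(23930, (101, 1000), 27, 17, seed=0)
res = fisher_overlap(a, b, universe_size=23930)
print(res.table, f"{res.fisher_p:.3g}", f"{res.odds_ratio:.3g}",
      (round(res.or_ci_low, 2), round(res.or_ci_high, 1)),
      res.concordant, res.discordant)
```

```
(27, 74, 973, 22856) 5.66e-15 8.57 (5.35, 13.4) 17 10
```

A 27-gene overlap is overwhelmingly non-random (Fisher p ≈ 6·10⁻¹⁵, odds
ratio 8.6 with exact 95% CI 5.4–13.4), and 17 of the 27 shared genes move
in the same direction in both lists.

## Command line

```
mglia simulate  --seed 1 --out runs/sim --masks 5   # synthetic data + truth
mglia morphology runs/sim/masks --out runs/morpho   # masks → 25-feature table
mglia analyze   runs/sim/features.tsv --out runs/ml # t-tests, PCA, elbow, GBT
mglia rnaseq    runs/sim/counts.tsv runs/sim/groups.tsv --out runs/deg
```

All results go to versioned TSV/JSON files; logs go to standard error;
every run writes a manifest with config echo and output checksums.

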