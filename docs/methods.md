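# Methods

This note documents the models, conventions and numerical choices behind
`mglia`, and what the synthetic validation does and does not establish.

## Single-cell morphometry

**Skeletonization and pixel classes.** Masks are thinned with Zhang–Suen
2D thinning (8-connectivity), the behavior of the ImageJ Skeletonize
routine most morphometry workflows rely on. Skeleton pixels are
classified by the crossing number — the number of maximal runs of
foreground positions around the pixel's 8-neighbor ring: one run is an
endpoint, two a slab (branch interior), three or more a junction. On
clean thinned skeletons this coincides with the simpler neighbor-count
convention (1 / 2 / ≥3 neighbors); it differs only at staircase corners
of one-pixel paths, which the crossing number correctly treats as branch
interior rather than spurious junctions. Adjacent junction pixels merge
into junction clusters; triple and quadruple points are clusters with
exactly three or four incident branches.

**Branches.** A branch is a pixel path from one terminal (endpoint or
junction cluster) through slab pixels to another; closed loops with no
terminal count as one closed branch. Path length uses the standard step
metric (1 per orthogonal step, √2 per diagonal step) times the μm/px
calibration (default 0.31 μm/px, the confocal setting of the motivating
study). Each branch carries the chord between its end pixels. Because no
published convention fixes the per-cell summary of per-branch chords, the
canonical `euclidean_distance` is the chord of the longest branch (so the
chord ≤ path invariant ties it to `max_branch_length`); the mean chord is
also emitted (`euclidean_distance_mean` from the skeleton layer).

**Hull and shape descriptors.** The convex hull is taken over foreground
pixel centers (Qhull). Consequence, stated rather than hidden: a convex
blob's pixel-count area can slightly exceed its vertex-polygon hull area,
so `density` (pixel count / hull area in px²) can exceed 1; this matches
the point-hull behavior of the common fractal-analysis toolchain. The
bounding circle is the minimum enclosing circle of the hull vertices;
`mean_radius`, `max_radius` and `max_min_radii_ratio` are distances from
hull vertices to the hull polygon centroid; `span_ratio` is the square
root of the ratio of principal second moments of the filled hull.

**Perimeter.** The outer boundary is traced with Moore-neighbor tracing
(Jacob's stopping criterion). The default perimeter applies the
Vossepoel–Smeulders chain-code calibration (0.980·n_even + 1.406·n_odd −
0.091·n_corners), accurate to a few per mil on smooth digital shapes; the
raw 1/√2 chain length overestimates an isotropic boundary by ≈5.5%,
which would bias circularity of a disc to ≈0.90 instead of ≈1. The raw
chain (`"chain"`) and Crofton (`"crofton"`) estimators remain available;
the transformation index TI = P²/(4πA) uses the same estimator so
TI·circularity ≡ 1 holds exactly.

**Fractal dimension.** Box counting on the foreground bounding box with a
dyadic size ladder (2…half the box side), grid anchored at the bounding
box corner; the dimension is the least-squares slope of log N vs
log(1/s). Averaging over shifted grid anchors is available
(`n_offsets`) but off by default: shifted grids systematically inflate
boundary-box counts on objects only a few boxes wide (a 64-px filled
square drops from D = 2.00 to ≈1.86 under offset averaging). For
oracle fractals built on base-3 grids, a (1, 3, 9, 27) ladder recovers
the Sierpinski-carpet dimension log8/log3 exactly.

**Lacunarity.** Gliding-box Λ(r) = (σ/μ)² of foreground mass, unit step,
over the foreground bounding box (so empty canvas margins do not inflate
the variance); the reported value is the mean over the size ladder. No +1
is added: an all-foreground region has Λ = 0.

**Phagocytic efficiency.** Bead-ingestion bins (1, 2, 3, 4, 5, >5 beads)
are weighted 1…6 per cell and normalized by the total cell count
(×100%). The weight vector is configurable since conventions differ on
crediting the open-ended bin.

## Morphology statistics

Features are z-scored before PCA and k-means — the 25 features span μm,
μm² and dimensionless ratios, and unscaled Euclidean distance would be
dominated by areas. Per-feature screening is the two-tailed unpaired
Student's t-test at α = 0.05 (the study's convention); constant features
report p = 1 with a warning.

**Elbow rule.** The within-cluster MSE (inertia/n) is computed for
k = 1…12 with 10 restarts. The literal "largest drop" rule,
argmax MSE(k−1)−MSE(k), is degenerate on convex curves (always k = 2), so
the default `knee` rule takes the largest second difference of **log**
MSE over 2 ≤ k ≤ k_max−1 — the last k after which the relative
improvement collapses. The raw-MSE second difference inherits the k = 2
bias whenever cluster separations are hierarchical: on four
well-separated blobs it picks k = 4 in only ~70% of runs, the log form in
~100%. Both rules are reported. A selection whose drop explains less
than half the total MSE decrease is flagged low-confidence; a single
smooth cluster yields exactly such a geometric-looking curve.

**Classifier.** Gradient boosted trees (xgboost, logistic loss) tuned by
nested stratified cross-validation (5 outer, 5 inner folds) over
n_estimators, learning rate, max depth and the per-tree column-subsample
fraction; the grid includes the configuration selected on the study's
real data (100 estimators, depth 2, rate 0.1, 1/5 of columns). Inner-loop
ties break toward fewer estimators, then shallower trees. Importance is
the total loss-reduction (gain) summed over splits per feature, averaged
over the outer-fold models and normalized to sum to 1.

## Transcriptomics

Counts are normalized to reads per million; testing operates on
log2(RPM + 1). The default test moderates per-gene pooled variances by
empirical Bayes: s² ~ s₀²·F(d, d₀) with (d₀, s₀²) estimated by moment
matching on log s² (polygamma inversion), posterior
s²ₚ = (d₀s₀² + d·s²)/(d₀ + d), and d₀ + d degrees of freedom. Moderation
is the default rather than an option because with 3–4 replicates per
group an unmoderated t-test (df ≈ 6) essentially cannot reach
BH-corrected significance at genome scale — in the planted-signal
simulation below it recovers ~15 of 101 planted genes versus ~95 with
moderation — and because moderated linear models are what the original
analysis software family uses. A plain Welch test remains available
(`method="welch"`).

Fold changes follow the signed linear convention (|FC| ≥ 1, sign =
direction), under which the filter threshold |FC| > 1 excludes only
exactly-equal means; it is exposed as configuration because some
toolchains intend a larger linear cutoff. FDR is Benjamini–Hochberg
across all tested genes; genes with zero counts everywhere are emitted
flagged but untested.

**Overlap statistics.** The 2×2 contingency of two gene lists over a
stated universe (default 23,930 — the 20,767 RefSeq plus 3,163 XM/XR
genes of the targeted panel) is tested with the exact two-sided Fisher
test (minimum-likelihood convention, verified against brute-force
hypergeometric enumeration for all margins ≤ 12). The odds-ratio CI is
the Baptista–Pike exact interval: the set of noncentral-hypergeometric
odds ψ whose two-sided minimum-likelihood p exceeds α, found by bisection
in log ψ; zero cells yield one-sided intervals with a 0 or ∞ bound, and
the point estimate falls back to the Haldane-corrected ratio (flagged).
Gene symbols compare case-insensitively after whitespace stripping.
Direction concordance counts shared genes with equal direction labels.

**qPCR.** ΔCT = CT(target) − CT(housekeeping) per sample; ΔΔCT subtracts
the reference-group mean ΔCT, so the reference group is centered at unit
fold change (geometric mean 1).

## Synthetic data: what it emulates, and what it does not

The mask generator grows a soma disc (pixel-center rasterization, area
within ~1% of πr²) and persistent-heading random-walk branches (0.8-px
steps, Gaussian heading jitter, optional one-level secondary branching,
dilation to the process width). The ramified preset (6 primary branches,
60±10 px, thickness 1) and activated preset (2 branches, 15±5 px,
thickness 3, larger soma) reproduce the direction of every reported
morphological effect: activated cells show higher density and
circularity, lower total branch length, hull area and span. The
generator emits clean binary masks only — it does not model staining
artifacts, intensity, PSF blur, touching cells or 3D stacks, so passing
tests demonstrate correctness of the measurement chain, not robustness
to segmentation noise.

The feature-table generator samples two 25-dimensional Gaussians with a
shared covariance (default: independent features with SD = 25% of the
baseline mean) and applies shifts in SD units to chosen features, signed
so that density and circularity increase in the disease group and the
other significant features decrease. It deliberately ignores the strong
inter-feature correlations of real morphometry; it exists to give the
statistics stage exactly calibrated effect sizes.

The count generator is gamma–Poisson: per-gene baseline means are
log-normal with median 100 and natural-log SD 2.0 — an implied library
of ≈15 million reads over 20,000 genes, consistent with a high-output
targeted bulk run, with a realistically wide expression range — and
dispersion φ = 0.05 (variance μ + φμ²), a typical bulk value; planted
genes have the case mean multiplied or divided by 2^log2_effect. At the
study scale (83 up + 18 down planted at |log2FC| = 2, 4 vs 4) the
default pipeline recovers a median of ≈95–97 of the 101 planted genes
with ≈4 false discoveries; low-expression planted genes (bottom decile
of the log-normal) account for most misses. Real libraries add GC and
length biases, sample-level batch effects and correlated genes, none of
which are simulated.

The overlap generator plants an exact shared-gene count and concordance
split, so the worked examples with 27 shared / 17 concordant are exact by
construction.

## Problem sizes and determinism

Every generator and every stochastic stage is a pure function of its
spec and seed. The shipped validation uses the study's own scales where
they are known (310 + 389 cells; 20,000 genes, 4 vs 4; universe 23,930)
and modest replicate counts chosen for desk-scale runs (100 seeds for
cluster-count recovery, 20 for DEG recovery, 200 tables for CI coverage);
`scripts/acceptance.py` derives all of these seeds from a single
`--seed`.

## Known limitations

- 2D only; Z-projected masks are assumed upstream.
- The skeleton branch walker is greedy (orthogonal-first); exotic
  thinning artifacts could in principle split a branch, though none occur
  in the synthetic populations or oracles.
- FracLac-style grid options (multiple offsets, rotated grids) are only
  partially mirrored; defaults are documented above and configurable.
- The empirical-Bayes moderation assumes a single scaled-F variance
  ensemble; no mean-variance trend is fitted.
- The study's real-data quantities that depend on its unavailable raw
  images and libraries (per-feature p-values, PCA fractions, ~70%
  classifier accuracy) are not reproduced here; only their procedures
  are, validated on synthetic ground truth.
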