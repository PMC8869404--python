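"""Canonical per-cell morphometric feature names and study-design constants.

The morphometric profile of a single microglial cell is summarized by 25
features: 10 derived from the skeleton of the binary mask (ramification)
and 15 derived from the mask itself, its convex hull, and its multi-scale
texture (complexity and cell shape).  All length-type features are in μm,
area-type features in μm²; the remaining features are dimensionless.
"""

from __future__ import annotations

#: Skeleton (ramification) features, in canonical column order.
SKELETON_FEATURES: tuple[str, ...] = (
    "n_branches",
    "n_junction_voxels",
    "n_endpoint_voxels",
    "n_slab_voxels",
    "avg_branch_length",
    "max_branch_length",
    "total_branch_length",
    "euclidean_distance",
    "n_triple_points",
    "n_quadruple_points",
)

#: Shape / complexity features, in canonical column order.
SHAPE_FEATURES: tuple[str, ...] = (
    "fractal_dimension",
    "lacunarity",
    "density",
    "span_ratio",
    "convex_hull_area",
    "convex_hull_perimeter",
    "convex_hull_circularity",
    "bounding_circle_diameter",
    "mean_radius",
    "max_span_across_hull",
    "max_min_radii_ratio",
    "max_radius",
    "cell_area",
    "cell_perimeter",
    "cell_circularity",
)

#: All 25 features in canonical column order (skeleton first).
ALL_FEATURES: tuple[str, ...] = SKELETON_FEATURES + SHAPE_FEATURES

#: Skeleton features significantly lower in cervical-spinal-cord microglia
#: of the disease model (4 features).
SIGNIFICANT_SKELETON_FEATURES: tuple[str, ...] = (
    "n_slab_voxels",
    "max_branch_length",
    "total_branch_length",
    "euclidean_distance",
)

#: Shape features significantly different in the same comparison
#: (10 features; density and cell_circularity increase, the rest decrease).
SIGNIFICANT_SHAPE_FEATURES: tuple[str, ...] = (
    "lacunarity",
    "convex_hull_area",
    "convex_hull_perimeter",
    "bounding_circle_diameter",
    "mean_radius",
    "max_span_across_hull",
    "cell_area",
    "cell_perimeter",
    "density",
    "cell_circularity",
)

#: The 14 features carried into the clustering / classification stage.
SIGNIFICANT_FEATURES: tuple[str, ...] = (
    SIGNIFICANT_SKELETON_FEATURES + SIGNIFICANT_SHAPE_FEATURES
)

#: Features whose group effect is an *increase* in the disease group; every
#: other significant feature decreases (de-ramification / compaction).
INCREASED_IN_DISEASE: tuple[str, ...] = ("density", "cell_circularity")

#: Number of single microglial cells analyzed per region and genotype
#: (cervical spinal cord, deep cerebellar nuclei, pontine nuclei).
CELL_COUNTS: dict[tuple[str, str], int] = {
    ("CSC", "WT"): 310,
    ("CSC", "MJD"): 389,
    ("DCN", "WT"): 349,
    ("DCN", "MJD"): 445,
    ("PN", "WT"): 152,
    ("PN", "MJD"): 180,
}

#: Confocal pixel calibration, μm per pixel (40x objective, 1024 px field).
DEFAULT_CALIBRATION_UM_PER_PX: float = 0.31

#: Imaged field side length, μm.
FIELD_SIZE_UM: float = 624.39

#: Gene universe of the targeted sequencing panel: 20,767 well-annotated
#: RefSeq genes plus 3,163 XM/XR predicted models.
DEFAULT_GENE_UNIVERSE: int = 20767 + 3163
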