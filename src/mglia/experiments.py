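"""Study-scale simulation experiments.

These run the full pipeline on synthetic data generated at the scale of
the original study: 310 + 389 spinal-cord cells with 3-SD shifts on the 14
disease-altered features for the clustering arm, and 20,000 genes with
83 up- + 18 down-regulated planted DEGs (|log2FC| = 2, dispersion 0.05,
4 vs 4 samples) for the transcriptomic arm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import SIGNIFICANT_FEATURES
from .morpho_stats import elbow_select_k
from .synthetic import (
    MorphoPopulationSpec,
    disease_effects,
    planted_spec_at_study_scale,
    simulate_count_matrix,
    simulate_morphology_table,
)
from .transcriptomics import differential_expression, filter_degs, rpm_normalize


def elbow_cluster_recovery(
    seeds, effect_sd: float = 3.0, rule: str = "knee", n_restarts: int = 10
) -> list[int]:
    """Chosen cluster count per seed on the two-phenotype feature table.

    Each run generates 310 + 389 cells, restricts to the 14 significant
    features, standardizes, and picks k over 1..12.
    """
    chosen = []
    for seed in seeds:
        table, _ = simulate_morphology_table(
            MorphoPopulationSpec(effects=disease_effects(effect_sd), seed=int(seed))
        )
        x = table[list(SIGNIFICANT_FEATURES)].to_numpy(float)
        curve = elbow_select_k(x, k_max=12, rule=rule, n_restarts=n_restarts, seed=int(seed))
        chosen.append(curve.chosen_k)
    return chosen


def deg_filter_recovery(seeds) -> pd.DataFrame:
    """Filter-passing DEG counts per seed at the study-scale simulation.

    Returns one row per seed with the up-, down-regulated and total counts
    passing |FC| > 1, p < 0.05 and FDR < 0.1.
    """
    rows = []
    for seed in seeds:
        spec = planted_spec_at_study_scale(int(seed))
        counts, groups, _ = simulate_count_matrix(spec)
        rpm = rpm_normalize(counts)
        table = differential_expression(rpm, groups)
        up, down = filter_degs(table)
        rows.append({"seed": int(seed), "up": len(up), "down": len(down), "total": len(up) + len(down)})
    return pd.DataFrame(rows)


def modal_value(values) -> int:
    """The most frequent value (smallest wins ties)."""
    values = list(values)
    return int(min(sorted(set(values)), key=lambda v: (-values.count(v), v)))


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2³¹) from one master seed."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=n)
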