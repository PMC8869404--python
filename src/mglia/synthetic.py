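"""Synthetic data generators for every pipeline stage.

The study's raw data (masks, per-cell feature tables, counts) are not
deposited, so each downstream stage is exercised on generated data with a
known ground truth:

* :func:`simulate_cell_mask` grows a single microglia-like binary mask from
  a soma disc by a persistent-heading random-walk branch model, spanning
  the ramified (surveillant) to de-ramified/compact (activated) morphology
  axis.
* :func:`simulate_morphology_table` samples per-cell 25-feature vectors
  from two multivariate-normal populations with chosen effect sizes — a
  fast surrogate for mask-level generation used by the statistics stage.
* :func:`simulate_count_matrix` draws gamma–Poisson (negative binomial)
  gene counts with planted up-/down-regulated genes.
* :func:`simulate_overlap_gene_sets` builds two direction-annotated gene
  lists with an exact planted overlap and concordance structure.

Every generator is a pure function of its spec (including the seed): same
spec, same output, bit for bit.  Each generated record carries exactly one
ground-truth label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.morphology import dilation as _dilation, disk as _disk_se

from .features import (
    ALL_FEATURES,
    DEFAULT_GENE_UNIVERSE,
    INCREASED_IN_DISEASE,
    SIGNIFICANT_FEATURES,
)
from .gene_sets import GeneSet
from .mask import CellMask


class CanvasTooSmallError(ValueError):
    """Raised when the canvas cannot hold the soma plus maximal branch extent."""


# ---------------------------------------------------------------------------
# mask-level generator


@dataclass(frozen=True)
class CellPhenotypeParams:
    """Parameters of the random-walk cell-growth model.

    Branches leave the soma rim at evenly spaced headings (plus jitter) and
    take unit-ish pixel steps whose heading diffuses with standard
    deviation ``tortuosity_sd_deg`` per step; with probability
    ``secondary_branch_prob`` a branch sprouts one shorter side branch.
    ``process_thickness_px`` dilates the traced paths to the process width.
    """

    soma_radius_px: float = 8.0
    n_primary_branches: int = 5
    branch_length_mean_px: float = 45.0
    branch_length_sd_px: float = 10.0
    secondary_branch_prob: float = 0.5
    tortuosity_sd_deg: float = 12.0
    process_thickness_px: int = 1
    seed: int = 0
    label: str = "cell"

    def __post_init__(self) -> None:
        if self.soma_radius_px <= 0:
            raise ValueError("soma_radius_px must be positive")
        if self.n_primary_branches < 0:
            raise ValueError("n_primary_branches must be non-negative")
        if self.branch_length_mean_px <= 0 or self.branch_length_sd_px <= 0:
            raise ValueError("branch lengths must be positive")
        if not 0 <= self.secondary_branch_prob <= 1:
            raise ValueError("secondary_branch_prob must be a probability")
        if self.tortuosity_sd_deg < 0:
            raise ValueError("tortuosity_sd_deg must be non-negative")
        if self.process_thickness_px < 1:
            raise ValueError("process_thickness_px must be a positive integer")

    def max_extent_px(self) -> float:
        """Upper bound on the radial reach of the cell from its center.

        Branch lengths are clipped at mean + 4 SD; a secondary branch
        (half the primary length, sprouting at the midpoint) cannot reach
        beyond the primary tip, so the primary length bounds the extent.
        """
        lmax = self.branch_length_mean_px + 4.0 * self.branch_length_sd_px
        return self.soma_radius_px + lmax + self.process_thickness_px + 2


def ramified_preset(seed: int = 0) -> CellPhenotypeParams:
    """A surveillant-like cell: many long thin processes."""
    return CellPhenotypeParams(
        soma_radius_px=8,
        n_primary_branches=6,
        branch_length_mean_px=60,
        branch_length_sd_px=10,
        secondary_branch_prob=0.6,
        tortuosity_sd_deg=12,
        process_thickness_px=1,
        seed=seed,
        label="ramified",
    )


def activated_preset(seed: int = 0) -> CellPhenotypeParams:
    """A de-ramified/compact cell: few short thick processes, larger soma."""
    return CellPhenotypeParams(
        soma_radius_px=12,
        n_primary_branches=2,
        branch_length_mean_px=15,
        branch_length_sd_px=5,
        secondary_branch_prob=0.2,
        tortuosity_sd_deg=20,
        process_thickness_px=3,
        seed=seed,
        label="activated",
    )


def _walk(rng, start, heading, n_steps, jitter_rad, canvas_shape):
    """Persistent-heading pixel walk; returns visited integer pixels."""
    pos = np.array(start, dtype=float)
    pixels = []
    h = heading
    for _ in range(n_steps):
        h += rng.normal(0.0, jitter_rad)
        pos = pos + 0.8 * np.array([np.cos(h), np.sin(h)])
        r = int(np.floor(pos[0] + 0.5))
        c = int(np.floor(pos[1] + 0.5))
        if not (0 <= r < canvas_shape[0] and 0 <= c < canvas_shape[1]):
            break
        pixels.append((r, c))
    return pixels, pos, h


def simulate_cell_mask(
    params: CellPhenotypeParams, canvas: tuple[int, int] = (256, 256)
) -> tuple[CellMask, dict]:
    """Grow one cell mask on the canvas; returns (mask, truth record).

    Raises
    ------
    CanvasTooSmallError
        If the soma plus maximal branch extent does not fit with a margin
        at least one process width wide (the message names the required
        canvas side).
    """
    need = params.max_extent_px() + params.process_thickness_px
    side = int(np.ceil(2 * need)) + 1
    if min(canvas) < side:
        raise CanvasTooSmallError(
            f"canvas {canvas} too small: phenotype needs a margin of "
            f"{need:.0f} px around the center, i.e. at least {side}×{side}"
        )
    rng = np.random.default_rng(params.seed)
    center = (canvas[0] // 2, canvas[1] // 2)
    # soma disc over pixel centers: d² ≤ r² keeps the area within ~1% of πr²
    rr, cc = np.ogrid[: canvas[0], : canvas[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= params.soma_radius_px**2

    jitter = np.deg2rad(params.tortuosity_sd_deg)
    paths: list[tuple[int, int]] = []
    n = params.n_primary_branches
    for i in range(n):
        heading = 2 * np.pi * i / n + rng.normal(0.0, np.pi / max(6, 2 * n))
        length = float(
            np.clip(
                rng.normal(params.branch_length_mean_px, params.branch_length_sd_px),
                3.0,
                params.branch_length_mean_px + 4.0 * params.branch_length_sd_px,
            )
        )
        # start just inside the soma rim so the process stays attached
        start = (
            center[0] + (params.soma_radius_px - 1.0) * np.cos(heading),
            center[1] + (params.soma_radius_px - 1.0) * np.sin(heading),
        )
        n_steps = int(round(length / 0.8))
        px, end_pos, end_heading = _walk(rng, start, heading, n_steps, jitter, canvas)
        paths.extend(px)
        if rng.random() < params.secondary_branch_prob and len(px) > 4:
            k = len(px) // 2
            branch_pt = px[k]
            side_heading = end_heading + rng.choice([-1.0, 1.0]) * rng.uniform(
                np.deg2rad(30), np.deg2rad(60)
            )
            sec_len = max(2.0, 0.5 * length)
            sec_px, _, _ = _walk(
                rng, branch_pt, side_heading, int(round(sec_len / 0.8)), jitter, canvas
            )
            paths.extend(sec_px)
    if paths:
        proc = np.zeros(canvas, dtype=bool)
        rows, cols = zip(*paths)
        proc[list(rows), list(cols)] = True
        if params.process_thickness_px > 1:
            proc = _dilation(proc, _disk_se((params.process_thickness_px - 1) // 2))
        mask |= proc
    truth = {"label": params.label, "params": params}
    return CellMask(mask), truth


# ---------------------------------------------------------------------------
# feature-table generator

#: Baseline feature means of a ramified (wild-type-like) population, in the
#: units of the feature table (μm / μm² / dimensionless).
DEFAULT_FEATURE_MEANS: dict[str, float] = {
    "n_branches": 14.0,
    "n_junction_voxels": 20.0,
    "n_endpoint_voxels": 12.0,
    "n_slab_voxels": 260.0,
    "avg_branch_length": 6.0,
    "max_branch_length": 18.0,
    "total_branch_length": 80.0,
    "euclidean_distance": 14.0,
    "n_triple_points": 5.0,
    "n_quadruple_points": 1.2,
    "fractal_dimension": 1.45,
    "lacunarity": 0.45,
    "density": 0.35,
    "span_ratio": 1.6,
    "convex_hull_area": 900.0,
    "convex_hull_perimeter": 115.0,
    "convex_hull_circularity": 0.85,
    "bounding_circle_diameter": 42.0,
    "mean_radius": 16.0,
    "max_span_across_hull": 40.0,
    "max_min_radii_ratio": 2.2,
    "max_radius": 22.0,
    "cell_area": 160.0,
    "cell_perimeter": 210.0,
    "cell_circularity": 0.05,
}

#: Baseline feature standard deviations (≈25% of the mean).
DEFAULT_FEATURE_SDS: dict[str, float] = {
    k: 0.25 * abs(v) for k, v in DEFAULT_FEATURE_MEANS.items()
}


@dataclass(frozen=True)
class MorphoPopulationSpec:
    """Two-group multivariate-normal feature-population specification.

    ``effects`` maps feature names to shifts (in pooled-SD units) applied
    to group 2; positive values shift in the feature's disease direction
    (increase for density and cell circularity, decrease otherwise).
    """

    n_per_group: tuple[int, int] = (310, 389)
    group_names: tuple[str, str] = ("WT", "MJD")
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FEATURE_MEANS))
    covariance: np.ndarray | None = None
    effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 2:
            raise ValueError("exactly two groups are supported")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError(f"need n ≥ 2 per group, got {self.n_per_group}")
        unknown = set(self.means) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names in means: {sorted(unknown)}")
        unknown = set(self.effects) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown feature names in effects: {sorted(unknown)}")
        cov = self.covariance
        if cov is None:
            sds = np.array([DEFAULT_FEATURE_SDS[f] for f in ALL_FEATURES])
            cov = np.diag(sds**2)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (len(ALL_FEATURES), len(ALL_FEATURES)):
            raise ValueError(f"covariance must be {len(ALL_FEATURES)}-dimensional")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-8 * max(1.0, np.abs(cov).max()):
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "covariance", cov)


def disease_effects(magnitude_sd: float) -> dict[str, float]:
    """Uniform |effect| on the 14 disease-altered features, signed per feature."""
    return {f: magnitude_sd for f in SIGNIFICANT_FEATURES}


def simulate_morphology_table(spec: MorphoPopulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample the two-group feature table; returns (table, truth).

    The table has the 25 canonical feature columns plus ``genotype``; the
    truth frame echoes the genotype label and, per feature, whether and how
    far it was shifted.
    """
    rng = np.random.default_rng(spec.seed)
    mean_vec = np.array([spec.means.get(f, DEFAULT_FEATURE_MEANS[f]) for f in ALL_FEATURES])
    sds = np.sqrt(np.diag(spec.covariance))
    shift = np.zeros(len(ALL_FEATURES))
    for feat, eff in spec.effects.items():
        i = ALL_FEATURES.index(feat)
        sign = +1.0 if feat in INCREASED_IN_DISEASE else -1.0
        shift[i] = sign * eff * sds[i]
    frames = []
    for gname, n, mu in (
        (spec.group_names[0], spec.n_per_group[0], mean_vec),
        (spec.group_names[1], spec.n_per_group[1], mean_vec + shift),
    ):
        x = rng.multivariate_normal(mu, spec.covariance, size=n, method="cholesky" if _is_pd(spec.covariance) else "eigh")
        df = pd.DataFrame(x, columns=list(ALL_FEATURES))
        df.insert(0, "genotype", gname)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "feature": list(ALL_FEATURES),
            "shift_sd": [spec.effects.get(f, 0.0) for f in ALL_FEATURES],
            "shifted": [f in spec.effects for f in ALL_FEATURES],
        }
    )
    return table, truth


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


# ---------------------------------------------------------------------------
# count-matrix generator


@dataclass(frozen=True)
class CountSimSpec:
    """Negative-binomial bulk count simulation with planted signal.

    Baseline per-gene means are log-normal with natural-log mean
    ``baseline_log_mean`` and spread ``baseline_log_sd``; the defaults give
    a median count of 100 and an implied library of roughly 15 million
    reads over 20,000 genes, matching a high-throughput targeted bulk run.
    Planted genes have the case-group mean multiplied (up) or divided
    (down) by ``2**log2_effect``.  ``nb_dispersion`` is the gamma–Poisson
    dispersion φ (variance μ + φμ²).
    """

    n_genes: int = 20000
    n_per_group: tuple[int, int] = (4, 4)
    group_names: tuple[str, str] = ("WT", "MJD")
    planted_up: frozenset[int] = frozenset()
    planted_down: frozenset[int] = frozenset()
    log2_effect: float = 2.0
    nb_dispersion: float = 0.05
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_up", frozenset(self.planted_up))
        object.__setattr__(self, "planted_down", frozenset(self.planted_down))
        if any(n < 2 for n in self.n_per_group):
            raise ValueError(f"need ≥2 samples per group, got {self.n_per_group}")
        if self.planted_up & self.planted_down:
            raise ValueError("planted_up and planted_down must be disjoint")
        all_planted = self.planted_up | self.planted_down
        if all_planted and (min(all_planted) < 0 or max(all_planted) >= self.n_genes):
            raise ValueError("planted gene indices out of range")
        if self.log2_effect < 0:
            raise ValueError("log2_effect must be non-negative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")


def planted_spec_at_study_scale(seed: int = 0) -> CountSimSpec:
    """The study-scale simulation: 20,000 genes, 4 vs 4, 83 up + 18 down planted."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(20000, size=101, replace=False)
    return CountSimSpec(
        planted_up=frozenset(int(i) for i in idx[:83]),
        planted_down=frozenset(int(i) for i in idx[83:]),
        seed=seed,
    )


def simulate_count_matrix(spec: CountSimSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the counts; returns (counts, groups, truth).

    ``counts`` is genes × samples (integer), ``groups`` maps sample id to
    group label, ``truth`` records per-gene DEG status and direction.
    """
    rng = np.random.default_rng(spec.seed)
    mu = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    factor = np.ones(spec.n_genes)
    up = np.array(sorted(spec.planted_up), dtype=int)
    down = np.array(sorted(spec.planted_down), dtype=int)
    if up.size:
        factor[up] = 2.0**spec.log2_effect
    if down.size:
        factor[down] = 2.0**-spec.log2_effect

    def draw(mean_vec: np.ndarray, n: int) -> np.ndarray:
        lam = mean_vec[:, None]
        if spec.nb_dispersion > 0:
            lam = rng.gamma(
                1.0 / spec.nb_dispersion,
                mean_vec[:, None] * spec.nb_dispersion,
                size=(spec.n_genes, n),
            )
        else:
            lam = np.broadcast_to(lam, (spec.n_genes, n))
        return rng.poisson(lam)

    ctrl = draw(mu, spec.n_per_group[0])
    case = draw(mu * factor, spec.n_per_group[1])
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]
    samples = [f"{spec.group_names[0]}_{i+1}" for i in range(spec.n_per_group[0])] + [
        f"{spec.group_names[1]}_{i+1}" for i in range(spec.n_per_group[1])
    ]
    counts = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=samples)
    groups = pd.Series(
        [spec.group_names[0]] * spec.n_per_group[0] + [spec.group_names[1]] * spec.n_per_group[1],
        index=samples,
        name="group",
    ).to_frame()
    status = np.array(["null"] * spec.n_genes, dtype=object)
    status[up] = "up"
    status[down] = "down"
    truth = pd.DataFrame({"gene": genes, "status": status})
    return counts, groups, truth


# ---------------------------------------------------------------------------
# overlap gene-set generator


def simulate_overlap_gene_sets(
    universe_size: int = DEFAULT_GENE_UNIVERSE,
    list_sizes: tuple[int, int] = (101, 1000),
    planted_overlap: int = 27,
    planted_concordant: int = 17,
    seed: int = 0,
) -> tuple[GeneSet, GeneSet, pd.DataFrame]:
    """Two direction-annotated gene sets with exact planted overlap structure.

    Exactly ``planted_overlap`` symbols are shared and exactly
    ``planted_concordant`` of those carry the same direction label in both
    sets.  Returns (set A, set B, truth frame).
    """
    if not (0 <= planted_concordant <= planted_overlap):
        raise ValueError("need 0 ≤ planted_concordant ≤ planted_overlap")
    if planted_overlap > min(list_sizes):
        raise ValueError(
            f"planted_overlap {planted_overlap} exceeds smallest list size {min(list_sizes)}"
        )
    if sum(list_sizes) - planted_overlap > universe_size:
        raise ValueError("universe too small for the requested lists")
    rng = np.random.default_rng(seed)
    symbols = [f"Gene{i:05d}" for i in range(universe_size)]
    order = rng.permutation(universe_size)
    shared = [symbols[i] for i in order[:planted_overlap]]
    only_a = [
        symbols[i] for i in order[planted_overlap : list_sizes[0]]
    ]
    only_b = [
        symbols[i]
        for i in order[list_sizes[0] : list_sizes[0] + list_sizes[1] - planted_overlap]
    ]

    def rand_dirs(n):
        return ["up" if u < 0.5 else "down" for u in rng.random(n)]

    dirs_a = dict(zip(shared, rand_dirs(planted_overlap)))
    dirs_b = {}
    for j, g in enumerate(shared):
        if j < planted_concordant:
            dirs_b[g] = dirs_a[g]
        else:
            dirs_b[g] = "down" if dirs_a[g] == "up" else "up"
    dirs_a.update(dict(zip(only_a, rand_dirs(len(only_a)))))
    dirs_b.update(dict(zip(only_b, rand_dirs(len(only_b)))))
    set_a = GeneSet("sim_A", tuple(shared + only_a), dirs_a)
    set_b = GeneSet("sim_B", tuple(shared + only_b), dirs_b)
    truth = pd.DataFrame(
        {
            "gene": shared,
            "concordant": [j < planted_concordant for j in range(planted_overlap)],
        }
    )
    return set_a, set_b, truth
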