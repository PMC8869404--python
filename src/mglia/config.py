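"""Pipeline configuration and run manifests.

The configuration is a flat, human-readable YAML document with an explicit
``seed``; it round-trips losslessly through :meth:`PipelineConfig.to_yaml`
and :meth:`PipelineConfig.from_yaml`.  A :class:`RunManifest` records the
configuration echo, package version, and SHA-256 checksums of per-stage
outputs so deterministic stages can be verified bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .features import DEFAULT_CALIBRATION_UM_PER_PX, DEFAULT_GENE_UNIVERSE


@dataclass
class PipelineConfig:
    seed: int = 0
    calibration_um_per_px: float = DEFAULT_CALIBRATION_UM_PER_PX
    # morphology simulation
    n_cells_per_group: tuple[int, int] = (310, 389)
    effect_sd: float = 3.0
    # feature screening / clustering / classification
    alpha: float = 0.05
    elbow_rule: str = "knee"
    k_max: int = 12
    kmeans_restarts: int = 10
    cv_outer: int = 5
    cv_inner: int = 5
    # differential expression
    de_method: str = "moderated"
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.1
    universe_size: int = DEFAULT_GENE_UNIVERSE
    excluded_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.p_threshold < 1 or not 0 < self.fdr_threshold <= 1:
            raise ValueError("p/FDR thresholds must be in (0, 1]")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold below 1 is meaningless for signed linear FC")
        if self.elbow_rule not in ("knee", "largest_drop"):
            raise ValueError(f"unknown elbow rule {self.elbow_rule!r}")
        if self.k_max < 3:
            raise ValueError("k_max must be ≥ 3")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = dataclasses.asdict(self)
        doc["n_cells_per_group"] = list(self.n_cells_per_group)
        doc["excluded_samples"] = list(self.excluded_samples)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text) or {}
        if "n_cells_per_group" in doc:
            doc["n_cells_per_group"] = tuple(doc["n_cells_per_group"])
        if "excluded_samples" in doc:
            doc["excluded_samples"] = tuple(doc["excluded_samples"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path → sha256
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, path: str | Path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
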