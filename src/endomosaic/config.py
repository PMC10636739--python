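"""Run configuration: every tunable threshold in one place.

Defaults are loaded from the dataclasses below; a YAML file can override
any subset.  Unknown keys are rejected with the offending key named, so
typos in config files fail loudly instead of silently running with
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "default_config"]

VALID_SOURCES = ("feature", "flow", "direct")
VALID_FUSION_MODES = (
    "graph",
    "average",
    "single:feature",
    "single:flow",
    "single:direct",
)


@dataclass
class FeatureConfig:
    """SIFT-style keypoint detection and matching."""

    c_dog: float = 0.007          # DoG contrast threshold (low: endoscopy is low-contrast)
    c_edge: float = 10.0
    max_ratio: float = 0.75       # Lowe ratio test
    cross_check: bool = True      # mutual-nearest filter


@dataclass
class FlowConfig:
    """Dense optical-flow backend and sampling of the field."""

    backend: str = "ilk"          # "ilk" | "tvl1" | "precomputed"
    radius: int = 7               # ilk window radius, px
    precomputed_dir: str = ""     # directory of .flo files for the adapter
    stride: int = 8               # flow-field subsampling before RANSAC
    border_margin: int = 4        # px excluded at the image border


@dataclass
class EstimationConfig:
    """RANSAC affine estimation."""

    eps: float = 2.0              # inlier reprojection threshold, px
    max_iters: int = 1000
    min_inliers: int = 10
    sample_size: int = 4          # 4-point hypotheses for the affine model


@dataclass
class DirectConfig:
    """Pyramidal direct photometric registration."""

    pyramid_levels: int = 3
    tol: float = 1e-6             # relative loss-change stop criterion
    max_iters: int = 50           # L-M iterations per pyramid level
    min_valid_fraction: float = 0.25


@dataclass
class UncertaintyConfig:
    """Failure classification feeding the zero-information rule."""

    min_inliers: int = 10
    max_residual: float = 0.01    # mean-squared intensity on the [0, 1] scale
    identity_tol: float = 1e-9


@dataclass
class LoopClosureConfig:
    enabled: bool = True
    dist_thresh: float = 0.0      # px; 0 -> half the image width at runtime
    time_thresh: int = 30         # frames
    sim_thresh: float = 0.75      # cosine similarity on tf-idf BoW vectors
    min_gap: int = 20             # frames; excludes trivial neighbours
    vocab_size: int = 256         # k-means visual words


@dataclass
class GraphConfig:
    """Levenberg-Marquardt pose-graph optimiser."""

    lambda0: float = 1e-4
    tol: float = 1e-9             # relative cost-change stop criterion
    max_iters: int = 100
    jacobian_step: float = 1e-6
    bridge_information: float = 1e-6  # identity bridge when all sources fail


@dataclass
class PanoramaConfig:
    interpolation: str = "bilinear"  # or "nearest" for bit-exact tests


@dataclass
class EvaluationConfig:
    d_max: int = 5
    min_overlap_frac: float = 0.2


@dataclass
class RunConfig:
    sources: list = field(default_factory=lambda: list(VALID_SOURCES))
    fusion_mode: str = "graph"
    seed: int = 0
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    direct: DirectConfig = field(default_factory=DirectConfig)
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    loop_closure: LoopClosureConfig = field(default_factory=LoopClosureConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    panorama: PanoramaConfig = field(default_factory=PanoramaConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self):
        if not self.sources:
            raise ValueError("at least one source must be enabled")
        for s in self.sources:
            if s not in VALID_SOURCES:
                raise ValueError(f"unknown source {s!r}; valid: {VALID_SOURCES}")
        if self.fusion_mode not in VALID_FUSION_MODES:
            raise ValueError(
                f"unknown fusion mode {self.fusion_mode!r}; valid: {VALID_FUSION_MODES}"
            )


def _update_dataclass(obj, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            raise ValueError(f"unknown config key '{path}{key}'")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ValueError(f"config section {path}{key!r} must be a mapping")
            _update_dataclass(current, value, f"{path}{key}.")
        else:
            setattr(obj, key, value)
    return obj


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and overrides."""
    cfg = RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping at the top level")
        _update_dataclass(cfg, data, "")
    if overrides:
        _update_dataclass(cfg, overrides, "")
    cfg.__post_init__()
    return cfg
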