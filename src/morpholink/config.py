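"""Configuration, shared constants, logging, and error types.

Every printed threshold of the analysis lives here as a named default so a
run is fully determined by one serializable config object.
"""
from __future__ import annotations

import logging
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger("morpholink")
if not logger.handlers:  # stderr by default; pipeline adds a per-run file handler
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ConfigurationError(ValueError):
    """Invalid configuration or invalid input for an operation."""


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


# ---------------------------------------------------------------------------
# Column conventions for cell-level feature tables
# ---------------------------------------------------------------------------

#: Metadata columns of a cell table; every other column is a morphology feature.
METADATA_COLUMNS = (
    "field",
    "well",
    "plate",
    "line",
    "day",
    "population",
    "cytoplasm_area",
    "nucleus_area",
    "nucleus_intensity",
    "er_intensity",
    "mito_intensity",
    "cgan_intensity",
)

#: Required identifying metadata when reading a table from disk.
REQUIRED_METADATA = ("field", "well", "plate", "line", "day")

#: Image-quality channels carrying a PowerLogLogSlope value per field.
QC_CHANNELS = ("nucleus", "er", "mito", "cgan")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QCParams(_Strict):
    """Quality-control thresholds (defaults are the analysis' printed values)."""

    blur_threshold: float = -2.16        # mean PowerLogLogSlope must be strictly greater
    cytoplasm_area_min: float = 1000.0   # inclusive removal bounds
    cytoplasm_area_max: float = 100000.0
    nucleus_area_min: float = 10000.0
    min_nucleus_intensity: float = 0.003
    kde_bandwidth: float = 1.0
    min_density: float = 0.0001
    intensity_statistic: str = "mean"    # which statistic the 0.003 cut applies to


class RegularizeParams(_Strict):
    scale_max: float = 1000.0            # features scaled to [0, scale_max]
    logit_eps: float = 1e-6


class SubsampleParams(_Strict):
    max_per_population: int = 2000
    target_min: int = 50000
    target_max: int = 60000
    seed: int = 0


class SelectParams(_Strict):
    r_threshold: float = 0.99
    exclusion_patterns: list[str] = Field(
        default_factory=lambda: ["_X", "_Y", "Zernike", "AngleBtNghbors_Adjacent"]
    )


class ClusterParams(_Strict):
    n_neighbors: int = 20
    resolution: float = 1.0
    seed: int = 0
    #: clusters removed after inspection (never inferred automatically)
    excluded_clusters: list[int] = Field(default_factory=list)


class ModuleParams(_Strict):
    k_min: int = 2
    k_max: int = 40
    metric: str = "covariance"           # or "correlation"
    k_override: Optional[int] = None     # force a module count (study data used 18)


class CrossmodalParams(_Strict):
    alpha: float = 0.02
    max_iter: int = 10000
    tol: float = 1e-4
    n_metacells: int = 3
    standardize: bool = False
    seed: int = 0


class AnnotateParams(_Strict):
    cellcycle_alpha: float = 0.02
    marker_sd_threshold: float = 2.5
    transfer_max_dist: float = 400.0
    marker_score: str = "smd"            # standardized mean difference; or "auc"


class SyntheticParams(_Strict):
    """Mirrors :class:`morpholink.synthetic.SyntheticConfig` for file configs."""

    n_lines_per_day: dict[int, int] = Field(default_factory=lambda: {20: 6, 40: 4, 70: 4})
    cells_per_population: int = 200
    n_genes: int = 2000
    n_features: int = 300
    n_programs: int = 10
    link_density: float = 0.005
    noise_sd: float = 0.1
    n_redundant_pairs: int = 10
    n_module_blocks: int = 3
    blur_fields: int = 0
    tiny: int = 0
    huge: int = 0
    dim_nucleus: int = 0
    density_outliers: int = 0
    seed: int = 0


class PipelineConfig(_Strict):
    """Full pipeline configuration; unknown keys are rejected on load."""

    run_dir: str = "morpholink_run"
    #: either simulate paired data, or point at real inputs
    simulate: Optional[SyntheticParams] = None
    feature_table: Optional[str] = None
    expression_dir: Optional[str] = None
    cellcycle_scores: Optional[str] = None
    stages: list[str] = Field(
        default_factory=lambda: [
            "simulate", "qc", "regularize", "subsample", "select_features",
            "cluster_modules", "metacells", "lasso", "predict", "annotate",
        ]
    )
    qc: QCParams = Field(default_factory=QCParams)
    regularize: RegularizeParams = Field(default_factory=RegularizeParams)
    subsample: SubsampleParams = Field(default_factory=SubsampleParams)
    select: SelectParams = Field(default_factory=SelectParams)
    cluster: ClusterParams = Field(default_factory=ClusterParams)
    modules: ModuleParams = Field(default_factory=ModuleParams)
    crossmodal: CrossmodalParams = Field(default_factory=CrossmodalParams)
    annotate: AnnotateParams = Field(default_factory=AnnotateParams)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
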