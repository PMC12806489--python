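"""Pipeline configuration.

One flat dataclass carries every tunable of the per-site analysis chain plus
the model hyperparameters of the robustness and driver stages, so that a
single object (or YAML file) pins down a full run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Default FLUXNET2015 column names for each semantic field.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "timestamp": "TIMESTAMP_START",
    "er": "RECO_NT_VUT_REF",
    "er_qc": "RECO_NT_VUT_REF_QC",
    "sm": "SWC_F_MDS_1",
    "gpp": "GPP_NT_VUT_REF",
    "isr": "SW_IN_F",
    "tair": "TA_F",
    "vpd": "VPD_F",
}


@dataclass
class PipelineConfig:
    """Parameters of the response-curve pipeline and downstream analyses.

    Attributes
    ----------
    bin_width : float
        Soil-moisture bin width in volumetric %, anchored at 0.
    quantile : float
        Within-bin ER quantile defining the boundary line.
    window : int
        Running-average window (odd number of bins).
    min_bin_n : int
        Minimum records per bin; sparser bins are dropped before smoothing
        (the upper quantile of one or two records is too noisy to anchor
        the boundary line).
    outlier_k : float
        Outlier screen half-width in standard deviations (mean +/- k*SD).
    alpha : float
        Significance level for the two-sided segment-trend tests.
    gs_threshold_frac : float
        Growing-season threshold as a fraction of the p5-p95 dynamic range
        of smoothed daily GPP.
    gs_smooth_days : int
        Moving-mean window (days) applied to daily GPP before thresholding.
    gam_df : int
        Target B-spline basis dimension of the response-curve smooth
        (reduced automatically when there are few points).
    n_trees : int
        Trees in the random forest of the SHAP robustness check.
    n_boot : int
        Bootstrap replicates for ridge-coefficient confidence intervals.
    seed : int
        Seed feeding every stochastic step (forest bagging, bootstrap).
    """

    bin_width: float = 0.05
    quantile: float = 0.90
    window: int = 3
    min_bin_n: int = 5
    outlier_k: float = 2.0
    alpha: float = 0.05
    gs_threshold_frac: float = 0.10
    gs_smooth_days: int = 15
    gam_df: int = 10
    n_trees: int = 500
    n_boot: int = 1000
    seed: int = 0
    column_map: dict = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ConfigurationError(f"quantile must be in (0,1), got {self.quantile}")
        if self.bin_width <= 0:
            raise ConfigurationError(f"bin_width must be positive, got {self.bin_width}")
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError(f"window must be a positive odd integer, got {self.window}")
        if not 0 < self.gs_threshold_frac < 1:
            raise ConfigurationError(
                f"gs_threshold_frac must be in (0,1), got {self.gs_threshold_frac}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" (line {mark.line + 1})" if mark is not None else ""
            raise ConfigurationError(f"malformed YAML in {path}{line}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
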