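"""Pipeline configuration: every fixed constant in one validated record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .health import F_RURAL, F_URBAN, RURAL_DENSITY_MAX


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end hazard/exposure/health pipeline.

    Defaults follow the study design the package implements: six
    binarization thresholds, 80/20 stratified splits, p < 0.05 univariate
    retention, VIF ≤ 10, 1000 screening repeats and ensemble runs, a
    10-group Hosmer–Lemeshow gate at α = 0.05, a 0.001 cutoff grid, and
    rural/urban groundwater-usage fractions of 0.48/0.29.
    """

    thresholds: tuple[float, ...] = (10.0, 5.0, 4.0, 3.0, 2.0, 1.0)
    map_thresholds: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 10.0)
    train_fraction: float = 0.8
    n_repeats: int = 1000
    n_runs: int = 1000
    base_seed: int = 0
    p_cutoff: float = 0.05
    vif_cutoff: float = 10.0
    vif_variant: str = "linear"
    hl_groups: int = 10
    hl_alpha: float = 0.05
    cutoff_grid_step: float = 0.001
    fixed_cutoff: float | None = None  # e.g. 0.50 for the fixed-cutoff map
    stepwise_start: str = "full"
    f_rural: float = F_RURAL
    f_urban: float = F_URBAN
    density_threshold: float = RURAL_DENSITY_MAX
    band_concs: dict | None = None
    dr_params: dict | None = None  # cancer → sex → {q1,q2,k,m}
    # synthetic-study block
    nrows: int = 64
    ncols: int = 64
    cell_size: float = 7.0  # km; 64×64 cells ≈ a 200,000 km² state
    n_continuous: int = 10
    n_categorical: int = 2
    smoothing_radius: int = 3
    n_wells: int = 2000
    total_population: float = 70_445_000.0
    active_variables: tuple[str, ...] = ("cont_00", "cont_01", "cont_02")
    true_coefficients: tuple[float, ...] = (1.0, -0.8, 0.6)

    def __post_init__(self) -> None:
        ts = tuple(float(t) for t in self.thresholds)
        if any(t <= 0 for t in ts):
            raise ValueError("thresholds must be positive")
        if any(a <= b for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly decreasing")
        self.thresholds = ts
        self.map_thresholds = tuple(float(t) for t in self.map_thresholds)
        if self.n_repeats < 1 or self.n_runs < 1:
            raise ValueError("n_repeats and n_runs must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, for replayable run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
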