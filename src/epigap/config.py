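"""Pipeline configuration: YAML in, validated and fully defaulted out.

Unknown keys are rejected (typo safety), cross-field constraints are
enforced at load time (friction must be positive, the outer margin should
clear several screening lengths, a fixed time step must be CFL-feasible
for the requested grid), and every run can emit a frozen copy of the
resolved configuration whose hash stamps all derived artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ShapeConfig(_Strict):
    family: Literal["circle", "moon", "lobed", "polygon"] = "circle"
    radius_um: float = Field(30.0, gt=0)
    h_um: float = 0.0  # moon: signed semi-minor axis
    lobe_amplitude_um: float = 0.0
    lobe_count: int = 4
    vertices_um: Optional[list[list[float]]] = None
    resolution_um: float = Field(0.5, gt=0)


class ImageConfig(_Strict):
    shape_px: list[int] = [256, 256]
    pixel_size_um: float = Field(0.5, gt=0)
    mean_intensity: float = 100.0
    sigma_tissue: float = Field(20.0, ge=0)
    sigma_gap: float = Field(2.0, ge=0)
    sigma_noise: float = Field(1.0, ge=0)

    @model_validator(mode="after")
    def _contrast(self):
        if self.sigma_gap > self.sigma_tissue:
            raise ValueError("sigma_gap must not exceed sigma_tissue")
        return self


class ModelConfig(_Strict):
    eta: float = Field(1.0, gt=0)
    c_f: float = 0.08
    f_l: float = Field(0.0, ge=0)
    gamma: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _friction(self):
        if self.c_f <= 0:
            raise ValueError(
                "c_f = 0 leaves a floating-body null space (rigid translations "
                "and rotation) under pure-traction boundaries; set c_f > 0"
            )
        return self

    @property
    def screening_length_um(self) -> float:
        return float(np.sqrt(2 * self.eta / self.c_f))


class ScheduleConfig(_Strict):
    t_end_min: float = Field(1e4, gt=0)
    dt_min: Optional[float] = Field(None, gt=0)
    cfl_safety: float = Field(0.5, gt=0, le=1.0)
    store_every: int = Field(1, ge=1)
    area_min_um2: Optional[float] = Field(None, gt=0)
    max_steps: int = Field(5000, ge=1)


class GridConfig(_Strict):
    grid_um: float = Field(0.5, gt=0)
    outer_margin_lengths: float = Field(8.0, gt=0)
    outer: Literal["rect", "circle"] = "rect"


class AnalysisConfig(_Strict):
    n_points: int = Field(8, ge=1)
    arc_spacing_um: float = Field(15.0, gt=0)
    fit_form: Literal["log", "linear"] = "log"


class SegmentationConfig(_Strict):
    window: int = 9
    threshold: Optional[float] = None
    closing_radius_px: int = 2
    min_object_px: int = 50
    pixel_size_um: float = Field(0.5, gt=0)

    @model_validator(mode="after")
    def _odd(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("segmentation window must be odd and >= 3")
        return self


class PipelineConfig(_Strict):
    format_version: int = 1
    seed: int = 0
    out_dir: str = "epigap_out"
    shape: ShapeConfig = ShapeConfig()
    image: ImageConfig = ImageConfig()
    model: ModelConfig = ModelConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    grid: GridConfig = GridConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    warnings: list[str] = []

    def hash(self) -> str:
        payload = self.model_dump(exclude={"warnings"})
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def freeze(self, path) -> None:
        data = self.model_dump(exclude={"warnings"})
        data["config_hash"] = self.hash()
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def validate_config(path) -> PipelineConfig:
    """Load, default-fill and cross-validate a YAML pipeline config."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(**raw)
    warnings = []
    ell = cfg.model.screening_length_um
    if cfg.grid.outer_margin_lengths < 5:
        warnings.append(
            f"outer margin {cfg.grid.outer_margin_lengths} screening lengths "
            "< 5: the far boundary may influence the edge speed"
        )
    if cfg.grid.grid_um > ell / 4:
        warnings.append(
            f"grid spacing {cfg.grid.grid_um} um is coarse relative to the "
            f"screening length {ell:.2f} um; expect reduced accuracy"
        )
    if cfg.schedule.dt_min is not None:
        # crude CFL feasibility: edge speeds of order traction * l / (2 eta)
        kappa_scale = 1.0 / max(cfg.shape.radius_um, 1e-6)
        v_scale = (cfg.model.f_l + cfg.model.gamma * kappa_scale) * ell / (2 * cfg.model.eta)
        if v_scale > 0 and cfg.schedule.dt_min * v_scale > cfg.grid.grid_um:
            raise ValueError(
                f"schedule infeasible: dt = {cfg.schedule.dt_min} min exceeds the "
                f"CFL scale {cfg.grid.grid_um / v_scale:.3g} min for these forces"
            )
    cfg.warnings = warnings
    return cfg


def substream_seed(global_seed: int, name: str) -> int:
    """Deterministic named substream of the global seed (< 2^31)."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % 2**31)
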