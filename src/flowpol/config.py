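"""Validated run configuration.

A run config names the inputs, the flow direction for the field of view,
and the per-module parameter blocks.  Unknown keys are rejected so typos
fail before any computation; the resolved config is written beside every
run's outputs.

Flow direction is required experimental metadata: the upstream/downstream
identity of a cell end cannot be inferred from morphology without silently
breaking the flow-reversal symmetry guarantees, so it is never guessed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationBlock(_Strict):
    sigma: float = 2.0
    min_cell_area_px: int = 50


class ClustersBlock(_Strict):
    tophat_radius: int = 5
    min_area: int = 4
    pla_size_band: tuple[int, int] = (4, 200)


class CalciumBlock(_Strict):
    threshold_iod: float = 2.0
    detrend: str = "none"
    frame_interval_s: float = 3.0
    peak_prominence_mads: float = 5.0
    peak_min_separation_s: float = 9.0


class SyntheticBlock(_Strict):
    n_cells: int = 60
    fov: tuple[int, int] = (300, 400)
    aspect_ratio_mean: float = 4.0
    aspect_ratio_sd: float = 0.8
    polarization_fold: float = 3.0
    n_frames: int = 200
    active_fraction: float = 0.5


class ChannelMap(_Strict):
    junction: int = 0
    nucleus: int = 1
    stain: int = 2
    puncta: int = 3


class RunConfig(_Strict):
    image: str | None = None          # multi-channel scene TIFF
    movie: str | None = None          # (T, Y, X) GCaMP TIFF
    label_mask: str | None = None     # pre-computed label TIFF (optional)
    channels: ChannelMap = Field(default_factory=ChannelMap)
    flow_direction: tuple[float, float] = (1.0, 0.0)
    pixel_size_um: float = 1.0
    segmentation: SegmentationBlock = Field(default_factory=SegmentationBlock)
    clusters: ClustersBlock = Field(default_factory=ClustersBlock)
    calcium: CalciumBlock = Field(default_factory=CalciumBlock)
    synthetic: SyntheticBlock = Field(default_factory=SyntheticBlock)
    background: float | None = None   # None = median of background pixels
    out_dir: str = "flowpol_run"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("flow_direction")
    @classmethod
    def _nonzero_flow(cls, v: tuple[float, float]) -> tuple[float, float]:
        if v[0] == 0 and v[1] == 0:
            raise ValueError("flow_direction must be non-zero")
        return v


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))
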