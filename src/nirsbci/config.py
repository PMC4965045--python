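"""Validated run/experiment configuration (YAML or JSON).

Defaults mirror the deployed system's constants: 12 selected channels, a
7.69 Hz sampling rate, six task / seven rest blocks, a 20-level
thermometer and 25 mm optode separation.  Unknown keys are rejected and
every stochastic stage has an explicit seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .preprocess import PreprocConfig
from .synth import HemoParams


class ConfigError(ValueError):
    """Invalid or unreadable configuration."""


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_task_blocks: int = 6
    task_dur_s: float = Field(default=20.0, gt=0)
    rest_dur_s: float = Field(default=20.0, gt=0)

    @field_validator("n_task_blocks")
    @classmethod
    def _even(cls, v: int) -> int:
        if v < 0 or v % 2 != 0:
            raise ValueError("n_task_blocks must be even for left/right balance")
        return v


class LayoutConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    grid_rows: int = Field(default=4, ge=1)
    grid_cols: int = Field(default=4, ge=1)
    n_grids: int = 2
    spacing_mm: float = Field(default=25.0, gt=0)

    @field_validator("n_grids")
    @classmethod
    def _grids(cls, v: int) -> int:
        if v not in (1, 2):
            raise ValueError("n_grids must be 1 or 2")
        return v


class HemoConfig(BaseModel):
    """Mirrors HemoParams; validated here, materialized via to_params()."""

    model_config = ConfigDict(extra="forbid")

    fs: float = Field(default=7.69, gt=0)
    peak_delay_s: float = Field(default=2.1, gt=0)
    undershoot_delay_s: float = Field(default=5.0, gt=0)
    undershoot_ratio: float = 0.6
    sustained_gain: float = Field(default=0.16, ge=0, le=1)
    habituation_tau_s: float = Field(default=0.5, gt=0)
    hbo_amp_um: float = 0.5
    mi_gain: float = Field(default=0.6, gt=0, le=1)
    hbr_ratio: float = 0.35
    hbr_lag_s: float = 1.0
    contra_gain: float = 1.0
    ipsi_gain: float = Field(default=0.3, ge=0)
    noise_sd_um: float = Field(default=0.45, ge=0)
    mayer_amp_um: float = 0.15
    mayer_freq_hz: float = 0.1
    resp_amp_um: float = 0.1
    resp_freq_hz: float = 0.3
    cardiac_amp_um: float = 0.05
    cardiac_freq_hz: float = 1.1
    drift_slope_um_per_s: float = 0.002
    active_channel_fraction: float = Field(default=0.25, gt=0, le=1)

    def to_params(self) -> HemoParams:
        return HemoParams(**self.model_dump())


class PreprocSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    baseline_window: str = "preceding_rest"
    precolor_len_s: float = Field(default=30.0, gt=0)
    wavelet: str = "db4"
    depth: int | None = Field(default=None, ge=1)
    mdl: bool = True
    precolor_online: bool = False

    def to_config(self) -> PreprocConfig:
        return PreprocConfig(
            baseline_window=self.baseline_window,
            precolor_len_s=self.precolor_len_s,
            wavelet=self.wavelet,
            depth=self.depth,
            mdl=self.mdl,
        )


class SelectorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_select: int = 12

    @field_validator("n_select")
    @classmethod
    def _even(cls, v: int) -> int:
        if v < 0 or v % 2 != 0:
            raise ValueError("n_select must be even so both hemispheres contribute equally")
        return v


class SvmConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c_param: float = Field(default=1.0, gt=0)
    block_level_folds: bool = False


class SessionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    thermometer_levels: int = 20
    feedback: bool = True

    @field_validator("thermometer_levels")
    @classmethod
    def _levels(cls, v: int) -> int:
        if v < 2 or v % 2 != 0:
            raise ValueError("thermometer_levels must be an even count >= 2")
        return v


class RunConfig(BaseModel):
    """Top-level configuration for every pipeline stage."""

    model_config = ConfigDict(extra="forbid")

    protocol: ProtocolConfig = ProtocolConfig()
    layout: LayoutConfig = LayoutConfig()
    hemo: HemoConfig = HemoConfig()
    preproc: PreprocSection = PreprocSection()
    selector: SelectorConfig = SelectorConfig()
    svm: SvmConfig = SvmConfig()
    session: SessionConfig = SessionConfig()
    seed: int = 0


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML/JSON configuration; None gives full defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(text) if text.strip() else {}
        else:
            raw = yaml.safe_load(text) or {}
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"config {path} is not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping at the top level")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        keys = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration in {path}: {keys}") from exc
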