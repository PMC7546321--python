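"""Declarative pipeline configuration.

A single nested mapping (YAML on disk) holds every numeric setting of
the analysis; stage code receives values from here and hard-codes
nothing.  Unknown keys are rejected by name so typos cannot silently
fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PreprocessConfig:
    k_drop: int = 10
    fwhm_mm: float = 4.0
    band: tuple[float, float] = (0.01, 0.08)
    fd_threshold: float = 0.2
    fd_sphere_radius_mm: float = 50.0
    max_trans_mm: float = 2.0
    max_rot_deg: float = 2.0
    rotation_unit: str = "radians"
    scrub_floor: int = 30
    erode_wm: bool = True


@dataclass
class GFCConfig:
    mode: str = "mean_z"
    include_self: bool = False
    block_size: int = 512
    gm_threshold: float = 0.2


@dataclass
class InferenceConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 26


@dataclass
class ClassifyConfig:
    log2_c_min: int = -5
    log2_c_max: int = 15
    log2_gamma_min: int = -15
    log2_gamma_max: int = 3
    grid_step: int = 2
    nested: bool = False
    roc_direction: str = "lower"


@dataclass
class SimulateConfig:
    """Mirrors CohortSpec; values here are handed to the generator."""

    n_patients: int = 20
    n_controls: int = 23
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    n_volumes: int = 250
    tr: float = 2.0
    global_coupling_control: float = 1.0
    global_coupling_patient_effect: float = 0.4
    regional_coupling: float = 0.4
    coupling_jitter_sd: float = 0.25
    noise_sd: float = 1.0
    duration_slope: float = 15.0
    duration_noise_sd: float = 5.0
    spike_rate: float = 0.05


@dataclass
class PipelineConfig:
    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 0
    tr_fallback: float | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gfc: GFCConfig = field(default_factory=GFCConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "gfc": GFCConfig,
    "inference": InferenceConfig,
    "classify": ClassifyConfig,
    "simulate": SimulateConfig,
}


def _build(cls: type, values: dict[str, Any], path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(values) - set(known)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under '{path}'"
        )
    coerced = {}
    for name, value in values.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[name] = value
    return cls(**coerced)


def load_config(source: str | Path | dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file, a dict, or defaults."""
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    top_known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)
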