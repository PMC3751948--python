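"""Pipeline configuration: one structured file drives all stages."""

from __future__ import annotations

import copy
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .chromophore import ChromophoreModel
from .generator import GeneratorParams
from .radiometry import SUN_ANGULAR_RADIUS_DEG, ExposureConfig


def _default_dict(obj) -> dict:
    return asdict(obj)


@dataclass
class PipelineConfig:
    """Everything the radiometry, simulation and analysis stages need.

    ``solar_csv`` and ``tau_csv`` of ``None`` select the bundled tables.
    ``plate_peak_mw_cm2`` is the exposure-device normalization used by
    the ``transmittance-only`` solar mode: the brightest band is driven
    at this irradiance and the others scale with the filtered solar
    spectrum.
    """

    seed: int = 1
    grid_start_nm: float = 380.0
    grid_stop_nm: float = 700.0
    grid_step_nm: float = 1.0

    solar_csv: str | None = None
    tau_csv: str | None = None
    solar_mode: str = "transmittance-only"
    sun_angular_radius_deg: float = SUN_ANGULAR_RADIUS_DEG
    plate_peak_mw_cm2: float = 1.0

    pupil_diameter_mm: float = 5.0
    eye_length_mm: float = 17.0

    exposure: dict = field(default_factory=lambda: _default_dict(ExposureConfig()))

    band_first_nm: float = 390.0
    band_last_nm: float = 520.0
    band_step_nm: float = 10.0
    band_extra_nm: list = field(default_factory=lambda: [630.0])
    band_width_nm: float = 10.0
    band_shape: str = "rectangular"

    a2e_levels_uM: list = field(default_factory=lambda: [0.0, 12.5, 20.0, 40.0])
    wells_per_condition: int = 4
    replicates: int = 5

    generator: dict = field(default_factory=lambda: _default_dict(GeneratorParams()))
    chromophore: dict = field(default_factory=lambda: _default_dict(ChromophoreModel()))

    alpha: float = 0.05
    alpha_gate: float = 0.05

    # -- constructed objects ------------------------------------------

    def exposure_config(self) -> ExposureConfig:
        return ExposureConfig(**self.exposure)

    def generator_params(self) -> GeneratorParams:
        return GeneratorParams(**self.generator)

    def chromophore_model(self) -> ChromophoreModel:
        return ChromophoreModel(**self.chromophore)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        base = cls()
        data = base.to_dict()
        for key, value in (overrides or {}).items():
            if key not in data:
                raise KeyError(f"unknown configuration key {key!r}")
            if isinstance(data[key], dict) and isinstance(value, dict):
                merged = copy.deepcopy(data[key])
                unknown = set(value) - set(merged)
                if unknown:
                    raise KeyError(f"unknown keys under {key!r}: {sorted(unknown)}")
                merged.update(value)
                data[key] = merged
            else:
                data[key] = value
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(overrides)
        for key in ("solar_csv", "tau_csv"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{key}: {value} does not exist")
        return cfg

    def sha(self) -> str:
        """Short digest of the canonical configuration, for output headers."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
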