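"""Simulation and pipeline configuration objects (YAML-serialisable)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class OscillationConfig:
    """Metaphase oscillation of the pair centre along the plate normal.

    A sawtooth (triangle-wave) excursion of ``amplitude`` nm with direction
    reversals every ``half_period`` s, sampled every ``sample_interval`` s —
    the characteristic quasi-periodic poleward / away-from-the-pole motion.
    """

    amplitude: float = 300.0
    half_period: float = 35.0
    sample_interval: float = 7.5
    n_frames: int = 40
    position_noise_sd: float = 0.0  # white positional noise per frame, nm

    def validate(self):
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.half_period <= 0:
            raise ValueError("half_period must be positive")
        if self.amplitude < 0 or self.position_noise_sd < 0:
            raise ValueError("amplitude and noise sd must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class SimulationConfig:
    """Generative truth for an ensemble of sister kinetochore pairs.

    Lengths in nm, angles in degrees.  Defaults follow the measured
    metaphase ensemble in untreated human cells: 98 nm inner-to-outer
    distance, ~950 nm median sister separation, y-swivel dispersion 56.4 deg.
    """

    n_pairs: int = 1000
    delta_magnitude: float = 98.0
    delta_dispersion: float = 0.0
    swivel_model: str = "gaussian_y"  # or "isotropic"
    swivel_sd: float = 56.4
    z_swivel_sd: float | None = None  # defaults to swivel_sd
    inter_sister_median: float = 950.0
    inter_sister_sd: float = 150.0
    twist_sd: float = 20.0
    plate_halfwidth_y: float = 5000.0
    plate_halfwidth_z: float = 5000.0
    plate_thickness_sd: float = 550.0
    chromatic_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    localization_noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    oscillation: OscillationConfig | None = None
    seed: int = 0

    def validate(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.swivel_model not in ("gaussian_y", "isotropic"):
            raise ValueError(f"unknown swivel_model {self.swivel_model!r}")
        nonneg = {
            "delta_magnitude": self.delta_magnitude,
            "delta_dispersion": self.delta_dispersion,
            "swivel_sd": self.swivel_sd,
            "inter_sister_median": self.inter_sister_median,
            "inter_sister_sd": self.inter_sister_sd,
            "twist_sd": self.twist_sd,
            "plate_halfwidth_y": self.plate_halfwidth_y,
            "plate_halfwidth_z": self.plate_halfwidth_z,
            "plate_thickness_sd": self.plate_thickness_sd,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(s < 0 for s in self.localization_noise_sd):
            raise ValueError("localization noise sds must be non-negative")
        if self.z_swivel_sd is not None and self.z_swivel_sd < 0:
            raise ValueError("z_swivel_sd must be non-negative")
        if self.oscillation is not None:
            self.oscillation.validate()

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        osc = d.get("oscillation")
        if isinstance(osc, dict):
            d["oscillation"] = OscillationConfig(**osc)
        for key in ("chromatic_shift", "localization_noise_sd"):
            if key in d and d[key] is not None:
                d[key] = tuple(float(v) for v in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
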