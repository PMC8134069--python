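"""Run configuration: YAML-backed, fully serializable, seeds explicit."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import celsius_to_kelvin

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings for a pipeline run.

    Every stage draws its randomness from ``seed``; no stage reads entropy
    from the environment.  ``temperature_c`` is the experimental bath
    temperature (18-30 degC range in practice).
    """

    seed: int = 0
    temperature_c: float = 25.0
    units: dict = field(default_factory=lambda: {
        "displacement": "um", "stiffness": "uN/m", "force": "pN",
        "gating_force": "fN"})
    gating: dict = field(default_factory=lambda: {
        "n_populations": 2, "n_restarts": 20, "k_steady": "fit",
        "symmetric_dips": False})
    frap: dict = field(default_factory=lambda: {
        "n_restarts": 10, "bootstrap": 1000})
    fluctuation: dict = field(default_factory=lambda: {
        "band": [100.0, 1000.0], "segment_s": 1.0,
        "stiffness_for_equipartition": "K_steady"})
    statistics: dict = field(default_factory=lambda: {
        "test": "student", "design": "unpaired", "correction": "none"})

    @property
    def temperature_k(self) -> float:
        return celsius_to_kelvin(self.temperature_c)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key '{key}'")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def to_dict(self) -> dict:
        return asdict(self)
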