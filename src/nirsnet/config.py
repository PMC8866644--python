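"""Declarative pipeline configuration with documented defaults.

Every threshold the pipeline uses lives here: the 0.01-0.2 Hz band, the
per-wavelength DPFs (7.25 / 6.38 at 760 / 850 nm), the extinction table id,
HRF parameters, the 128-s DCT drift cutoff, the hotspot alpha ladder
(alpha0 = 0.05 relaxed in 0.001 steps), the strong-edge threshold z = 1.0,
the sparsity grid (0.01 ... 1.00 in 0.01 steps) and the per-point network
alpha 0.1. The sampling rate is a parameter (default 7.8125 Hz), never
hard-coded downstream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .glm import HrfParams
from .mbll import DEFAULT_DPF, DEFAULT_EXTINCTION_TABLE


def default_sparsity_grid() -> list[float]:
    return [round(0.01 * k, 2) for k in range(1, 101)]


@dataclass
class PipelineConfig:
    sampling_rate: float = 7.8125
    low_hz: float = 0.01
    high_hz: float = 0.2
    dpf: tuple[float, float] = DEFAULT_DPF
    extinction_table: str = DEFAULT_EXTINCTION_TABLE
    hrf: HrfParams = field(default_factory=HrfParams)
    dct_cutoff_s: float = 128.0
    hotspot_alpha0: float = 0.05
    hotspot_step: float = 0.001
    strong_z: float = 1.0
    sparsity_grid: list[float] = field(default_factory=default_sparsity_grid)
    network_alpha: float = 0.1
    artifact_removal: bool = True
    spike_z: float = 5.0
    jump_z: float = 5.0
    artifact_window_s: float = 2.0
    correlation_window: str = "full"
    edge_ranking_signed: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.low_hz < self.high_hz < self.sampling_rate / 2:
            raise ConfigError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) < "
                f"Nyquist ({self.sampling_rate / 2})")
        if not 0 < self.hotspot_alpha0 < 1:
            raise ConfigError("hotspot alpha0 must be in (0, 1)")
        if self.hotspot_step <= 0:
            raise ConfigError("hotspot step must be > 0")
        grid = np.asarray(self.sparsity_grid, dtype=float)
        if grid.size == 0:
            raise ConfigError("sparsity grid must not be empty")
        if np.any(grid < 0) or np.any(grid > 1) or np.any(np.diff(grid) <= 0):
            raise ConfigError("sparsity grid must be strictly increasing within [0, 1]")
        if any(d <= 0 for d in self.dpf):
            raise ConfigError("DPF must be > 0")
        if self.correlation_window not in ("full", "task_blocks"):
            raise ConfigError(f"unknown correlation window {self.correlation_window!r}")
        if not 0 <= self.network_alpha <= 1:
            raise ConfigError("network alpha must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dpf"] = list(self.dpf)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "hrf" in data and isinstance(data["hrf"], dict):
            data = dict(data)
            data["hrf"] = HrfParams(**data["hrf"])
        if "dpf" in data:
            data = dict(data)
            data["dpf"] = tuple(data["dpf"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
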