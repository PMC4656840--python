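"""Run configuration: analysis parameters, seeds, and paths.

A single flat config object covers all analyzers; unknown keys are rejected
so typos fail fast.  Values mirror the analysis defaults: the spectral peak
thresholds (0.008 / 0.003), stimulus windows, Monte Carlo replicate counts,
ROI radius and background sample count, and bootstrap size.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # spike analysis
    peak_threshold: float = 0.008
    index_threshold: float = 0.003
    lag_window_s: float = 2.0
    acg_bin_s: float = 0.1
    pulse_onset_s: float = 5.0
    pulse_duration_s: float = 1.0
    inter_pulse_interval_s: float = 19.0
    n_sweeps: int = 30
    # spatial analysis
    n_sim_entropy: int = 50_000
    n_sim_median: int = 10_000
    # count model
    bootstrap_B: int = 1000
    # GAD scoring
    roi_radius_px: int = 20
    n_background: int = 1000
    # VEP
    n_perm: int = 10_000
    vep_stim_onset_s: float = 0.1
    vep_stim_duration_s: float = 0.3
    vep_sampling_rate_hz: float = 20_000.0
    # run control
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        positive = (
            "peak_threshold", "index_threshold", "lag_window_s", "acg_bin_s",
            "pulse_duration_s", "n_sim_entropy", "n_sim_median", "bootstrap_B",
            "roi_radius_px", "n_background", "n_perm", "n_sweeps",
            "vep_stim_duration_s", "vep_sampling_rate_hz",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config parameter {name} must be positive")
        if self.pulse_onset_s < 0 or self.vep_stim_onset_s < 0:
            raise ValueError("stimulus onsets must be non-negative")
        if self.log_level not in {"DEBUG", "INFO", "WARN", "ERROR"}:
            raise ValueError(f"unknown log level {self.log_level!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)
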