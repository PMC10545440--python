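"""Pipeline configuration: every task constant has a named key with the
standard gradCPT value as default, loadable from a YAML file."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Config:
    run_duration: float = 400.0
    soa_auditory: float = 1.6
    soa_visual: float = 0.8
    nogo_rate: float = 0.1
    n_runs: int = 4
    window_open_frac: float = 0.7   # of the appearance phase
    window_close_frac: float = 0.4  # of the disappearance phase
    fwhm: float = 7.0               # VTC smoothing kernel, seconds
    band_low: float = 0.005         # fluctuation-frequency search band, Hz
    band_high: float = 0.10
    tr: float = 2.0                 # scan repetition time, seconds
    discard_volumes: int = 5
    n_volumes: int = 205
    hrf_dt: float = 0.1
    highpass_cutoff: float = 128.0
    bayes_kappa: float = 1.0
    bayes_cauchy_scale: float = 0.7071067811865476
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.window_open_frac < 1 and 0 < self.window_close_frac < 1):
            raise ValueError("window fractions must be in (0, 1)")
        for name in ("run_duration", "soa_auditory", "soa_visual", "fwhm", "tr", "hrf_dt",
                     "highpass_cutoff", "bayes_kappa", "bayes_cauchy_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_scans(self) -> int:
        return self.n_volumes - self.discard_volumes

    @property
    def t0(self) -> float:
        return self.discard_volumes * self.tr

    def soa(self, modality: str) -> float:
        if modality == "auditory":
            return self.soa_auditory
        if modality == "visual":
            return self.soa_visual
        raise ValueError(f"unknown modality {modality!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config; unknown keys are rejected, missing ones default."""
    if path is None:
        return Config()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = set(Config.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
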