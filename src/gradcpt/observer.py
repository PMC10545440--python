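"""Synthetic gradCPT observer with sinusoidally fluctuating attention.

The generative model is deliberately simple: a deterministic latent
attentional state ``s(t) = sin(2*pi*f0*t + phase)`` modulates, trial by
trial, (i) the SD of the reaction-time noise and (ii) the miss and
commission probabilities.  Trial-to-trial RT variability therefore carries a
narrowband amplitude envelope at ``f0``, which is exactly the structure the
variance-time-course (VTC) analysis is designed to detect: the magnitude of
z-scored RTs rises and falls with the latent state, so the VTC spectrum
peaks at ``f0``.

Sessions generated here exercise every downstream stage (press assignment,
outcome classification, d-prime, VTC, frequency estimation, regressors)
without any recorded data.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .schedule import StimulusSchedule

#: RT floor, seconds; prevents non-physiological near-zero or negative RTs.
RT_FLOOR = 0.05


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the fluctuating-attention observer.

    mu_rt        mean Go reaction time, seconds
    sigma0       baseline RT noise SD, seconds
    mod_depth    fractional modulation of the noise SD by the latent state,
                 in [0, 1); 0 disables the fluctuation entirely
    f0           attentional fluctuation frequency, Hz
    phase        phase of the latent sinusoid, radians
    p_fa_base    baseline commission probability on No-go trials
    fa_slope     coupling of the latent state into the commission rate
    p_miss_base  baseline miss probability on Go trials
    miss_slope   coupling of the latent state into the miss rate
    """

    mu_rt: float = 0.625
    sigma0: float = 0.08
    mod_depth: float = 0.0
    f0: float = 0.032
    phase: float = 0.0
    p_fa_base: float = 0.188
    fa_slope: float = 0.0
    p_miss_base: float = 0.036
    miss_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 0 <= self.mod_depth < 1:
            raise ValueError("mod_depth must be in [0, 1)")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        for name in ("p_fa_base", "p_miss_base"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class KeypressLog:
    """Sorted keypress times (seconds from run start) for one run."""

    press_times: np.ndarray
    run_duration: float

    def __post_init__(self):
        t = np.asarray(self.press_times, float)
        if len(t) and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ValueError("press_times must be sorted and non-negative")


def auditory_observer(**overrides) -> ObserverParams:
    """Observer parameterized for the auditory task (SOA 1.6 s): slower
    responses, more misses."""
    defaults = dict(mu_rt=1.558, sigma0=0.14, p_miss_base=0.259, p_fa_base=0.238)
    defaults.update(overrides)
    return ObserverParams(**defaults)


def simulate_observer(schedule: StimulusSchedule, params: ObserverParams) -> KeypressLog:
    """Generate a keypress log for one run.

    On each Go trial the observer presses at
    ``onset + max(RT_FLOOR, mu_rt + Normal(0, sigma_n^2))`` unless it
    misses; on each No-go trial it presses (a commission error) with the
    state-dependent probability, under the same RT law.  The per-trial noise
    SD is ``sigma0 * (1 + mod_depth * s(t_n))``.  Misses and correct
    rejections emit no press.  Identical parameters (including seed) yield
    identical logs.
    """
    rng = np.random.default_rng(params.seed)
    t = schedule.onsets
    s = np.sin(2 * np.pi * params.f0 * t + params.phase)
    sigma_n = params.sigma0 * (1 + params.mod_depth * s)

    p_miss = np.clip(params.p_miss_base + params.miss_slope * params.mod_depth * s, 0, 1)
    p_fa = np.clip(params.p_fa_base + params.fa_slope * params.mod_depth * s, 0, 1)
    p_press = np.where(schedule.is_nogo, p_fa, 1 - p_miss)

    presses = rng.random(schedule.n_trials) < p_press
    rts = np.maximum(RT_FLOOR, params.mu_rt + rng.normal(0, 1, schedule.n_trials) * sigma_n)
    times = np.sort((t + rts)[presses])
    return KeypressLog(press_times=times, run_duration=schedule.run_duration)


def simulate_bold(regressor, coupling: float, noise_sd: float, seed: int):
    """Synthetic BOLD series: ``coupling * regressor + white noise``.

    Returns a new :class:`~gradcpt.regressors.Regressor` on the same scan
    grid.  Serves as the test surface tying the VTC regressor to a
    recoverable signal: ordinary least squares of the output on the input
    regressor estimates ``coupling``.
    """
    from .regressors import Regressor

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    values = np.asarray(regressor.values, float)
    if values.size == 0:
        raise ValueError("regressor is empty")
    rng = np.random.default_rng(seed)
    noisy = coupling * values + rng.normal(0, noise_sd, values.shape)
    return Regressor(values=noisy, dt=regressor.dt, t0=regressor.t0)


def write_keypresses(log: KeypressLog, path) -> None:
    """Single-column TSV of press times, seconds."""
    with open(path, "w") as fh:
        fh.write("press_time\n")
        for t in log.press_times:
            fh.write(f"{t:.6f}\n")


def read_keypresses(path, run_duration: float) -> KeypressLog:
    times = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "press_time":
            raise ValueError(f"keypress file {path}: expected 'press_time' header")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                times.append(float(line))
            except ValueError as e:
                raise ValueError(f"keypress file {path}, line {ln}: not a number") from e
    return KeypressLog(press_times=np.asarray(sorted(times)), run_duration=run_duration)
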