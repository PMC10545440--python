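"""Design-matrix ingredients for event-related fMRI of the gradCPT.

Builds the canonical double-gamma hemodynamic response function (HRF),
stick (unit-impulse) regressors for the four trial outcomes, the
amplitude-modulated VTC regressor sampled on the scan grid (TR = 2 s), and
a discrete-cosine high-pass basis with a 128-s cutoff period.

All builders work on a fine time grid (default dt = 0.1 s), convolve with
the HRF, then sample at scan times ``t0 + k*TR``.  ``t0`` defaults to 10 s:
with 5 discarded equilibration volumes at TR 2 s, the first retained scan
falls 10 s into the run.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .assignment import CR, FA, HIT, MISS
from .schedule import StimulusSchedule

DEFAULT_DT = 0.1
DEFAULT_TR = 2.0
DEFAULT_T0 = 10.0  # 5 discarded volumes x TR 2 s
DEFAULT_HRF_DURATION = 32.0
DEFAULT_CUTOFF = 128.0

# Canonical double-gamma parameters: response peak delay 6 s, undershoot
# delay 16 s, unit dispersions, undershoot ratio 1/6.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0


@dataclass(frozen=True)
class Regressor:
    """A time series on a uniform grid: values, step ``dt``, start ``t0``."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regressor values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.dt


def canonical_hrf(dt: float = DEFAULT_DT, duration: float = DEFAULT_HRF_DURATION) -> np.ndarray:
    """Canonical double-gamma HRF sampled on [0, duration] at dt, unit peak.

    h(t) = g(t; 6, 1) - g(t; 16, 1)/6 with g the gamma density whose shape
    is delay/dispersion and scale the dispersion; peaks near 5 s with a
    negative undershoot afterwards.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must be in (0, 1]")
    t = np.arange(0, duration + dt / 2, dt)
    peak = gamma_dist.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
    under = gamma_dist.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP
    )
    h = peak - HRF_RATIO * under
    return h / h.max()


def _convolved_regressor(
    onsets: np.ndarray,
    weights: np.ndarray,
    run_duration: float,
    dt: float,
    tr: float,
    n_scans: int,
    t0: float,
) -> Regressor:
    """Weighted impulses on the fine grid -> HRF convolution -> scan grid."""
    import logging

    n_fine = int(np.ceil(run_duration / dt)) + 1
    fine = np.zeros(n_fine)
    kept = 0
    for onset, w in zip(onsets, weights):
        idx = int(round(onset / dt))
        if 0 <= idx < n_fine:
            fine[idx] += w
            kept += 1
        else:
            logging.getLogger(__name__).warning(
                "impulse at %.3f s outside run span [0, %.1f]; dropped", onset, run_duration
            )
    conv = np.convolve(fine, canonical_hrf(dt))[:n_fine]
    scan_times = t0 + np.arange(n_scans) * tr
    fine_times = np.arange(n_fine) * dt
    values = np.interp(scan_times, fine_times, conv, left=0.0, right=0.0)
    return Regressor(values=values, dt=tr, t0=t0)


def stick_regressors(
    table: pd.DataFrame,
    run_duration: float,
    dt: float = DEFAULT_DT,
    tr: float = DEFAULT_TR,
    n_scans: int = 200,
    t0: float = DEFAULT_T0,
) -> dict[str, Regressor]:
    """One HRF-convolved unit-impulse regressor per trial outcome class.

    A class with no trials yields an all-zero regressor.
    """
    if n_scans <= 0:
        raise ValueError("n_scans must be positive")
    out: dict[str, Regressor] = {}
    outcome = table["outcome"].str.lower()
    for cls in (HIT, MISS, FA, CR):
        onsets = table.loc[outcome == cls, "onset"].to_numpy(float)
        out[cls] = _convolved_regressor(
            onsets, np.ones(len(onsets)), run_duration, dt, tr, n_scans, t0
        )
    return out


def vtc_regressor(
    raw_vtc: np.ndarray,
    schedule: StimulusSchedule,
    dt: float = DEFAULT_DT,
    tr: float = DEFAULT_TR,
    n_scans: int = 200,
    t0: float = DEFAULT_T0,
) -> Regressor:
    """Amplitude-modulated VTC regressor on the scan grid.

    Impulses at trial onsets are weighted by the raw (non-smoothed) VTC
    values, convolved with the canonical HRF, and sampled at TR = 2 s; the
    HRF convolution supplies the hemodynamic delay.
    """
    raw_vtc = np.asarray(raw_vtc, float)
    if len(raw_vtc) != schedule.n_trials:
        raise ValueError(
            f"VTC length {len(raw_vtc)} != schedule trial count {schedule.n_trials}"
        )
    return _convolved_regressor(
        schedule.onsets, raw_vtc, schedule.run_duration, dt, tr, n_scans, t0
    )


def highpass_basis(n_scans: int, tr: float = DEFAULT_TR, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Discrete-cosine drift basis with periods >= cutoff seconds.

    Columns are c_k(t) = cos(pi*k*(2t+1)/(2N)) for k = 1..K with
    K = floor(2*N*tr/cutoff); residualizing against these plus a constant
    removes fluctuations slower than the cutoff period.  Shape (n_scans, K).
    """
    if n_scans <= 2:
        raise ValueError("n_scans must exceed 2")
    if cutoff < 2 * tr:
        raise ValueError("cutoff must be at least 2*tr")
    k_max = int(np.floor(2 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, k_max + 1)]
    )
    return basis


def residualize(series: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Remove the span of [1, basis] from a series by least squares."""
    x = np.column_stack([np.ones(len(series)), basis])
    beta, *_ = np.linalg.lstsq(x, series, rcond=None)
    return series - x @ beta


def design_matrix(regressors: dict[str, Regressor]) -> pd.DataFrame:
    """Assemble named regressors (common scan grid) into one table."""
    lengths = {len(r.values) for r in regressors.values()}
    if len(lengths) != 1:
        raise ValueError("regressors have mismatched lengths")
    return pd.DataFrame({name: r.values for name, r in regressors.items()})
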