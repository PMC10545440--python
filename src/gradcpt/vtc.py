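"""Variance time course (VTC): the trial-by-trial attention-fluctuation index.

The VTC is the absolute value of the z-scored reaction-time series of a run:
both unusually fast and unusually slow responses count as departures from
stable attending, so |z| tracks the momentary erraticness of performance.
Response-absent trials (misses and correct rejections) are first filled by
linear interpolation from the neighboring observed RTs so the series is
defined on every trial.  A Gaussian kernel of 7-s full width at half maximum
smooths the raw VTC; the dominant fluctuation frequency is then read from
the amplitude spectrum averaged over runs.

z-scoring is strictly per run; runs are never concatenated first.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import ABSENT, INTERPOLATED, OBSERVED

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
DEFAULT_FWHM = 7.0
DEFAULT_BAND = (0.005, 0.10)


@dataclass(frozen=True)
class VTCSeries:
    """Per-trial raw and smoothed |z|-RT values on the uniform trial grid."""

    trial_times: np.ndarray
    raw_vtc: np.ndarray
    smoothed_vtc: np.ndarray
    soa: float
    fwhm: float = DEFAULT_FWHM

    @property
    def n_trials(self) -> int:
        return len(self.raw_vtc)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(self.n_trials),
                "time": self.trial_times,
                "raw_vtc": self.raw_vtc,
                "smoothed_vtc": self.smoothed_vtc,
            }
        )


def interpolate_rts(table: pd.DataFrame) -> pd.DataFrame:
    """Fill response-absent trials by linear interpolation in trial time.

    Interior gaps take the straight line between the nearest observed RTs
    on either side; leading and trailing gaps copy the nearest observed RT.
    ``rt_source`` is updated to mark filled trials as interpolated.
    """
    rts = table["response_time"].to_numpy(float)
    observed = ~np.isnan(rts)
    if observed.sum() < 2:
        raise ValueError("need at least 2 observed RTs to interpolate")
    x = table["onset"].to_numpy(float)
    filled = np.interp(x, x[observed], rts[observed])

    out = table.copy()
    out.attrs = dict(table.attrs)
    out["response_time"] = filled
    src = out["rt_source"].to_numpy(object)
    src[(src == ABSENT)] = INTERPOLATED
    out["rt_source"] = src
    return out


def compute_vtc(rts: np.ndarray) -> np.ndarray:
    """|z| of a full (gap-free) RT series; sample SD (n-1 denominator)."""
    rts = np.asarray(rts, float)
    if len(rts) < 3:
        raise ValueError("need at least 3 RTs")
    if np.any(np.isnan(rts)):
        raise ValueError("RT series contains gaps; interpolate first")
    sd = rts.std(ddof=1)
    if sd == 0:
        raise ValueError("RT series has zero spread")
    return np.abs((rts - rts.mean()) / sd)


def smooth_vtc(raw_vtc: np.ndarray, soa: float, fwhm: float = DEFAULT_FWHM) -> np.ndarray:
    """Gaussian smoothing with edge renormalization.

    The kernel SD is ``fwhm / (2 sqrt(2 ln 2))`` seconds, i.e. sigma/soa in
    trial units, truncated at +/-4 sigma.  Near the edges the kernel is
    renormalized over the available samples so a constant input is returned
    unchanged everywhere.
    """
    if fwhm <= 0 or soa <= 0:
        raise ValueError("fwhm and soa must be positive")
    v = np.asarray(raw_vtc, float)
    sigma = fwhm * FWHM_TO_SIGMA / soa  # in trials
    half = max(1, int(np.ceil(4 * sigma)))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    num = np.convolve(v, k, mode="same")
    den = np.convolve(np.ones_like(v), k, mode="same")
    return num / den


def amplitude_spectrum(series: np.ndarray, soa: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed discrete-Fourier amplitude spectrum.

    Returns (frequencies, amplitudes) at ``k / (N * soa)`` for k >= 1.
    """
    x = np.asarray(series, float)
    n = len(x)
    amp = np.abs(np.fft.rfft(x - x.mean())) * 2 / n
    freqs = np.fft.rfftfreq(n, d=soa)
    return freqs[1:], amp[1:]


def fluctuation_frequency(
    vtcs: Sequence[np.ndarray],
    soa: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Dominant VTC fluctuation frequency, Hz.

    Per run: remove the mean of the (smoothed) VTC and take the DFT
    amplitude spectrum.  Spectra are averaged across runs on a common
    frequency grid (runs of unequal length are interpolated onto the grid
    of the longest run), and the peak within ``band`` is returned.
    """
    if not len(vtcs):
        raise ValueError("need at least one run")
    lo, hi = band
    n_max = max(len(v) for v in vtcs)
    f_res = 1.0 / (n_max * soa)
    nyquist = 1.0 / (2.0 * soa)
    if lo < f_res or hi > nyquist:
        raise ValueError(
            f"band {band} outside resolvable range [{f_res:.4g}, {nyquist:.4g}] Hz"
        )

    grid = np.fft.rfftfreq(n_max, d=soa)[1:]
    acc = np.zeros_like(grid)
    for v in vtcs:
        f, a = amplitude_spectrum(v, soa)
        acc += a if len(v) == n_max else np.interp(grid, f, a)
    mean_amp = acc / len(vtcs)

    in_band = (grid >= lo) & (grid <= hi)
    if not in_band.any():
        raise ValueError(f"no spectral bins inside band {band}")
    return float(grid[in_band][np.argmax(mean_amp[in_band])])


def vtc_from_table(table: pd.DataFrame, soa: float, fwhm: float = DEFAULT_FWHM) -> VTCSeries:
    """Full VTC stage for one run's trial table: interpolate, z, |.|, smooth."""
    filled = interpolate_rts(table)
    raw = compute_vtc(filled["response_time"].to_numpy(float))
    return VTCSeries(
        trial_times=filled["onset"].to_numpy(float),
        raw_vtc=raw,
        smoothed_vtc=smooth_vtc(raw, soa=soa, fwhm=fwhm),
        soa=soa,
        fwhm=fwhm,
    )


def write_vtc(series: VTCSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
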