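"""Session-level gradCPT performance measures: hit/FA rates, d', median RT.

d' is the signal-detection sensitivity Phi^-1(hit rate) - Phi^-1(FA rate).
Rates of exactly 0 or 1 would make it infinite, so each rate is clipped to
[1/(2N), 1 - 1/(2N)] with N the number of trials of the corresponding
category -- the standard extreme-rate correction.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assignment import FA, HIT, INTERPOLATED


@dataclass(frozen=True)
class SessionMetrics:
    hit_rate: float
    fa_rate: float
    d_prime: float
    median_rt: float
    n_go: int
    n_nogo: int
    fluct_freq: float | None = None  # filled by the VTC stage

    def to_dict(self) -> dict:
        return asdict(self)


def d_prime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Sensitivity d' with 1/(2N) clipping of extreme rates.

    Antisymmetric: ``d_prime(h, f, ...) == -d_prime(f, h, ...)`` when the
    trial counts are swapped accordingly.
    """
    if n_go <= 0 or n_nogo <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    h = np.clip(hit_rate, 1 / (2 * n_go), 1 - 1 / (2 * n_go))
    f = np.clip(fa_rate, 1 / (2 * n_nogo), 1 - 1 / (2 * n_nogo))
    return float(norm.ppf(h) - norm.ppf(f))


def session_metrics(tables: Sequence[pd.DataFrame]) -> SessionMetrics:
    """Pool trial tables across runs into one set of session measures.

    Hit and FA rates are pooled over all runs' trials (not averaged per
    run); d' comes from the pooled rates.  Median RT uses observed (hit and
    FA) responses only -- interpolated values exist for the VTC, not for RT
    summaries.
    """
    if not tables:
        raise ValueError("need at least one run")
    frames = pd.concat(tables, ignore_index=True)
    outcome = frames["outcome"].str.lower()
    observed = frames["response_time"].notna() & frames["rt_source"].ne(INTERPOLATED)

    n_go = int(outcome.isin([HIT, "miss"]).sum())
    n_nogo = int(outcome.isin([FA, "cr"]).sum())
    if n_go == 0:
        raise ValueError("no Go trials in session")
    if n_nogo == 0:
        raise ValueError("no No-go trials in session")

    hit_rate = float((outcome == HIT).sum() / n_go)
    fa_rate = float((outcome == FA).sum() / n_nogo)
    rts = frames.loc[observed, "response_time"]
    median_rt = float(rts.median()) if len(rts) else float("nan")

    return SessionMetrics(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=d_prime(hit_rate, fa_rate, n_go, n_nogo),
        median_rt=median_rt,
        n_go=n_go,
        n_nogo=n_nogo,
    )
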