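"""Keypress-to-trial response assignment and outcome classification.

In a gradCPT the stimuli cross-fade continuously, so a keypress has no
self-evident target trial.  The assignment rule used here attributes each
press to a trial via a response window anchored to the stimulus's fade
phases: the window of trial *n* (onset ``t_n``, appearance phase
``[t_n, t_n + SOA]``, disappearance phase ``[t_n + SOA, t_n + 2*SOA]``)
opens at 70% of the appearance phase and closes at 40% of the disappearance
phase, i.e. ``[t_n + 0.7*SOA, t_n + 1.4*SOA)``.  Presses falling between
one window's close and the next window's open, ``[t_n + 1.4*SOA,
t_n + 1.7*SOA)``, are ambiguous and are given to whichever adjacent trial
(earlier first) still lacks a response.  When a trial collects several
presses, the earliest one defines its RT and the rest are discarded.

All intervals are half-open so that a press on an exact boundary belongs to
exactly one region.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .observer import KeypressLog
from .schedule import GO, NOGO, StimulusSchedule

logger = logging.getLogger(__name__)

WINDOW_OPEN_FRAC = 0.7   # of the appearance phase
WINDOW_CLOSE_FRAC = 0.4  # of the disappearance phase

OBSERVED = "observed"
INTERPOLATED = "interpolated"
ABSENT = "absent"

HIT = "hit"
MISS = "miss"
FA = "fa"
CR = "cr"


@dataclass(frozen=True)
class AssignmentStats:
    """Bookkeeping for the press-assignment pass: every input press is
    either assigned or lands in exactly one discard category."""

    n_presses: int
    n_assigned: int
    n_surplus_discarded: int
    n_ambiguous_assigned: int
    n_ambiguous_discarded: int
    n_pre_window: int
    n_post_run: int

    def __post_init__(self):
        total = (
            self.n_assigned
            + self.n_surplus_discarded
            + self.n_ambiguous_discarded
            + self.n_pre_window
            + self.n_post_run
        )
        assert total == self.n_presses, "press accounting must balance"


def assign_presses(
    schedule: StimulusSchedule, presses: KeypressLog | np.ndarray
) -> pd.DataFrame:
    """Attribute keypresses to trials and classify outcomes.

    Returns a trial table (one row per trial) with columns ``trial_index``,
    ``onset``, ``trial_type``, ``response_time`` (seconds from the trial's
    onset; NaN when no press was attributed), ``outcome`` (hit/miss/fa/cr)
    and ``rt_source`` (observed/absent at this stage).  Assignment counts
    are attached in ``df.attrs["assignment_stats"]``.

    Observed RTs lie in ``[0.7*SOA, 1.7*SOA)`` for presses assigned through
    a trial's own window or gap, and in ``[0.4*SOA, 0.7*SOA)`` for gap
    presses handed forward to the next trial.
    """
    press_times = presses.press_times if isinstance(presses, KeypressLog) else np.asarray(presses, float)
    press_times = np.sort(press_times)
    s = schedule.soa
    n_trials = schedule.n_trials
    t0 = schedule.onsets[0] if n_trials else 0.0

    open_frac = WINDOW_OPEN_FRAC
    close = 1.0 + WINDOW_CLOSE_FRAC  # window closes at 1.4 SOA after onset

    rts = np.full(n_trials, np.nan)
    n_surplus = n_pre = n_post = n_amb_assigned = n_amb_discarded = 0
    ambiguous: list[tuple[int, float]] = []  # (gap owner trial, press time)

    for p in press_times:
        u = (p - t0) / s - open_frac
        if u < 0:
            n_pre += 1
            continue
        n = math.floor(u)
        frac = u - n  # position within [t_n + 0.7 SOA, t_n + 1.7 SOA)
        in_primary = frac < (close - open_frac)  # first 0.7 SOA is the window
        if n >= n_trials:  # past the last trial's window and gap
            n_post += 1
            continue
        if in_primary:
            if np.isnan(rts[n]):
                rts[n] = p - schedule.onsets[n]
            else:
                n_surplus += 1  # shortest-RT rule: later press discarded
        else:
            ambiguous.append((n, p))

    # Ambiguous (gap) presses resolve after all window presses, in time
    # order: the earlier response-less trial wins, else the later one.
    for n, p in ambiguous:
        if np.isnan(rts[n]):
            rts[n] = p - schedule.onsets[n]
            n_amb_assigned += 1
        elif n + 1 < n_trials and np.isnan(rts[n + 1]):
            rts[n + 1] = p - schedule.onsets[n + 1]
            n_amb_assigned += 1
        else:
            n_amb_discarded += 1

    has_rt = ~np.isnan(rts)
    is_nogo = schedule.is_nogo
    outcome = np.where(
        is_nogo, np.where(has_rt, FA, CR), np.where(has_rt, HIT, MISS)
    )

    stats = AssignmentStats(
        n_presses=len(press_times),
        n_assigned=int(has_rt.sum()),
        n_surplus_discarded=n_surplus,
        n_ambiguous_assigned=n_amb_assigned,
        n_ambiguous_discarded=n_amb_discarded,
        n_pre_window=n_pre,
        n_post_run=n_post,
    )
    if n_pre or n_post:
        logger.warning(
            "ignored %d pre-window and %d post-run presses", n_pre, n_post
        )
    logger.info(
        "assigned %d/%d presses (%d surplus, %d ambiguous->assigned, %d ambiguous->discarded)",
        stats.n_assigned, stats.n_presses, n_surplus, n_amb_assigned, n_amb_discarded,
    )

    table = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "onset": schedule.onsets,
            "trial_type": schedule.categories,
            "response_time": rts,
            "outcome": outcome,
            "rt_source": np.where(has_rt, OBSERVED, ABSENT),
        }
    )
    table.attrs["assignment_stats"] = stats
    table.attrs["soa"] = s
    return table


def classify_trials(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive outcome labels from category and response presence.

    hit  = Go with an observed RT;   miss = Go without;
    fa   = No-go with an observed RT; cr  = No-go without.
    """
    has_rt = table["response_time"].notna() & (table["rt_source"] != INTERPOLATED)
    is_nogo = table["trial_type"].str.lower().eq(NOGO)
    out = table.copy()
    out.attrs = dict(table.attrs)
    out["outcome"] = np.where(
        is_nogo, np.where(has_rt, FA, CR), np.where(has_rt, HIT, MISS)
    )
    return out


def write_trial_table(table: pd.DataFrame, path) -> None:
    cols = ["trial_index", "onset", "trial_type", "response_time", "outcome", "rt_source"]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"trial_index", "onset", "trial_type", "response_time", "outcome"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} missing columns: {sorted(missing)}")
    if "rt_source" not in df:
        df["rt_source"] = np.where(df["response_time"].notna(), OBSERVED, ABSENT)
    onsets = df["onset"].to_numpy(float)
    if len(onsets) > 1:
        df.attrs["soa"] = float(np.median(np.diff(onsets)))
    return df
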