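"""Stimulus schedules for the gradual-onset continuous performance task.

A gradCPT run presents a continuous stream of cross-fading stimuli: each
stimulus ramps up over one stimulus onset asynchrony (SOA) while the previous
one ramps down, so there is no abrupt onset.  Most trials are frequent "Go"
stimuli requiring a button press; a rare minority are "No-go" stimuli on
which the response must be withheld.  The schedule records, per trial, the
onset of the appearance ramp, the Go/No-go category, and which exemplar
(individual image or narration) was shown.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GO = "go"
NOGO = "nogo"

#: SOA conventions used in the task: 1.6 s for the auditory variant,
#: 0.8 s for the visual variant, each with 400-s runs and 10% No-go trials.
AUDITORY_SOA = 1.6
VISUAL_SOA = 0.8
DEFAULT_RUN_DURATION = 400.0
DEFAULT_NOGO_RATE = 0.1


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered trial onsets and categories for one run.

    Trial onsets are the start of each stimulus's appearance (fade-in) ramp,
    uniformly spaced at ``soa`` starting from 0.  The appearance phase of
    trial *n* spans ``[onset_n, onset_n + soa]`` and its disappearance phase
    the following SOA, overlapping the next stimulus's fade-in.
    """

    run_duration: float
    soa: float
    onsets: np.ndarray
    categories: np.ndarray  # array of GO / NOGO strings
    exemplar_ids: np.ndarray
    nogo_rate: float = DEFAULT_NOGO_RATE

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def is_nogo(self) -> np.ndarray:
        return self.categories == NOGO

    def __post_init__(self):
        if self.soa <= 0 or self.run_duration <= 0:
            raise ValueError("soa and run_duration must be positive")
        if not (len(self.onsets) == len(self.categories) == len(self.exemplar_ids)):
            raise ValueError("onsets, categories and exemplar_ids must be equal-length")

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type, stim_id)."""
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "duration": np.full(self.n_trials, self.soa),
                "trial_type": self.categories,
                "stim_id": self.exemplar_ids,
            }
        )


def make_schedule(
    run_duration: float = DEFAULT_RUN_DURATION,
    soa: float = VISUAL_SOA,
    nogo_rate: float = DEFAULT_NOGO_RATE,
    n_go_exemplars: int = 10,
    n_nogo_exemplars: int = 10,
    seed: int | np.random.Generator = 0,
    exact_counts: bool = False,
) -> StimulusSchedule:
    """Generate a random gradCPT schedule.

    Parameters
    ----------
    run_duration, soa:
        Run length and stimulus onset asynchrony, seconds.  A 400-s run
        yields 250 trials at SOA 1.6 s (auditory) or 500 at 0.8 s (visual).
    nogo_rate:
        Probability that a trial is No-go (0.1 in the standard task).
    n_go_exemplars, n_nogo_exemplars:
        Number of distinct stimuli per category; consecutive trials never
        repeat an exemplar, matching the task's no-immediate-repeat rule.
    seed:
        Integer seed or a ``numpy.random.Generator``.
    exact_counts:
        If True, place exactly ``round(nogo_rate * n_trials)`` No-go trials
        at random positions instead of drawing categories i.i.d.
    """
    if soa <= 0 or run_duration <= 0:
        raise ValueError("soa and run_duration must be positive")
    if soa > run_duration:
        raise ValueError("soa must not exceed run_duration")
    if not 0 <= nogo_rate <= 1:
        raise ValueError("nogo_rate must be in [0, 1]")
    if n_go_exemplars < 2 or n_nogo_exemplars < 2:
        raise ValueError("need at least 2 exemplars per category")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_trials = math.floor(run_duration / soa)
    onsets = np.arange(n_trials) * soa

    if exact_counts:
        n_nogo = round(nogo_rate * n_trials)
        cats = np.array([GO] * n_trials, dtype=object)
        cats[rng.choice(n_trials, size=n_nogo, replace=False)] = NOGO
    else:
        cats = np.where(rng.random(n_trials) < nogo_rate, NOGO, GO).astype(object)
    categories = cats.astype("U4")

    # Exemplars are drawn uniformly within category, excluding whichever
    # exemplar (of either category) was shown on the immediately preceding
    # trial -- two cross-fading stimuli are never the same item.
    exemplar_ids = np.empty(n_trials, dtype=np.int64)
    prev = -1
    for i in range(n_trials):
        n_ex = n_nogo_exemplars if categories[i] == NOGO else n_go_exemplars
        choice = int(rng.integers(n_ex))
        if choice == prev:
            choice = (choice + 1 + int(rng.integers(n_ex - 1))) % n_ex
        exemplar_ids[i] = choice
        prev = choice

    return StimulusSchedule(
        run_duration=run_duration,
        soa=soa,
        onsets=onsets,
        categories=categories,
        exemplar_ids=exemplar_ids,
        nogo_rate=nogo_rate,
    )


def write_events(schedule: StimulusSchedule, path) -> None:
    schedule.to_events().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path, run_duration: float | None = None) -> StimulusSchedule:
    """Read a BIDS-style events TSV back into a :class:`StimulusSchedule`.

    The SOA is recovered from the onset spacing; ``run_duration`` defaults
    to ``n_trials * soa``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns: {sorted(missing)}")
    onsets = df["onset"].to_numpy(float)
    if len(onsets) < 2:
        raise ValueError(f"events file {path} has fewer than 2 trials")
    soa = float(np.median(np.diff(onsets)))
    if run_duration is None:
        run_duration = len(onsets) * soa
    cats = df["trial_type"].astype(str).str.lower().to_numpy()
    if not set(cats) <= {GO, NOGO}:
        bad = sorted(set(cats) - {GO, NOGO})
        raise ValueError(f"events file {path}: unknown trial_type values {bad}")
    stim = df["stim_id"].to_numpy(np.int64) if "stim_id" in df else np.zeros(len(df), np.int64)
    nogo_rate = float(np.mean(cats == NOGO))
    return StimulusSchedule(
        run_duration=run_duration,
        soa=soa,
        onsets=onsets,
        categories=cats.astype("U4"),
        exemplar_ids=stim,
        nogo_rate=nogo_rate,
    )
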