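import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from gradcpt import ObserverParams, assign_presses, make_schedule, simulate_observer


@pytest.fixture
def visual_schedule():
    """One 400-s visual run: SOA 0.8 s, 500 trials, 10% No-go."""
    return make_schedule(400.0, 0.8, 0.1, seed=7)


@pytest.fixture
def auditory_schedule():
    """One 400-s auditory run: SOA 1.6 s, 250 trials, 10% No-go."""
    return make_schedule(400.0, 1.6, 0.1, seed=7)


@pytest.fixture
def noisy_session(visual_schedule):
    """A realistic simulated run and its assigned trial table."""
    params = ObserverParams(mod_depth=0.4, seed=11)
    log = simulate_observer(visual_schedule, params)
    table = assign_presses(visual_schedule, log)
    return visual_schedule, log, table


def make_trial_table(rts, categories=None, soa=0.8):
    """Hand-build a trial table from per-trial RTs (None = no response)."""
    n = len(rts)
    cats = categories or ["go"] * n
    rt = np.array([np.nan if v is None else v for v in rts], float)
    has = ~np.isnan(rt)
    outcome = [
        ("fa" if h else "cr") if c == "nogo" else ("hit" if h else "miss")
        for c, h in zip(cats, has)
    ]
    df = pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "onset": np.arange(n) * soa,
            "trial_type": cats,
            "response_time": rt,
            "outcome": outcome,
            "rt_source": np.where(has, "observed", "absent"),
        }
    )
    df.attrs["soa"] = soa
    return df
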