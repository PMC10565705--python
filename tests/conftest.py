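import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import serialdep as sd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_trials(n=20, participant="P1", session=1, start_index=1, **overrides):
    """A small valid trial table with overridable columns.

    Scalar overrides broadcast; array overrides must have length ``n``.
    Distractor fields default to absent to keep the invariant satisfied.
    """
    rng = np.random.default_rng(0)
    base = {
        "participant_id": participant,
        "session": session,
        "trial_index": np.arange(start_index, start_index + n),
        "location_condition": "random",
        "distractor_present": False,
        "distractor_orientation": np.nan,
        "distractor_location": np.nan,
        "probe_orientation": rng.uniform(0, 180, n),
        # accurate-by-default reports so exclusion-rule tests control their
        # own outliers explicitly
        "reported_orientation": None,
        "discrimination_correct": True,
        "discrimination_rt": 500.0,
        "adjustment_rt": 1500.0,
    }
    base.update(overrides)
    if base["reported_orientation"] is None:
        probe = np.broadcast_to(np.asarray(base["probe_orientation"], float), (n,))
        base["reported_orientation"] = np.mod(probe + rng.normal(0, 2, n), 180.0)
    df = pd.DataFrame(base)
    return df[sd.TRIAL_COLUMNS]


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated 4-participant experiment reused by read-only tests."""
    observers = sd.make_cohort(4, seed=42)
    design = sd.DesignParams(trials_per_session=400)
    return sd.simulate_experiment(design, observers, seed=42)


@pytest.fixture(scope="session")
def annotated_experiment(small_experiment):
    return sd.annotate_trials(small_experiment)
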