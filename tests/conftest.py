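import numpy as np
import pytest

import pavlov
from pavlov.task import SessionSequence, TaskConfig, TrialRecord


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()

@pytest.fixture(scope="session")
def appetitive_sessions(default_config):
    """19 default appetitive sessions with fixed seeds."""
    return [pavlov.generate_session(default_config, 100 + i) for i in range(19)]


@pytest.fixture(scope="session")
def aversive_sessions():
    cfg = TaskConfig(session_valence="aversive")
    return [pavlov.generate_session(cfg, 500 + i) for i in range(19)]


@pytest.fixture(scope="session")
def one_session(appetitive_sessions):
    return appetitive_sessions[0]


def make_session(events, valence="appetitive", config=None):
    """Build a hand-specified session from (cue, outcome[, new_pair]) tuples.

    ``latent_state`` is fixed at cue 1 -> valenced unless an event supplies an
    explicit 4th element.
    """
    config = config or TaskConfig(
        n_trials_per_session=120, fixed_length=False, session_valence=valence
    )
    trials = []
    for i, ev in enumerate(events):
        cue, outcome = ev[0], ev[1]
        new_pair = ev[2] if len(ev) > 2 else (i == 0)
        latent = ev[3] if len(ev) > 3 else 1
        trials.append(
            TrialRecord(
                trial_index=i,
                phase_index=0,
                pair_index=0,
                cue_id=cue,
                side="left" if i % 2 == 0 else "right",
                outcome=outcome,
                latent_state=latent,
                is_reversal_onset=False,
                is_new_pair_onset=new_pair,
                iti_s=3.0,
            )
        )
    return SessionSequence(config=config, seed=-1, trials=trials)


def random_short_session(rng, n_trials=6, valence="appetitive"):
    """A random hand-built session for oracle cross-checks."""
    events = []
    for i in range(n_trials):
        cue = int(rng.integers(1, 3))
        outcome = rng.choice(["valenced", "neutral", "none"], p=[0.3, 0.3, 0.4])
        if outcome == "valenced" and cue != 1:
            outcome = "none"
        if outcome == "neutral" and cue == 1:
            outcome = "none"
        new_pair = i == 0 or (n_trials > 4 and i == n_trials // 2 and rng.random() < 0.5)
        events.append((cue, outcome, new_pair))
    return make_session(events, valence=valence)
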