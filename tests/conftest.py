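"""Shared fixtures: small simulated sessions and hand-built trial factories."""

import numpy as np
import pytest

from puffcrus import BehaviorParams, SessionTable, TaskConfig, TrialRecord
from puffcrus.simulate import simulate_session


@pytest.fixture(scope="session")
def task():
    return TaskConfig()


@pytest.fixture(scope="session")
def behavior():
    return BehaviorParams(3.0, 0.3, 0.5, -0.2)


@pytest.fixture(scope="session")
def small_session(task, behavior):
    """A 120-trial baseline session reused by imaging/somatic/decoding tests."""
    return simulate_session(task, behavior, 120, rng_seed=1234)


def make_trial(trial_id, n_left, n_right, choice, cue_duration=3.8,
               correct_side=None, decision_time=None, task=None):
    """Build a valid TrialRecord with evenly spaced interior puffs."""
    task = task or TaskConfig()

    def times(n):
        interior = np.linspace(0.3, cue_duration - 0.3, n) if n else np.empty(0)
        return np.concatenate([[0.0], interior, [cue_duration]])

    if correct_side is None:
        correct_side = "R" if n_right >= n_left else "L"
    outcome = None if choice is None else (
        "correct" if choice == correct_side else "error")
    if decision_time is None:
        decision_time = task.pre_cue + cue_duration + task.delay + 0.5
    return TrialRecord(
        trial_id=trial_id, cue_duration=cue_duration,
        puffs_left=times(n_left), puffs_right=times(n_right),
        correct_side=correct_side, choice=choice, outcome=outcome,
        decision_time=decision_time,
        lick_times_left=np.array([decision_time]) if choice == "L" else np.empty(0),
        lick_times_right=np.array([decision_time]) if choice == "R" else np.empty(0))


def make_session(trials, task=None, **kw):
    return SessionTable(trials=list(trials), task=task or TaskConfig(), **kw)


@pytest.fixture
def trial_factory():
    return make_trial


@pytest.fixture
def session_factory():
    return make_session
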