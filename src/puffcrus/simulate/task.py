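"""Generative model of the puff-based evidence-accumulation task.

Stimuli are censored Poisson trains: each side draws homogeneous Poisson
arrivals (total rate split majority:minority by the configured side ratio)
which are then thinned left-to-right so that consecutive same-side puffs
are at least ``min_ipi`` apart.  Bilateral puffs mark the start and end of
the cue period.  Choices are drawn from a four-coefficient logistic model
with scaled evidence, previous-trial success/failure history terms, and a
bias.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy.special import expit

from ..types import BehaviorParams, SessionTable, TaskConfig, TrialRecord, substreams

__all__ = [
    "generate_puff_train",
    "draw_cue_durations",
    "history_terms",
    "choice_probability",
    "simulate_choice",
    "simulate_session",
]


def _censored_train(rate: float, duration: float, min_ipi: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Poisson proposals thinned so consecutive retained events are >= min_ipi apart.

    The boundary puff at time 0 seeds the thinning, and events within
    ``min_ipi`` of the end-boundary puff are dropped, so the full train
    (including both boundary puffs) respects the refractory constraint.
    """
    n = rng.poisson(rate * duration)
    proposals = np.sort(rng.uniform(0.0, duration, size=n))
    kept = []
    last = 0.0  # the start boundary puff
    for t in proposals:
        if t - last >= min_ipi and duration - t >= min_ipi:
            kept.append(t)
            last = t
    return np.asarray(kept, float)


def generate_puff_train(config: TaskConfig, cue_duration: float, correct_side: str,
                        rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Draw one trial's puff times for both sides.

    Returns ``(puffs_left, puffs_right)`` in seconds from cue onset, sorted,
    including the bilateral boundary puffs at 0 and ``cue_duration``.  The
    majority generative rate is assigned to ``correct_side``; because of
    refractory censoring the realized majority:minority count ratio is
    slightly below the configured rate ratio.
    """
    if cue_duration <= 0:
        raise ValueError("cue_duration must be positive")
    if correct_side not in ("L", "R"):
        raise ValueError("correct_side must be 'L' or 'R'")
    rates = {"L": config.minority_rate, "R": config.minority_rate}
    rates[correct_side] = config.majority_rate
    out = {}
    for side in ("L", "R"):
        interior = _censored_train(rates[side], cue_duration, config.min_ipi, rng)
        out[side] = np.concatenate([[0.0], interior, [cue_duration]])
    return out["L"], out["R"]


def draw_cue_durations(config: TaskConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` cue durations from the configured duration mixture."""
    return rng.choice(np.asarray(config.cue_durations, float), size=n,
                      p=np.asarray(config.cue_duration_probs, float))


def history_terms(prev: Optional[TrialRecord]) -> Tuple[float, float]:
    """Success/failure history codes from the previous trial.

    ``h_success`` is 0 if the previous trial was incorrect and -1/+1 if it
    was a correct left/right choice; ``h_failure`` mirrors this for
    erroneous left/right choices.  No previous trial gives (0, 0).
    """
    if prev is None or prev.choice not in ("L", "R"):
        return 0.0, 0.0
    sign = 1.0 if prev.choice == "R" else -1.0
    if prev.outcome == "correct":
        return sign, 0.0
    return 0.0, sign


def choice_probability(params: BehaviorParams, n_left: int, n_right: int,
                       prev: Optional[TrialRecord], scale: float) -> float:
    """P(rightward choice) under the history logistic model."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    s = np.clip((n_right - n_left) / scale, -1.0, 1.0)
    h_s, h_f = history_terms(prev)
    logit = (params.b_evidence * s + params.b_success * h_s
             + params.b_failure * h_f + params.b_bias)
    return float(expit(logit))


def simulate_choice(params: BehaviorParams, trial: TrialRecord,
                    prev: Optional[TrialRecord], scale: float,
                    rng: np.random.Generator) -> str:
    """Draw a choice ('L' or 'R') for ``trial`` given the previous trial."""
    p_right = choice_probability(params, trial.n_left, trial.n_right, prev, scale)
    return "R" if rng.random() < p_right else "L"


def _lick_trains(trial: TrialRecord, config: TaskConfig, rng: np.random.Generator,
                 consumption_rate: float, iti_lick_rate: float) -> None:
    """Synthesize decision, consumption, and sparse inter-trial licks in place.

    The decision lick is at ``decision_time``; correct trials are followed by
    consumption licking on the rewarded side, while after errors licking
    ceases.  A low spontaneous lick rate during the inter-trial interval
    provides isolated lick-bout events in both outcome contexts.
    """
    licks = {"L": [], "R": []}
    licks[trial.choice].append(trial.decision_time)
    iti = config.iti_correct if trial.outcome == "correct" else config.iti_error
    if trial.outcome == "correct" and consumption_rate > 0:
        t = trial.decision_time
        while True:
            t += rng.exponential(1.0 / consumption_rate)
            if t > trial.decision_time + config.consumption - 0.5:
                break
            licks[trial.choice].append(t)
    # sparse spontaneous licks late in the ITI, away from the decision phase
    iti_start = trial.decision_time + config.consumption
    n_spont = rng.poisson(iti_lick_rate * max(iti - 1.0, 0.0))
    for t in np.sort(rng.uniform(iti_start + 0.5, iti_start + max(iti - 0.5, 0.6), n_spont)):
        licks[rng.choice(["L", "R"])].append(t)
    trial.lick_times_left = np.sort(np.asarray(licks["L"]))
    trial.lick_times_right = np.sort(np.asarray(licks["R"]))


def simulate_session(task: TaskConfig, behavior: BehaviorParams, n_trials: int,
                     rng_seed: int, condition: str = "baseline",
                     consumption_lick_rate: float = 7.0,
                     iti_lick_rate: float = 0.3,
                     scale: Optional[float] = None) -> SessionTable:
    """Simulate a full behavioral session.

    Cue durations come from the configured mixture, the majority-rate side
    is a fair coin per trial, and choices are drawn sequentially from the
    history logistic model.  The evidence scale divisor defaults to the
    session-wide max |#R - #L| so that scaled evidence spans [-1, 1].
    Tie trials (equal interior counts) are redrawn so every trial has a
    defined correct side.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    streams = substreams(rng_seed, ["stimulus", "choice", "lick"])
    stim_rng, choice_rng, lick_rng = (streams["stimulus"], streams["choice"],
                                      streams["lick"])
    durations = draw_cue_durations(task, n_trials, stim_rng)
    trials = []
    for i in range(n_trials):
        majority = "R" if stim_rng.random() < 0.5 else "L"
        for _ in range(100):
            left, right = generate_puff_train(task, durations[i], majority, stim_rng)
            trial = TrialRecord(trial_id=i, cue_duration=float(durations[i]),
                                puffs_left=left, puffs_right=right,
                                correct_side=majority)
            if trial.n_left != trial.n_right:
                break
        trial.correct_side = "R" if trial.n_right > trial.n_left else "L"
        trials.append(trial)
    if scale is None:
        scale = max(1.0, max(abs(t.evidence) for t in trials))
    prev = None
    for trial in trials:
        trial.choice = simulate_choice(behavior, trial, prev, scale, choice_rng)
        trial.outcome = "correct" if trial.choice == trial.correct_side else "error"
        decision_phase_start = task.pre_cue + trial.cue_duration + task.delay
        trial.decision_time = decision_phase_start + choice_rng.uniform(0.2, 0.8)
        _lick_trains(trial, task, lick_rng, consumption_lick_rate, iti_lick_rate)
        prev = trial
    return SessionTable(trials=trials, condition=condition, rng_seed=rng_seed,
                        task=task)


def trial_duration(trial: TrialRecord, task: TaskConfig) -> float:
    """Total wall-clock duration of one trial on the session timeline."""
    iti = task.iti_correct if trial.outcome == "correct" else task.iti_error
    return trial.decision_time + task.consumption + iti
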