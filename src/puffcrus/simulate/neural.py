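"""Ground-truth neural activity synthesis for simulated sessions.

Somatic fluorescence is modeled as a firing-rate drive (ramps, per-puff
impulses, or choice-dependent offsets) converted to Poisson events,
convolved with a slow single-exponential calcium kernel, scaled by a gain
and corrupted by Gaussian noise.  Dendritic fluorescence is modeled as
discrete calcium events whose rate is conditioned on trial outcome
(elevated after decision errors), convolved with a fast kernel.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

from ..types import (CellGroundTruth, CellTraceMatrix, EventTrain, SessionTable,
                     SyncMap, TaskConfig)
from .task import trial_duration

__all__ = [
    "session_timeline",
    "make_soma_population",
    "make_dendrite_population",
    "synthesize_soma_activity",
    "synthesize_dendrite_activity",
]

#: default mixture of somatic response classes (ramps dominate, as in the
#: recorded population where ~70% of cells show cue-period time modulation)
DEFAULT_SOMA_MIX = {
    "ramp+": 0.45,
    "ramp-": 0.25,
    "evidence_L": 0.06,
    "evidence_R": 0.06,
    "evidence_diff": 0.03,
    "choice_selective": 0.05,
    "null": 0.10,
}


def session_timeline(session: SessionTable, frame_rate: float) -> Tuple[SyncMap, int]:
    """Lay trials end-to-end on a frame grid and build the sync map."""
    task = session.task
    if task is None:
        raise ValueError("session has no TaskConfig; cannot build a timeline")
    starts, cues, decisions = [], [], []
    t0 = 0.0
    for trial in session.trials:
        starts.append(t0)
        cues.append(t0 + task.pre_cue)
        decisions.append(t0 + trial.decision_time)
        t0 += trial_duration(trial, task)
    n_frames = int(np.ceil(t0 * frame_rate))
    sync = SyncMap(
        trial_ids=np.array([t.trial_id for t in session.trials]),
        first_frame=np.floor(np.array(starts) * frame_rate).astype(int),
        cue_onset_frame=np.floor(np.array(cues) * frame_rate).astype(int),
        decision_frame=np.floor(np.array(decisions) * frame_rate).astype(int),
    )
    return sync, n_frames


def make_soma_population(n_cells: int, rng: np.random.Generator,
                         proportions: Optional[dict] = None,
                         gain: float = 0.05, kinetics_tau: float = 1.0,
                         noise_sd: float = 0.05) -> List[CellGroundTruth]:
    """Build a somatic population with the given response-class mixture."""
    mix = dict(DEFAULT_SOMA_MIX if proportions is None else proportions)
    kinds = list(mix)
    probs = np.array([mix[k] for k in kinds], float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_cells, probs)
    cells = []
    for kind, count in zip(kinds, counts):
        for _ in range(count):
            cells.append(CellGroundTruth(
                kind=kind, gain=gain, kinetics_tau=kinetics_tau,
                noise_sd=noise_sd,
                pref_side="R" if rng.random() < 0.5 else "L"))
    rng.shuffle(cells)
    return cells


def make_dendrite_population(n_cells: int, rng: np.random.Generator,
                             frac_error: float = 0.8, gain: float = 1.0,
                             kinetics_tau: float = 0.2,
                             noise_sd: float = 0.1) -> List[CellGroundTruth]:
    """Build a dendritic population (error-coding cells plus nulls)."""
    cells = []
    for i in range(n_cells):
        kind = "error_dendrite" if rng.random() < frac_error else "null"
        cells.append(CellGroundTruth(kind=kind, gain=gain,
                                     kinetics_tau=kinetics_tau,
                                     noise_sd=noise_sd))
    return cells


def _exp_kernel(tau: float, frame_rate: float) -> np.ndarray:
    dt = 1.0 / frame_rate
    n = max(int(np.ceil(8.0 * tau / dt)), 2)
    return np.exp(-np.arange(n) * dt / tau)


def _convolve(events: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(events, kernel)[: events.size]


def synthesize_soma_activity(truth: Sequence[CellGroundTruth], session: SessionTable,
                             frame_rate: float = 28.0,
                             rng: Optional[np.random.Generator] = None,
                             sampling: str = "poisson",
                             ramp_peak_rate: float = 10.0,
                             puff_events: float = 2.0,
                             choice_rate: float = 10.0) -> CellTraceMatrix:
    """Simulate somatic ΔF/F traces for a population over a session.

    Per cell, a trial-wise drive (expected calcium events per frame) is
    built from its response class, sampled as Poisson counts (or used
    directly when ``sampling='expected'``, which removes spiking noise),
    convolved with the cell's exponential kernel, scaled by its gain, and
    corrupted by Gaussian noise.  Traces decay back toward baseline during
    the inter-trial interval through the kernel itself.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if sampling not in ("poisson", "expected"):
        raise ValueError("sampling must be 'poisson' or 'expected'")
    rng = np.random.default_rng() if rng is None else rng
    sync, n_frames = session_timeline(session, frame_rate)
    dt = 1.0 / frame_rate
    traces = np.zeros((len(truth), n_frames), float)
    for ci, cell in enumerate(truth):
        mu_pos = np.zeros(n_frames)
        mu_neg = np.zeros(n_frames)  # only used by evidence_diff cells
        for i, trial in enumerate(session.trials):
            f_cue = sync.cue_onset_frame[i]
            n_cue = max(int(round(trial.cue_duration * frame_rate)), 1)
            f_end = min(f_cue + n_cue, n_frames)
            if cell.kind in ("ramp+", "ramp-"):
                progress = np.arange(f_end - f_cue) / max(n_cue - 1, 1)
                mu_pos[f_cue:f_end] += ramp_peak_rate * progress * dt
            elif cell.kind in ("evidence_L", "evidence_R"):
                side = cell.kind[-1]
                for tp in trial.interior_puffs(side):
                    f = f_cue + int(tp * frame_rate)
                    if f < n_frames:
                        mu_pos[f] += puff_events
            elif cell.kind == "evidence_diff":
                for tp in trial.interior_puffs("R"):
                    f = f_cue + int(tp * frame_rate)
                    if f < n_frames:
                        mu_pos[f] += puff_events
                for tp in trial.interior_puffs("L"):
                    f = f_cue + int(tp * frame_rate)
                    if f < n_frames:
                        mu_neg[f] += puff_events
            elif cell.kind == "choice_selective":
                if trial.choice == cell.pref_side:
                    f0 = max(f_end - int(round(0.5 * frame_rate)), f_cue)
                    mu_pos[f0:f_end] += choice_rate * dt
        if sampling == "poisson":
            ev_pos = rng.poisson(mu_pos).astype(float)
            ev_neg = rng.poisson(mu_neg).astype(float) if mu_neg.any() else mu_neg
        else:
            ev_pos, ev_neg = mu_pos, mu_neg
        kernel = _exp_kernel(cell.kinetics_tau, frame_rate)
        trace = _convolve(ev_pos, kernel)
        if mu_neg.any():
            trace = trace - _convolve(ev_neg, kernel)
        trace = cell.gain * trace
        if cell.noise_sd > 0:
            trace = trace + rng.normal(0.0, cell.noise_sd, n_frames)
        traces[ci] = trace
    return CellTraceMatrix(values=traces, frame_rate=frame_rate, kind="dff",
                           sync=sync)


def synthesize_dendrite_activity(truth: Sequence[CellGroundTruth],
                                 session: SessionTable,
                                 frame_rate: float = 28.0,
                                 rng: Optional[np.random.Generator] = None,
                                 rate_error: float = 2.5,
                                 rate_correct: float = 0.5,
                                 spont_rate: float = 0.05,
                                 outcome_window: float = 0.8,
                                 ) -> Tuple[CellTraceMatrix, List[EventTrain]]:
    """Simulate dendritic ΔF/F traces with outcome-locked discrete events.

    ``error_dendrite`` cells emit events in the ``outcome_window`` seconds
    after the decision at rate ``rate_error`` on error trials and
    ``rate_correct`` on correct trials, plus a common low spontaneous rate
    everywhere; ``null`` cells have the spontaneous rate only.  Returns the
    noisy traces and the ground-truth event trains (for deconvolution
    testing).
    """
    if rate_error < 0 or rate_correct < 0:
        raise ValueError("event rates must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    sync, n_frames = session_timeline(session, frame_rate)
    wf = int(outcome_window * frame_rate)
    traces = np.zeros((len(truth), n_frames), float)
    trains: List[EventTrain] = []
    for ci, cell in enumerate(truth):
        events = np.zeros(n_frames)
        # spontaneous events across the whole session
        n_spont = rng.poisson(spont_rate * n_frames / frame_rate)
        for f in rng.integers(0, n_frames, n_spont):
            events[f] += 1.0
        if cell.kind == "error_dendrite":
            for i, trial in enumerate(session.trials):
                rate = rate_error if trial.outcome == "error" else rate_correct
                f0 = sync.decision_frame[i]
                n_ev = rng.poisson(rate * outcome_window)
                for f in rng.integers(f0, min(f0 + wf, n_frames), n_ev):
                    events[f] += 1.0
        kernel = _exp_kernel(cell.kinetics_tau, frame_rate)
        trace = cell.gain * _convolve(events, kernel)
        if cell.noise_sd > 0:
            trace = trace + rng.normal(0.0, cell.noise_sd, n_frames)
        traces[ci] = trace
        frames = np.flatnonzero(events)
        gamma = float(np.exp(-1.0 / (cell.kinetics_tau * frame_rate)))
        trains.append(EventTrain(event_frames=frames,
                                 amplitudes=cell.gain * events[frames],
                                 ar_coefficient=gamma))
    return (CellTraceMatrix(values=traces, frame_rate=frame_rate, kind="dff",
                            sync=sync), trains)
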