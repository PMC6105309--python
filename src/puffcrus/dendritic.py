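"""Dendritic calcium-event detection and error-signal quantification.

Dendritic transients reflect climbing-fiber input and are modeled as an
AR(1) process driven by sparse non-negative events: y(t) = gamma*y(t-1) +
s(t) + noise.  Events are inferred by minimizing 0.5*||y - K s||^2 +
lambda*||s||_0 (K the AR(1) convolution matrix) with a candidate-detection
/ non-negative-least-squares refit / backward-pruning scheme, then
binarized at an amplitude threshold (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize
import scipy.stats

from .somatic import window_means
from .types import CellTraceMatrix, EventTrain, SessionTable

__all__ = [
    "deconvolve_events",
    "gamma_from_tau",
    "OutcomeResponse",
    "outcome_response_stats",
    "lick_bouts",
    "MotorEventResult",
    "motor_event_ratio",
    "DifficultyResult",
    "difficulty_modulation",
]


def gamma_from_tau(tau: float, frame_rate: float) -> float:
    """Per-frame AR(1) decay coefficient for a given calcium time constant."""
    return float(np.exp(-1.0 / (tau * frame_rate)))


def _nnls_on_support(y: np.ndarray, support: np.ndarray, gamma: float
                     ) -> Tuple[np.ndarray, float]:
    """Non-negative LS amplitudes for events at ``support`` frames."""
    t = np.arange(y.size)
    K = np.zeros((y.size, support.size))
    for j, f in enumerate(support):
        rows = t >= f
        K[rows, j] = gamma ** (t[rows] - f)
    amps, rnorm = scipy.optimize.nnls(K, y)
    return amps, rnorm ** 2


def _solve_cluster(y: np.ndarray, support: np.ndarray, gamma: float,
                   lam: float) -> Tuple[np.ndarray, np.ndarray]:
    """NNLS refit + backward pruning of one candidate cluster."""
    support = np.asarray(support, int)
    amps, rss = _nnls_on_support(y, support, gamma)
    keep = amps > 0
    support, amps = support[keep], amps[keep]
    if support.size:
        amps, rss = _nnls_on_support(y, support, gamma)
    # backward elimination: drop the weakest event while the sparsity
    # penalty saved exceeds the residual cost of removing it
    while support.size:
        j = int(np.argmin(amps))
        reduced = np.delete(support, j)
        if reduced.size:
            amps_r, rss_r = _nnls_on_support(y, reduced, gamma)
        else:
            amps_r, rss_r = np.empty(0), float(y @ y)
        if rss_r - rss < lam:
            support, amps, rss = reduced, amps_r, rss_r
        else:
            break
    return support, amps


def deconvolve_events(dff: np.ndarray, ar_coefficient: float,
                      sparsity: Optional[float] = None,
                      threshold: float = 0.1) -> EventTrain:
    """Sparse AR(1) deconvolution of a ΔF/F trace with an L0 penalty.

    Candidate events are detected from the AR(1)-whitened innovation
    d(t) = y(t) - gamma*y(t-1); amplitudes are refit on the candidate
    support by non-negative least squares and pruned backward under the L0
    objective.  ``sparsity`` is the L0 penalty weight lambda; its default
    is noise-scaled (lambda = (2.5*sigma)^2/2 with sigma a robust MAD
    estimate of the innovation noise).  Events with refit amplitude at or
    above ``threshold`` form the binarized train; the threshold is in the
    trace's ΔF/F units.
    """
    y = np.asarray(dff, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite values")
    gamma = float(ar_coefficient)
    if not 0.0 < gamma < 1.0:
        raise ValueError("ar_coefficient must be in (0, 1)")
    d = y - gamma * np.r_[0.0, y[:-1]]
    if sparsity is None:
        sigma = 1.4826 * np.median(np.abs(d - np.median(d)))
        kappa = 2.5 * sigma
        lam = 0.5 * kappa ** 2
    else:
        lam = float(sparsity)
        kappa = np.sqrt(2.0 * lam)
    candidates = np.flatnonzero(d > max(kappa, 1e-6))
    if candidates.size == 0:
        return EventTrain(np.empty(0, int), np.empty(0),
                          binarization_threshold=threshold,
                          ar_coefficient=gamma)
    # split candidates into clusters separated by more than the kernel's
    # effective length, and solve each cluster independently
    L = int(np.ceil(np.log(1e-6) / np.log(gamma)))
    breaks = np.flatnonzero(np.diff(candidates) > L) + 1
    frames_out, amps_out = [], []
    for cluster in np.split(candidates, breaks):
        a = int(cluster[0])
        b = min(int(cluster[-1]) + L, y.size)
        sup, amps = _solve_cluster(y[a:b], cluster - a, gamma, lam)
        frames_out.extend((sup + a).tolist())
        amps_out.extend(amps.tolist())
    frames_out = np.asarray(frames_out, int)
    amps_out = np.asarray(amps_out)
    keep = amps_out >= threshold
    return EventTrain(frames_out[keep], amps_out[keep],
                      binarization_threshold=threshold, ar_coefficient=gamma)


@dataclass
class OutcomeResponse:
    """Post-decision activity split by trial outcome, across cells."""

    mean_post_error: np.ndarray    # per cell
    mean_post_correct: np.ndarray  # per cell
    ratio_error_correct: np.ndarray
    fraction_error_greater: float
    signed_rank_p: float
    n_frames: int                  # frames per 800 ms window (floored)
    n_error_trials: int
    n_correct_trials: int


def outcome_response_stats(traces: CellTraceMatrix, session: SessionTable,
                           window: float = 0.8) -> OutcomeResponse:
    """Per-cell mean ΔF/F in the post-decision window split by outcome.

    The window covers ``window`` seconds after the decision lick (reward
    delivery on correct trials, its absence on errors), floored to whole
    frames.  Reports the per-cell error:correct means and ratio, the
    fraction of cells with error > correct, and a population Wilcoxon
    signed-rank test on the paired means.
    """
    idx = [i for i, t in enumerate(session.trials) if t.outcome in
           ("correct", "error")]
    outcomes = np.array([session.trials[i].outcome for i in idx])
    n_err = int((outcomes == "error").sum())
    n_cor = int((outcomes == "correct").sum())
    if n_err < 3 or n_cor < 3:
        raise ValueError("need at least 3 trials of each outcome")
    means = window_means(traces, session, "post_decision", idx)
    m_err = means[:, outcomes == "error"].mean(axis=1)
    m_cor = means[:, outcomes == "correct"].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_err / m_cor
    diffs = m_err - m_cor
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(scipy.stats.wilcoxon(m_err, m_cor)[1])
    return OutcomeResponse(
        mean_post_error=m_err, mean_post_correct=m_cor,
        ratio_error_correct=ratio,
        fraction_error_greater=float((m_err > m_cor).mean()),
        signed_rank_p=p,
        n_frames=int(window * traces.frame_rate),
        n_error_trials=n_err, n_correct_trials=n_cor)


def lick_bouts(lick_times: np.ndarray, min_gap: float = 0.25
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Lick-bout initiations and cessations on one side.

    A lick is a bout start if at least ``min_gap`` seconds precede it
    without licking on that side (the first lick always starts a bout),
    and a bout stop if at least ``min_gap`` seconds follow it.  An
    isolated lick is both.
    """
    t = np.sort(np.asarray(lick_times, float))
    if t.size == 0:
        return np.empty(0), np.empty(0)
    gaps = np.diff(t)
    starts = t[np.r_[True, gaps >= min_gap]]
    stops = t[np.r_[gaps >= min_gap, True]]
    return starts, stops


@dataclass
class MotorEventResult:
    """Error:correct activity ratios at one motor event kind."""

    kind: str
    ratios: np.ndarray  # per cell (cells with non-positive denominator dropped)
    signed_rank_p: float
    n_events_error: int
    n_events_correct: int
    n_cells_excluded: int

    @property
    def median_ratio(self) -> float:
        return float(np.median(self.ratios)) if self.ratios.size else np.nan


_WINDOW_MODES = {
    "centered_1s": (-0.5, 0.5),
    "pre_200ms": (-0.2, 0.0),
    "post_200ms": (0.0, 0.2),
}


def _event_window_means(traces: CellTraceMatrix, frames: Sequence[int],
                        lo_f: int, hi_f: int) -> np.ndarray:
    """Per-cell mean activity over windows around event frames: (cells, events)."""
    cols = []
    for f in frames:
        a, b = max(f + lo_f, 0), min(f + hi_f, traces.n_frames)
        if b > a:
            cols.append(traces.values[:, a:b].mean(axis=1))
    return (np.stack(cols, axis=1) if cols
            else np.empty((traces.n_cells, 0)))


def motor_event_ratio(traces: CellTraceMatrix, session: SessionTable,
                      movement_onsets: Optional[Dict[str, np.ndarray]] = None,
                      window_mode: str = "centered_1s",
                      min_gap: float = 0.25,
                      min_events: int = 3) -> Dict[str, MotorEventResult]:
    """Error:correct dendritic activity ratios at motor events.

    Lick bout starts/stops are extracted per side with the ``min_gap``
    rule and pooled; optional ``movement_onsets`` maps an event kind to
    absolute frame indices (e.g. from ``detect_onsets`` on a movement
    index).  Each event inherits the outcome context of its trial (events
    in the inter-trial interval belong to the preceding trial).  Per cell,
    the mean windowed ΔF/F is computed per context and their ratio taken;
    a one-sample Wilcoxon signed-rank test of the log-ratio against 0 is
    run across cells.  Cells with a non-positive denominator are excluded
    and counted.
    """
    if window_mode not in _WINDOW_MODES:
        raise ValueError(f"unknown window_mode {window_mode!r}")
    lo, hi = _WINDOW_MODES[window_mode]
    fr = traces.frame_rate
    lo_f, hi_f = int(round(lo * fr)), int(round(hi * fr))
    sync = traces.sync
    first = sync.first_frame

    def trial_of_frame(f: int) -> int:
        return int(np.searchsorted(first, f, side="right") - 1)

    events: Dict[str, Dict[str, list]] = {}
    for i, trial in enumerate(session.trials):
        if trial.outcome not in ("correct", "error"):
            continue
        ctx = trial.outcome
        for side_times in (trial.lick_times_left, trial.lick_times_right):
            starts, stops = lick_bouts(side_times, min_gap)
            for kind, times in (("lick_start", starts), ("lick_stop", stops)):
                for t in times:
                    f = int(first[i]) + int(t * fr)
                    events.setdefault(kind, {"error": [], "correct": []})
                    events[kind][ctx].append(f)
    if movement_onsets:
        for kind, frames in movement_onsets.items():
            events.setdefault(kind, {"error": [], "correct": []})
            for f in np.asarray(frames, int):
                i = trial_of_frame(int(f))
                if 0 <= i < len(session.trials):
                    ctx = session.trials[i].outcome
                    if ctx in ("correct", "error"):
                        events[kind][ctx].append(int(f))
    results = {}
    for kind, ctxs in events.items():
        if min(len(ctxs["error"]), len(ctxs["correct"])) < min_events:
            continue
        m_err = _event_window_means(traces, ctxs["error"], lo_f, hi_f).mean(axis=1)
        m_cor = _event_window_means(traces, ctxs["correct"], lo_f, hi_f).mean(axis=1)
        valid = m_cor > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = (m_err / m_cor)[valid & (m_err > 0)]
        log_r = np.log(ratios)
        if log_r.size < 5 or np.allclose(log_r, 0):
            p = np.nan if log_r.size < 5 else 1.0
        else:
            p = float(scipy.stats.wilcoxon(log_r)[1])
        results[kind] = MotorEventResult(
            kind=kind, ratios=ratios, signed_rank_p=p,
            n_events_error=len(ctxs["error"]),
            n_events_correct=len(ctxs["correct"]),
            n_cells_excluded=int((~(valid & (m_err > 0))).sum()))
    return results


@dataclass
class DifficultyResult:
    """Strong-minus-weak evidence error responses, per session."""

    differences: np.ndarray  # one value per session
    p: Optional[float]       # two-tailed paired t-test across sessions
    strong_means: np.ndarray
    weak_means: np.ndarray


def difficulty_modulation(sessions: Sequence[Tuple[CellTraceMatrix, SessionTable]],
                          n_strata: int = 3) -> DifficultyResult:
    """Does the post-error dendritic response depend on trial difficulty?

    Per session, error trials are split into terciles of evidence strength
    |#R-#L|; the mean post-decision dendritic response (over cells and
    trials) is compared between the strongest and weakest terciles, and
    the per-session differences are tested across sessions with a
    two-tailed paired t-test (omitted for a single session).
    """
    strong, weak = [], []
    for traces, session in sessions:
        idx = [i for i, t in enumerate(session.trials) if t.outcome == "error"]
        if len(idx) < 2 * n_strata:
            raise ValueError("too few error trials to stratify by difficulty")
        mags = np.abs([session.trials[i].evidence for i in idx])
        # rank-based split: ties in the discrete |#R-#L| cannot empty a stratum
        order = np.argsort(mags, kind="stable")
        bounds = np.linspace(0, len(idx), n_strata + 1).astype(int)
        means = window_means(traces, session, "post_decision", idx)
        strong.append(means[:, order[bounds[-2]:]].mean())
        weak.append(means[:, order[:bounds[1]]].mean())
    strong = np.asarray(strong)
    weak = np.asarray(weak)
    if len(sessions) < 2:
        p = None
    elif np.allclose(strong, weak):
        p = 1.0
    else:
        p = float(scipy.stats.ttest_rel(strong, weak)[1])
    return DifficultyResult(differences=strong - weak, p=p,
                            strong_means=strong, weak_means=weak)
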