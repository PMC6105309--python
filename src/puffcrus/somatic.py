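"""Per-cell statistics on somatic ΔF/F: time-modulation index, choice
selectivity, puff-triggered responses, and the trial-wise evidence linear
model with its choice-held shuffle control.

Somatic analyses are restricted by default to trials of the primary cue
duration so that windows are comparable across trials.  Per-cell tests are
reported uncorrected; a Benjamini-Hochberg column is available for users.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .types import CellTraceMatrix, SessionTable

__all__ = [
    "modulation_index",
    "modulation_indices",
    "ModulationResult",
    "modulation_fraction_test",
    "choice_selectivity",
    "PuffTriggeredResponse",
    "puff_triggered_response",
    "EvidenceModelResult",
    "evidence_linear_model",
    "compare_category_rates",
    "baseline_return_test",
]


# ---------------------------------------------------------------- windows

def _primary_trials(traces: CellTraceMatrix, session: SessionTable,
                    restrict_primary: bool) -> list:
    idx = list(range(len(session.trials)))
    if restrict_primary:
        primary = (session.task.primary_cue_duration
                   if session.task is not None else 3.8)
        idx = [i for i in idx
               if np.isclose(session.trials[i].cue_duration, primary)]
    return [i for i in idx if session.trials[i].choice in ("L", "R")]


def _window_frames(traces: CellTraceMatrix, session: SessionTable, i: int,
                   which: str) -> Tuple[int, int]:
    """Frame range [start, stop) of a named per-trial analysis window."""
    sync = traces.sync
    fr = traces.frame_rate
    trial = session.trials[i]
    task = session.task
    cue_f = int(sync.cue_onset_frame[i])
    n_cue = int(round(trial.cue_duration * fr))
    two_s = int(round(2.0 * fr))
    if which == "pre_cue":
        return cue_f - two_s, cue_f
    if which == "cue":
        return cue_f, cue_f + n_cue
    if which == "mid_cue":
        mid = cue_f + n_cue // 2
        return mid - two_s // 2, mid + two_s // 2
    if which == "pre_decision":  # 500 ms preceding the decision phase
        end = cue_f + int(round((trial.cue_duration + task.delay) * fr))
        return end - int(round(0.5 * fr)), end
    if which == "post_decision":
        d = int(sync.decision_frame[i])
        return d, d + int(0.8 * fr)
    if which == "pre_choice":
        d = int(sync.decision_frame[i])
        return d - int(0.8 * fr), d
    if which == "post_iti":  # final second of the trial's inter-trial interval
        end = sync.trial_end_frame(i, traces.n_frames)
        return end - int(round(1.0 * fr)), end
    raise ValueError(f"unknown window {which!r}")


def window_means(traces: CellTraceMatrix, session: SessionTable, which: str,
                 trial_idx: Optional[Sequence[int]] = None) -> np.ndarray:
    """Mean trace value in a named window: (n_cells, n_trials)."""
    if trial_idx is None:
        trial_idx = range(len(session.trials))
    cols = []
    for i in trial_idx:
        a, b = _window_frames(traces, session, i, which)
        a, b = max(a, 0), min(b, traces.n_frames)
        cols.append(traces.values[:, a:b].mean(axis=1))
    return np.stack(cols, axis=1)


def _trial_averaged_window(traces: CellTraceMatrix, session: SessionTable,
                           which: str, trial_idx: Sequence[int]) -> np.ndarray:
    """Trial-averaged windowed segments: (n_cells, window_frames)."""
    segs = []
    for i in trial_idx:
        a, b = _window_frames(traces, session, i, which)
        if a < 0 or b > traces.n_frames:
            continue
        segs.append(traces.values[:, a:b])
    n = min(s.shape[1] for s in segs)
    return np.mean([s[:, :n] for s in segs], axis=0)


# ---------------------------------------------------------- modulation r

def modulation_index(signal: np.ndarray) -> float:
    """Pearson correlation of a signal with a uniform time vector.

    Measures ramp-like modulation: +1 for a strictly increasing trace,
    0 for time-symmetric traces.  Zero-variance signals (or windows with
    fewer than 3 samples) are undefined and returned as NaN.
    """
    x = np.asarray(signal, float)
    if x.size < 3 or np.ptp(x) == 0:
        return np.nan
    return float(scipy.stats.pearsonr(np.arange(x.size), x)[0])


def modulation_indices(traces: CellTraceMatrix, session: SessionTable,
                       restrict_primary: bool = True
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell modulation index in the 2 s mid-cue and 2 s pre-cue windows.

    r is computed on the trial-averaged signal in each window, per cell.
    Returns ``(r_cue, r_precue)``.
    """
    idx = _primary_trials(traces, session, restrict_primary)
    cue = _trial_averaged_window(traces, session, "mid_cue", idx)
    pre = _trial_averaged_window(traces, session, "pre_cue", idx)
    r_cue = np.array([modulation_index(row) for row in cue])
    r_pre = np.array([modulation_index(row) for row in pre])
    return r_cue, r_pre


@dataclass
class ModulationResult:
    """Fraction of cells whose |r_cue| exceeds |r_precue|, with bootstrap CI.

    The CI is the 5th/95th percentile of fractions over cell resamples.
    The shuffle condition randomly swaps each cell's cue/pre-cue window
    identity before comparing, giving the symmetric null (~50%).
    """

    fraction: float
    ci: Tuple[float, float]
    shuffle_fraction: float
    shuffle_ci: Tuple[float, float]
    n_cells: int
    n_boot: int
    reliable: bool = True


def _bootstrap_fraction(exceed: np.ndarray, n_boot: int,
                        rng: np.random.Generator) -> Tuple[float, float]:
    n = exceed.size
    idx = rng.integers(0, n, size=(n_boot, n))
    fracs = exceed[idx].mean(axis=1)
    return float(np.percentile(fracs, 5)), float(np.percentile(fracs, 95))


def modulation_fraction_test(r_cue: np.ndarray, r_precue: np.ndarray,
                             n_boot: int = 10000,
                             rng: Optional[np.random.Generator] = None,
                             ) -> ModulationResult:
    """Test whether cue-period time modulation exceeds the pre-cue baseline.

    Point estimate: fraction of cells with |r_cue| > |r_precue|.  The CI
    bootstraps cells with replacement ``n_boot`` times.  The shuffle
    control swaps the two window labels independently per cell.
    """
    rng = np.random.default_rng() if rng is None else rng
    r_cue = np.asarray(r_cue, float)
    r_precue = np.asarray(r_precue, float)
    ok = np.isfinite(r_cue) & np.isfinite(r_precue)
    a, b = np.abs(r_cue[ok]), np.abs(r_precue[ok])
    exceed = (a > b).astype(float)
    ci = _bootstrap_fraction(exceed, n_boot, rng)
    swap = rng.random(a.size) < 0.5
    a_s, b_s = np.where(swap, b, a), np.where(swap, a, b)
    exceed_s = (a_s > b_s).astype(float)
    ci_s = _bootstrap_fraction(exceed_s, n_boot, rng)
    return ModulationResult(
        fraction=float(exceed.mean()), ci=ci,
        shuffle_fraction=float(exceed_s.mean()), shuffle_ci=ci_s,
        n_cells=int(exceed.size), n_boot=n_boot,
        reliable=exceed.size >= 10)


# ----------------------------------------------------- choice selectivity

def choice_selectivity(traces: CellTraceMatrix, session: SessionTable,
                       alpha: float = 0.05, restrict_primary: bool = True
                       ) -> pd.DataFrame:
    """Per-cell choice selectivity of pre-decision fluorescence.

    Two-tailed two-sample t-test of the per-trial mean over the 500 ms
    preceding the end of the delay, split by upcoming choice.  Cells are
    also classified by whether their cue-period modulation has the same or
    opposite sign in left- vs right-choice trials.
    """
    idx = _primary_trials(traces, session, restrict_primary)
    choices = np.array([session.trials[i].choice for i in idx])
    if len(set(choices)) < 2:
        return pd.DataFrame({"p": np.full(traces.n_cells, np.nan),
                             "significant": False, "greater_side": None,
                             "direction": None, "skipped": True})
    means = window_means(traces, session, "pre_decision", idx)
    li, ri = np.flatnonzero(choices == "L"), np.flatnonzero(choices == "R")
    stat, p = scipy.stats.ttest_ind(means[:, li], means[:, ri], axis=1)
    avg_l = _trial_averaged_window(traces, session, "cue", [idx[i] for i in li])
    avg_r = _trial_averaged_window(traces, session, "cue", [idx[i] for i in ri])
    r_l = np.array([modulation_index(row) for row in avg_l])
    r_r = np.array([modulation_index(row) for row in avg_r])
    direction = np.where(np.sign(r_l) == np.sign(r_r), "same", "opposite")
    greater = np.where(means[:, li].mean(axis=1) > means[:, ri].mean(axis=1),
                       "L", "R")
    return pd.DataFrame({
        "p": p, "significant": p < alpha, "greater_side": greater,
        "direction": direction, "r_left": r_l, "r_right": r_r,
        "p_bh": multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1],
        "skipped": False})


# ------------------------------------------------- puff-triggered average

@dataclass
class PuffTriggeredResponse:
    """Mean ΔF/F around puff onsets with the half-decay time of the peak."""

    lags: np.ndarray
    mean_response: np.ndarray
    baseline: float
    t_half_decay: float
    n_events: int
    ok: bool = True
    reason: str = ""


def _t_half(lags: np.ndarray, resp: np.ndarray, baseline: float,
            peak_search: Tuple[float, float]) -> Tuple[float, str]:
    post = (lags >= peak_search[0]) & (lags <= peak_search[1])
    if not post.any():
        return np.nan, "empty peak-search window"
    seg = np.where(post, resp, -np.inf)
    pk = int(np.argmax(seg))
    peak = resp[pk]
    if peak <= baseline:
        return np.nan, "flat response (no peak above baseline)"
    target = peak - 0.5 * (peak - baseline)
    for j in range(pk, resp.size - 1):
        if resp[j + 1] <= target:
            # linear interpolation between frames j and j+1
            frac = (resp[j] - target) / (resp[j] - resp[j + 1])
            t_cross = lags[j] + frac * (lags[j + 1] - lags[j])
            return float(t_cross - lags[pk]), ""
    return np.nan, "response never decayed to half amplitude"


def puff_triggered_response(trace: np.ndarray, session: SessionTable,
                            traces_meta: CellTraceMatrix, side: str,
                            max_puffs: int = 3,
                            window: Tuple[float, float] = (-0.4, 1.5),
                            baseline_window: float = 0.4,
                            peak_search: Tuple[float, float] = (0.0, 1.0),
                            min_events: int = 5) -> PuffTriggeredResponse:
    """Average ΔF/F triggered on sparse-side puff onsets.

    Qualifying puffs come from trials with fewer than ``max_puffs``
    interior puffs on ``side`` (bilateral boundary puffs excluded).  The
    baseline is the mean response in the 400 ms preceding the puff, and
    the half-decay time runs from the peak (searched within
    ``peak_search``) to 50% of the peak-to-baseline span, linearly
    interpolated between frames.
    """
    fr = traces_meta.frame_rate
    sync = traces_meta.sync
    lo, hi = int(round(window[0] * fr)), int(round(window[1] * fr))
    lags = np.arange(lo, hi + 1) / fr
    segs = []
    for i, trial in enumerate(session.trials):
        puffs = trial.interior_puffs(side)
        if puffs.size >= max_puffs:
            continue
        cue_f = int(sync.cue_onset_frame[i])
        for tp in puffs:
            f = cue_f + int(tp * fr)
            if f + lo >= 0 and f + hi + 1 <= trace.size:
                segs.append(trace[f + lo: f + hi + 1])
    if len(segs) < min_events:
        return PuffTriggeredResponse(lags, np.full_like(lags, np.nan), np.nan,
                                     np.nan, len(segs), ok=False,
                                     reason="too few qualifying puffs")
    mean_resp = np.mean(segs, axis=0)
    n_base = max(int(round(baseline_window * fr)), 1)
    baseline = float(mean_resp[lags < 0][-n_base:].mean())
    t_half, why = _t_half(lags, mean_resp, baseline, peak_search)
    return PuffTriggeredResponse(lags, mean_resp, baseline, t_half, len(segs),
                                 ok=(why == ""), reason=why)


# --------------------------------------------------- evidence linear model

EVIDENCE_CATEGORIES = ("+L", "-L", "+R", "-R", "+(L,R)", "-(L,R)",
                       "+(L,-R)", "-(L,-R)", "none")


@dataclass
class EvidenceModelResult:
    """Per-cell two-factor (puff-count) linear model fits and categories."""

    table: pd.DataFrame  # coef_L, coef_R, p_L, p_R, category per cell
    shuffled: bool = False

    def category_counts(self) -> pd.Series:
        return self.table["category"].value_counts().reindex(
            EVIDENCE_CATEGORIES, fill_value=0)

    def fraction_modulated(self) -> float:
        return float((self.table["category"] != "none").mean())


def _categorize(coef_l, coef_r, sig_l, sig_r) -> str:
    if sig_l and sig_r:
        s_l, s_r = np.sign(coef_l), np.sign(coef_r)
        if s_l == s_r:
            return "+(L,R)" if s_l > 0 else "-(L,R)"
        return "+(L,-R)" if s_l > 0 else "-(L,-R)"
    if sig_l:
        return "+L" if coef_l > 0 else "-L"
    if sig_r:
        return "+R" if coef_r > 0 else "-R"
    return "none"


def evidence_linear_model(traces: CellTraceMatrix, session: SessionTable,
                          shuffle: bool = False,
                          rng: Optional[np.random.Generator] = None,
                          alpha: float = 0.05, restrict_primary: bool = True,
                          min_trials: int = 20) -> EvidenceModelResult:
    """Two-factor linear model of pre-decision fluorescence on puff counts.

    Per cell, OLS (with intercept) of the mean ΔF/F in the 500 ms
    preceding the decision phase on the trial's left and right interior
    puff counts; per-coefficient two-tailed t-tests at ``alpha`` assign
    each cell to a signed single-side, sum, or difference category.  The
    shuffle control permutes (n_left, n_right) jointly across trials of
    the same choice, destroying evidence coding while preserving choice
    coding.
    """
    idx = _primary_trials(traces, session, restrict_primary)
    if len(idx) < min_trials:
        raise ValueError(f"need >= {min_trials} decided trials")
    n_l = np.array([session.trials[i].n_left for i in idx], float)
    n_r = np.array([session.trials[i].n_right for i in idx], float)
    choices = np.array([session.trials[i].choice for i in idx])
    if shuffle:
        rng = np.random.default_rng() if rng is None else rng
        perm = np.arange(len(idx))
        for c in np.unique(choices):
            rows = np.flatnonzero(choices == c)
            perm[rows] = rows[rng.permutation(rows.size)]
        n_l, n_r = n_l[perm], n_r[perm]
    if np.ptp(n_l) == 0 or np.ptp(n_r) == 0:
        raise ValueError("puff-count regressors must have non-zero variance")
    Y = window_means(traces, session, "pre_decision", idx).T  # trials x cells
    X = np.column_stack([n_l, n_r, np.ones_like(n_l)])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (3, n_cells)
    resid = Y - X @ beta
    dof = len(idx) - 3
    s2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), dof)
    collinear = ~np.isfinite(tstat[:2]).all(axis=0)
    rows = []
    for c in range(Y.shape[1]):
        sig_l, sig_r = pvals[0, c] < alpha, pvals[1, c] < alpha
        rows.append({
            "coef_L": beta[0, c], "coef_R": beta[1, c],
            "p_L": pvals[0, c], "p_R": pvals[1, c],
            "category": ("none" if collinear[c]
                         else _categorize(beta[0, c], beta[1, c], sig_l, sig_r)),
            "collinear": bool(collinear[c]),
        })
    return EvidenceModelResult(table=pd.DataFrame(rows), shuffled=shuffle)


def compare_category_rates(real: EvidenceModelResult,
                           shuffled: EvidenceModelResult) -> pd.DataFrame:
    """Two-proportion z-test of real vs shuffle category rates per category."""
    n_real = len(real.table)
    n_shuf = len(shuffled.table)
    rows = []
    for cat in EVIDENCE_CATEGORIES:
        k_real = int((real.table["category"] == cat).sum())
        k_shuf = int((shuffled.table["category"] == cat).sum())
        if k_real + k_shuf == 0:
            p = np.nan
        else:
            _, p = proportions_ztest([k_real, k_shuf], [n_real, n_shuf])
        rows.append({"category": cat, "rate_real": k_real / n_real,
                     "rate_shuffle": k_shuf / n_shuf, "p": p})
    return pd.DataFrame(rows)


# ------------------------------------------------------- baseline return

def baseline_return_test(traces: CellTraceMatrix, session: SessionTable
                         ) -> Tuple[float, float, int]:
    """Paired t-test of pre-cue vs post-ITI activity across cell x trial pairs.

    Returns (statistic, p, n_comparisons).  A non-significant result
    indicates activity returns to baseline by the end of each trial.
    """
    idx = [i for i in range(len(session.trials))
           if session.trials[i].choice in ("L", "R")]
    pre = window_means(traces, session, "pre_cue", idx).ravel()
    post = window_means(traces, session, "post_iti", idx).ravel()
    if np.allclose(pre, post):  # identical samples: no difference by construction
        return 0.0, 1.0, pre.size
    stat, p = scipy.stats.ttest_rel(pre, post)
    return float(stat), float(p), pre.size
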