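"""Behavioral model fitting: psychometric curves, time-binned evidence
regression, the trial-history choice GLM, and the bootstrap comparison used
for inactivation sessions.

All fits operate on decided trials only (trials with no decision lick are
excluded), and logistic fits are unpenalized maximum likelihood; separation
or non-convergence is reported, never silently regularized away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .types import BehaviorParams, SessionTable, TrialRecord

__all__ = [
    "PsychometricFit",
    "EvidenceTimecourse",
    "GlmFitResult",
    "four_param_logistic",
    "fit_psychometric",
    "jeffreys_ci",
    "evidence_timecourse_regression",
    "history_design",
    "fit_glm_design",
    "fit_history_glm",
    "muscimol_bootstrap_test",
]


def four_param_logistic(x, y0, A, x0, b):
    """y(x) = y0 + A / (1 + exp(-(x - x0)/b)) — the 4PL psychometric curve."""
    return y0 + A / (1.0 + np.exp(-(np.asarray(x, float) - x0) / b))


@dataclass
class PsychometricFit:
    """Four-parameter logistic fit of P(choose right) vs signed evidence."""

    y0: float = np.nan
    A: float = np.nan
    x0: float = np.nan
    b: float = np.nan
    cov: Optional[np.ndarray] = None
    levels: Optional[np.ndarray] = None       # distinct #R-#L values
    proportions: Optional[np.ndarray] = None  # P(choose R) per level
    n_per_level: Optional[np.ndarray] = None
    ok: bool = True
    reason: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.array([self.y0, self.A, self.x0, self.b])

    @property
    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(4, np.nan)
        return np.sqrt(np.diag(self.cov))

    def predict(self, x):
        return four_param_logistic(x, self.y0, self.A, self.x0, self.b)


def fit_psychometric(session: SessionTable) -> PsychometricFit:
    """Least-squares 4PL fit of per-level P(choose R) vs evidence #R - #L.

    Choice proportions are computed per distinct evidence level
    (unweighted in the curve fit).  Degenerate data (single evidence
    level, all-identical choices) or non-convergence return a flagged
    failure with diagnostics instead of raising.
    """
    trials = session.decided_trials()
    ev = np.array([t.evidence for t in trials], float)
    y = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    levels = np.unique(ev)
    if levels.size < 2:
        return PsychometricFit(ok=False, reason="fewer than 2 evidence levels")
    props = np.array([y[ev == lv].mean() for lv in levels])
    ns = np.array([(ev == lv).sum() for lv in levels])
    fit = PsychometricFit(levels=levels, proportions=props, n_per_level=ns)
    if np.all(y == y[0]):
        fit.ok = False
        fit.reason = "all choices identical (saturated data)"
        return fit
    p0 = (float(props.min()), float(props.max() - props.min()), 0.0,
          max(np.ptp(levels) / 8.0, 0.5))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = scipy.optimize.curve_fit(
                four_param_logistic, levels, props, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as err:
        fit.ok = False
        fit.reason = f"curve fit failed: {err}"
        return fit
    if not np.all(np.isfinite(pcov)):
        fit.ok = False
        fit.reason = "degenerate fit (non-finite parameter covariance)"
    fit.y0, fit.A, fit.x0, fit.b = popt
    fit.cov = pcov
    return fit


def jeffreys_ci(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Jeffreys binomial proportion interval from the Beta(k+1/2, n-k+1/2) posterior.

    Equal-tailed, with the standard boundary convention lo=0 when k=0 and
    hi=1 when k=n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    alpha = 1.0 - level
    post = scipy.stats.beta(k + 0.5, n - k + 0.5)
    lo = 0.0 if k == 0 else float(post.ppf(alpha / 2.0))
    hi = 1.0 if k == n else float(post.ppf(1.0 - alpha / 2.0))
    return lo, hi


@dataclass
class EvidenceTimecourse:
    """Per-bin logistic coefficients of choice on binned (R-L) puff counts."""

    coefficients: np.ndarray
    conf_int: np.ndarray  # (n_bins, 2), 95%
    wald_p: np.ndarray
    intercept: float
    control: str = "none"
    n_trials: int = 0
    ok: bool = True
    reason: str = ""

    @property
    def n_bins(self) -> int:
        return self.coefficients.size


def binned_evidence(trial: TrialRecord, n_bins: int) -> np.ndarray:
    """(R - L) interior puff counts in temporally uniform bins of the cue."""
    edges = np.linspace(0.0, trial.cue_duration, n_bins + 1)
    r = np.histogram(trial.interior_puffs("R"), bins=edges)[0]
    l = np.histogram(trial.interior_puffs("L"), bins=edges)[0]
    return (r - l).astype(float)


def evidence_timecourse_regression(session: SessionTable, n_bins: int = 5,
                                   control: str = "none",
                                   rng: Optional[np.random.Generator] = None,
                                   primary_duration: Optional[float] = None,
                                   ) -> EvidenceTimecourse:
    """Logistic regression of choice on per-bin (R - L) puff counts.

    Restricted to trials of the primary cue duration so bins are
    comparable across trials.  Controls: ``shuffle_bins`` permutes each
    trial's count vector across bins; ``shuffle_choices`` permutes choices
    across trials.
    """
    if control not in ("none", "shuffle_bins", "shuffle_choices"):
        raise ValueError(f"unknown control {control!r}")
    if control != "none" and rng is None:
        rng = np.random.default_rng()
    if primary_duration is None:
        primary_duration = (session.task.primary_cue_duration
                            if session.task is not None else 3.8)
    trials = [t for t in session.decided_trials()
              if np.isclose(t.cue_duration, primary_duration)]
    if len(trials) < n_bins + 2:
        return EvidenceTimecourse(np.full(n_bins, np.nan),
                                  np.full((n_bins, 2), np.nan),
                                  np.full(n_bins, np.nan), np.nan,
                                  control=control, ok=False,
                                  reason="too few primary-duration trials")
    X = np.stack([binned_evidence(t, n_bins) for t in trials])
    y = np.array([1.0 if t.choice == "R" else 0.0 for t in trials])
    if control == "shuffle_bins":
        X = np.stack([row[rng.permutation(n_bins)] for row in X])
    elif control == "shuffle_choices":
        y = y[rng.permutation(y.size)]
    if np.all(y == y[0]):
        return EvidenceTimecourse(np.full(n_bins, np.nan),
                                  np.full((n_bins, 2), np.nan),
                                  np.full(n_bins, np.nan), np.nan,
                                  control=control, ok=False,
                                  reason="all choices identical")
    Xc = sm.add_constant(X, prepend=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    return EvidenceTimecourse(
        coefficients=res.params[:n_bins],
        conf_int=np.asarray(res.conf_int())[:n_bins],
        wald_p=res.pvalues[:n_bins],
        intercept=float(res.params[n_bins]),
        control=control, n_trials=len(trials))


@dataclass
class GlmFitResult:
    """History-GLM maximum-likelihood estimates with standard errors."""

    params: BehaviorParams
    se: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    log_likelihood: float = np.nan
    n_trials: int = 0
    ok: bool = True
    reason: str = ""

    def as_array(self) -> np.ndarray:
        return self.params.as_array()


def history_design(session: SessionTable, scale: Optional[float] = None
                   ) -> pd.DataFrame:
    """Per-trial design rows (s, h_success, h_failure, choice_right).

    Scaled evidence s = (#R - #L)/scale clipped to [-1, 1]; the scale
    divisor defaults to the session max |#R - #L|.  History terms code the
    previous *decided* trial; the first trial's history terms are 0.
    """
    from .simulate.task import history_terms

    trials = session.decided_trials()
    if scale is None:
        scale = max(1.0, max(abs(t.evidence) for t in trials))
    rows, prev = [], None
    for t in trials:
        h_s, h_f = history_terms(prev)
        rows.append({
            "s": float(np.clip(t.evidence / scale, -1.0, 1.0)),
            "h_success": h_s, "h_failure": h_f,
            "choice_right": 1.0 if t.choice == "R" else 0.0,
        })
        prev = t
    return pd.DataFrame(rows)


def fit_glm_design(design: pd.DataFrame) -> GlmFitResult:
    """Fit the history GLM to a prebuilt design table (see history_design)."""
    X = sm.add_constant(design[["s", "h_success", "h_failure"]].to_numpy(),
                        prepend=False, has_constant="add")
    y = design["choice_right"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        params = np.asarray(res.params)
        if (not np.all(np.isfinite(res.bse)) or np.any(np.abs(params) > 50)
                or np.any(np.asarray(res.bse) > 100)):
            raise ValueError("separation or non-identified fit")
    except Exception as err:  # perfect separation, singular design, ...
        return GlmFitResult(params=BehaviorParams(0, 0, 0, 0), ok=False,
                            reason=str(err), n_trials=len(design))
    return GlmFitResult(
        params=BehaviorParams(*params),
        se=np.asarray(res.bse),
        log_likelihood=float(res.llf),
        n_trials=len(design))


def fit_history_glm(session: SessionTable, scale: Optional[float] = None
                    ) -> GlmFitResult:
    """Fit the four-coefficient trial-history logistic choice model.

    Binomial GLM with logit link of P(right) on scaled evidence, success
    history, failure history, and a bias (intercept).
    """
    return fit_glm_design(history_design(session, scale=scale))


@dataclass
class BootstrapComparison:
    """Per-coefficient bootstrap comparison of a test fit against baseline."""

    coef_names: tuple
    test_fit: GlmFitResult
    baseline_fit: GlmFitResult
    p_greater: np.ndarray  # fraction of bootstrap fits exceeded by the test fit
    p_less: np.ndarray
    p_two_sided: np.ndarray
    n_boot: int
    n_failures: int
    boot_params: np.ndarray = None  # (n_ok, 4) bootstrap coefficient draws


def muscimol_bootstrap_test(test_session: SessionTable,
                            baseline_session: SessionTable,
                            n_boot: int = 10000,
                            rng: Optional[np.random.Generator] = None,
                            ) -> BootstrapComparison:
    """Bootstrap test of whether an inactivation session's GLM coefficients
    differ from baseline.

    Baseline trials (design rows, with history terms already attached) are
    resampled with replacement ``n_boot`` times and refit; per coefficient
    the one-sided exceedance fraction — the fraction of bootstrap fits that
    the test-session fit exceeds — is reported along with its complement
    and min(2*tail, 1) as a two-sided p-value.
    """
    rng = np.random.default_rng() if rng is None else rng
    test_fit = fit_history_glm(test_session)
    base_design = history_design(baseline_session)
    base_fit = fit_glm_design(base_design)
    if not (test_fit.ok and base_fit.ok):
        raise RuntimeError("test or baseline GLM fit failed; cannot bootstrap")
    n = len(base_design)
    boots, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        fit = fit_glm_design(base_design.iloc[idx])
        if fit.ok:
            boots.append(fit.as_array())
        else:
            failures += 1
    if failures > 0.05 * n_boot:
        warnings.warn(f"{failures}/{n_boot} bootstrap refits failed",
                      stacklevel=2)
    boots = np.asarray(boots)
    test = test_fit.as_array()
    p_greater = (test[None, :] > boots).mean(axis=0)
    p_less = (test[None, :] < boots).mean(axis=0)
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))
    return BootstrapComparison(
        coef_names=("b_evidence", "b_success", "b_failure", "b_bias"),
        test_fit=test_fit, baseline_fit=base_fit,
        p_greater=p_greater, p_less=p_less, p_two_sided=p_two,
        n_boot=n_boot, n_failures=failures, boot_params=boots)
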