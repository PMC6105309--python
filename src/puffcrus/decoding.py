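"""Confound-controlled population decoding of choice, evidence side, and
trial outcome.

Choice and the side of greater evidence are correlated whenever the animal
performs above chance, so raw decoding accuracy conflates the two.  The
independence shuffle isolates each variable's own contribution: the target
label is permuted only within strata of the other (conditioning) variable,
which removes target information while preserving the conditioning
variable's joint distribution with every covariate exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .somatic import window_means
from .types import CellTraceMatrix, SessionTable

__all__ = [
    "DecodingResult",
    "bin_features",
    "independence_shuffle",
    "evidence_magnitude_strata",
    "decode_variable",
    "OutcomeDecodingResult",
    "decode_outcome",
]


def _classifier(C: float, rng: np.random.Generator):
    seed = int(rng.integers(0, 2 ** 31 - 1))
    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, max_iter=2000, random_state=seed))
    return clf, seed


@dataclass
class DecodingResult:
    """Cross-validated decoding accuracy per time bin."""

    bin_centers: np.ndarray  # s relative to cue onset
    accuracy: np.ndarray     # mean CV accuracy per bin
    sem: np.ndarray          # SEM over folds per bin
    fold_scores: np.ndarray  # (n_bins, k)
    condition: str
    target: str
    cv_folds: int
    n_trials: int


def bin_features(traces: CellTraceMatrix, session: SessionTable,
                 trial_idx: Sequence[int], bin_s: float = 0.4,
                 t_start: float = -2.0, t_stop: float = 4.0) -> Tuple[np.ndarray, np.ndarray]:
    """Per-trial, per-cell mean activity in uniform time bins.

    Bins are relative to cue onset; returns ``(X, centers)`` where X has
    shape (n_trials, n_cells, n_bins).
    """
    fr = traces.frame_rate
    edges = np.arange(t_start, t_stop + 1e-9, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    X = np.zeros((len(trial_idx), traces.n_cells, centers.size))
    for k, i in enumerate(trial_idx):
        cue_f = int(traces.sync.cue_onset_frame[i])
        for b in range(centers.size):
            a = cue_f + int(round(edges[b] * fr))
            z = cue_f + int(round(edges[b + 1] * fr))
            a, z = max(a, 0), min(z, traces.n_frames)
            X[k, :, b] = traces.values[:, a:z].mean(axis=1)
    return X, centers


def evidence_magnitude_strata(evidence: np.ndarray, n_strata: int = 4,
                              method: str = "quantile") -> np.ndarray:
    """Bin |#R-#L| into ``n_strata`` groups (quantile or fixed-width)."""
    mag = np.abs(np.asarray(evidence, float))
    if method == "quantile":
        qs = np.quantile(mag, np.linspace(0, 1, n_strata + 1)[1:-1])
        return np.searchsorted(qs, mag, side="right")
    if method == "fixed":
        edges = np.linspace(mag.min(), mag.max(), n_strata + 1)[1:-1]
        return np.searchsorted(edges, mag, side="right")
    raise ValueError("method must be 'quantile' or 'fixed'")


def independence_shuffle(labels_target: np.ndarray, strata: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Permute target labels only within strata of a conditioning variable.

    Within-stratum label multisets (and hence all marginals) are preserved
    exactly; singleton strata keep their label unchanged.
    """
    labels = np.asarray(labels_target).copy()
    strata = np.asarray(strata)
    for s in np.unique(strata):
        rows = np.flatnonzero(strata == s)
        if rows.size > 1:
            labels[rows] = labels[rows][rng.permutation(rows.size)]
    return labels


def decode_variable(traces: CellTraceMatrix, session: SessionTable,
                    target: str = "choice", condition: str = "real",
                    k: int = 5, rng: Optional[np.random.Generator] = None,
                    bin_s: float = 0.4, t_start: float = -2.0,
                    t_stop: float = 4.0, C: float = 1.0,
                    n_strata: int = 4, strata_method: str = "quantile",
                    restrict_primary: bool = True) -> DecodingResult:
    """Time-resolved decoding of choice or evidence side from binned activity.

    Per 400 ms time bin, a standardized linear logistic classifier is
    scored by stratified ``k``-fold cross-validation.  Conditions:
    ``real`` uses the true labels; ``shuffle`` permutes the target across
    all trials; ``independent`` permutes the target only within strata of
    the correlated variable (choice strata when decoding evidence;
    evidence-magnitude strata when decoding choice).
    """
    if target not in ("choice", "evidence_side"):
        raise ValueError("target must be 'choice' or 'evidence_side'")
    if condition not in ("real", "shuffle", "independent"):
        raise ValueError("condition must be real|shuffle|independent")
    rng = np.random.default_rng() if rng is None else rng
    primary = (session.task.primary_cue_duration
               if session.task is not None else 3.8)
    idx = [i for i, t in enumerate(session.trials)
           if t.choice in ("L", "R")
           and (not restrict_primary or np.isclose(t.cue_duration, primary))]
    choices = np.array([session.trials[i].choice == "R" for i in idx], int)
    evidence = np.array([session.trials[i].evidence for i in idx])
    ev_side = (evidence > 0).astype(int)
    labels = choices if target == "choice" else ev_side
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("decoding requires two label classes")
    if counts.max() / counts.min() > 9:
        warnings.warn("class imbalance exceeds 9:1", stacklevel=2)
    if condition == "shuffle":
        labels = labels[rng.permutation(labels.size)]
    elif condition == "independent":
        if target == "choice":
            strata = evidence_magnitude_strata(evidence, n_strata, strata_method)
        else:
            strata = choices
        labels = independence_shuffle(labels, strata, rng)
    X, centers = bin_features(traces, session, idx, bin_s, t_start, t_stop)
    fold_scores = np.zeros((centers.size, k))
    for b in range(centers.size):
        clf, seed = _classifier(C, rng)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        fold_scores[b] = cross_val_score(clf, X[:, :, b], labels, cv=cv)
    return DecodingResult(
        bin_centers=centers, accuracy=fold_scores.mean(axis=1),
        sem=fold_scores.std(axis=1, ddof=1) / np.sqrt(k),
        fold_scores=fold_scores, condition=condition, target=target,
        cv_folds=k, n_trials=len(idx))


@dataclass
class OutcomeDecodingResult:
    """Distribution of matched-batch outcome-decoding accuracies."""

    accuracies: np.ndarray  # one CV accuracy per batch
    window: str             # 'post_choice' or 'pre_choice'
    condition: str
    n_batches: int
    batch_size: int         # trials per class in each batch

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sem(self) -> float:
        return float(self.accuracies.std(ddof=1) / np.sqrt(self.accuracies.size))


def decode_outcome(traces: CellTraceMatrix, session: SessionTable,
                   window: str = "post_choice", n_batches: int = 1000,
                   k: int = 3, rng: Optional[np.random.Generator] = None,
                   condition: str = "real", C: float = 1.0
                   ) -> OutcomeDecodingResult:
    """Trial-outcome decoding from the 800 ms around the decision.

    Features are per-cell mean ΔF/F in the 800 ms following
    (``post_choice``) or preceding (``pre_choice``) the decision.  Each of
    ``n_batches`` batches subsamples equal numbers of correct and error
    trials and scores a standardized logistic classifier by stratified
    ``k``-fold CV; the accuracy distribution over batches is returned.
    The shuffle condition permutes outcomes within each batch.
    """
    if window not in ("post_choice", "pre_choice"):
        raise ValueError("window must be 'post_choice' or 'pre_choice'")
    if condition not in ("real", "shuffle"):
        raise ValueError("condition must be 'real' or 'shuffle'")
    rng = np.random.default_rng() if rng is None else rng
    idx = [i for i, t in enumerate(session.trials) if t.choice in ("L", "R")]
    outcomes = np.array([session.trials[i].outcome == "error" for i in idx], int)
    which = "post_decision" if window == "post_choice" else "pre_choice"
    feats = window_means(traces, session, which, idx).T  # trials x cells
    err = np.flatnonzero(outcomes == 1)
    cor = np.flatnonzero(outcomes == 0)
    m = min(err.size, cor.size)
    if m < k:
        raise ValueError(f"need at least {k} trials of each outcome")
    accs = np.zeros(n_batches)
    for b in range(n_batches):
        sel = np.concatenate([rng.choice(err, m, replace=False),
                              rng.choice(cor, m, replace=False)])
        y = outcomes[sel]
        if condition == "shuffle":
            y = y[rng.permutation(y.size)]
        clf, seed = _classifier(C, rng)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        accs[b] = cross_val_score(clf, feats[sel], y, cv=cv).mean()
    return OutcomeDecodingResult(accuracies=accs, window=window,
                                 condition=condition, n_batches=n_batches,
                                 batch_size=m)
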