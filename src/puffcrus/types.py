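"""Domain containers shared across the simulation and analysis modules.

The task under study is a head-fixed somatosensory evidence-accumulation
paradigm: on each trial two streams of air puffs are delivered to the left
and right whiskers during a cue period, and after a short delay the animal
reports which side received more puffs by licking one of two ports.
Neural data are two-photon calcium movies of cerebellar Purkinje cells
(somata or dendrites) synchronized to the trial structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "BehaviorParams",
    "TrialRecord",
    "SessionTable",
    "CellGroundTruth",
    "SyncMap",
    "FluorescenceMovie",
    "RoiMask",
    "CellTraceMatrix",
    "EventTrain",
    "substreams",
]

#: response classes used by the synthetic neural generator
CELL_KINDS = (
    "ramp+",
    "ramp-",
    "evidence_L",
    "evidence_R",
    "evidence_diff",
    "choice_selective",
    "error_dendrite",
    "null",
)


def substreams(seed: int, names: Sequence[str]) -> dict:
    """Derive named, independent random generators from a single session seed.

    All randomness in a simulated session flows from one integer seed through
    fixed-order spawned child sequences, so that e.g. the stimulus stream is
    unchanged when only the neural noise stream is consumed differently.
    """
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


@dataclass
class TaskConfig:
    """Generative parameters of the puff-based evidence-accumulation task.

    Rates and durations follow the task's standard settings: a total puff
    rate of 2.5 events/s split 1:4 between the minority and majority sides,
    a 200 ms per-side refractory period, cue durations of 1.5 s or 3.8 s
    drawn with probabilities 0.15/0.85, a 200 ms delay, and a 3 s decision
    window.  The trailing timing fields describe the surrounding trial
    phases used to lay trials out on a continuous session timeline.
    """

    total_puff_rate: float = 2.5
    side_ratio: float = 4.0
    min_ipi: float = 0.2
    cue_durations: tuple = (1.5, 3.8)
    cue_duration_probs: tuple = (0.15, 0.85)
    delay: float = 0.2
    decision_window: float = 3.0
    behavior_sample_rate: float = 500.0
    # session timeline phases (pre-cue baseline incl. start tone, reward
    # consumption, and outcome-dependent inter-trial intervals)
    pre_cue: float = 2.5
    consumption: float = 3.0
    iti_correct: float = 3.5
    iti_error: float = 6.0

    def __post_init__(self):
        probs = np.asarray(self.cue_duration_probs, float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("cue_duration_probs must sum to 1")
        if len(probs) != len(self.cue_durations):
            raise ValueError("cue_durations and cue_duration_probs length mismatch")
        for name in ("total_puff_rate", "side_ratio", "min_ipi", "delay",
                     "decision_window", "behavior_sample_rate"):
            if getattr(self, name) < 0 or (name != "total_puff_rate" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be strictly positive")
        if any(d <= 0 for d in self.cue_durations):
            raise ValueError("cue durations must be strictly positive")
        if self.majority_rate > 0 and self.min_ipi >= 1.0 / self.majority_rate:
            warnings.warn(
                "min_ipi exceeds the mean inter-event interval of the majority "
                "side; censoring will dominate the process", stacklevel=2)

    @property
    def majority_rate(self) -> float:
        return self.total_puff_rate * self.side_ratio / (self.side_ratio + 1.0)

    @property
    def minority_rate(self) -> float:
        return self.total_puff_rate / (self.side_ratio + 1.0)

    @property
    def primary_cue_duration(self) -> float:
        """Cue duration with the highest draw probability."""
        return self.cue_durations[int(np.argmax(self.cue_duration_probs))]


@dataclass
class BehaviorParams:
    """Coefficients of the trial-history logistic choice model (logit units).

    P(right) = logistic(b_evidence*s + b_success*h_success +
    b_failure*h_failure + b_bias), with s the scaled signed puff-count
    difference and the h terms the signed previous-trial outcome codes.
    """

    b_evidence: float = 3.0
    b_success: float = 0.3
    b_failure: float = 0.5
    b_bias: float = -0.2

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("behavior coefficients must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.b_evidence, self.b_success, self.b_failure, self.b_bias])


@dataclass
class TrialRecord:
    """One trial: stimulus, choice, outcome, and lick times.

    Puff times are in seconds from cue onset and include the bilateral
    boundary puffs at 0 and ``cue_duration``; ``n_left``/``n_right`` count
    interior (evidence-bearing) puffs only.  Lick and decision times are in
    seconds from trial start (trial start = start of the pre-cue baseline).
    """

    trial_id: int
    cue_duration: float
    puffs_left: np.ndarray
    puffs_right: np.ndarray
    correct_side: str  # 'L' or 'R'
    choice: Optional[str] = None  # 'L', 'R', or None (no decision lick)
    outcome: Optional[str] = None  # 'correct', 'error', or None
    decision_time: Optional[float] = None
    lick_times_left: np.ndarray = field(default_factory=lambda: np.empty(0))
    lick_times_right: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.puffs_left = np.asarray(self.puffs_left, float)
        self.puffs_right = np.asarray(self.puffs_right, float)
        self.lick_times_left = np.asarray(self.lick_times_left, float)
        self.lick_times_right = np.asarray(self.lick_times_right, float)

    def interior_puffs(self, side: str) -> np.ndarray:
        """Puff times on one side excluding the bilateral boundary puffs."""
        t = self.puffs_left if side == "L" else self.puffs_right
        return t[(t > 0.0) & (t < self.cue_duration)]

    @property
    def n_left(self) -> int:
        return int(self.interior_puffs("L").size)

    @property
    def n_right(self) -> int:
        return int(self.interior_puffs("R").size)

    @property
    def evidence(self) -> int:
        """Signed evidence #R - #L (interior puffs)."""
        return self.n_right - self.n_left


@dataclass
class SessionTable:
    """An ordered collection of trials plus session-level metadata."""

    trials: list
    condition: str = "baseline"  # baseline | saline | muscimol
    rng_seed: Optional[int] = None
    task: Optional[TaskConfig] = None

    def __post_init__(self):
        if self.condition not in ("baseline", "saline", "muscimol"):
            raise ValueError(f"unknown condition {self.condition!r}")
        ids = [t.trial_id for t in self.trials]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("trial_ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def decided_trials(self) -> list:
        """Trials on which the animal made a decision lick (all fits use these)."""
        return [t for t in self.trials if t.choice in ("L", "R")]

    def to_frame(self):
        """Flatten the session to a pandas DataFrame (one row per trial)."""
        import pandas as pd

        rows = []
        for t in self.trials:
            rows.append({
                "trial_id": t.trial_id,
                "cue_duration": t.cue_duration,
                "n_left": t.n_left,
                "n_right": t.n_right,
                "correct_side": t.correct_side,
                "choice": t.choice,
                "outcome": t.outcome,
                "decision_time": t.decision_time,
            })
        return pd.DataFrame(rows)


@dataclass
class CellGroundTruth:
    """Ground truth for one simulated cell.

    ``kind`` selects the response class (see CELL_KINDS); ``gain`` converts
    one calcium event into ΔF/F units (its sign matches the kind's suffix);
    ``kinetics_tau`` is the single-exponential calcium decay constant in
    seconds; ``pref_side`` is used by choice-selective cells.
    """

    kind: str
    gain: float = 0.05
    kinetics_tau: float = 1.0
    noise_sd: float = 0.05
    footprint: Optional[np.ndarray] = None  # boolean H x W mask
    pref_side: str = "R"

    def __post_init__(self):
        if self.kind not in CELL_KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kinetics_tau <= 0:
            raise ValueError("kinetics_tau must be positive")
        if self.kind == "ramp-" and self.gain > 0:
            self.gain = -abs(self.gain)
        if self.kind == "ramp+" and self.gain < 0:
            self.gain = abs(self.gain)

    def centroid_px(self) -> Optional[np.ndarray]:
        if self.footprint is None:
            return None
        rc = np.argwhere(self.footprint)
        return rc.mean(axis=0)


@dataclass
class SyncMap:
    """Frame-to-trial synchronization: per-trial frame landmarks.

    ``first_frame`` marks trial start, ``cue_onset_frame`` the first cue
    frame, ``decision_frame`` the decision lick.  Trials tile the session,
    so trial ``i`` ends at ``first_frame[i+1]`` (or the last frame).
    """

    trial_ids: np.ndarray
    first_frame: np.ndarray
    cue_onset_frame: np.ndarray
    decision_frame: np.ndarray

    def __post_init__(self):
        self.trial_ids = np.asarray(self.trial_ids, int)
        self.first_frame = np.asarray(self.first_frame, int)
        self.cue_onset_frame = np.asarray(self.cue_onset_frame, int)
        self.decision_frame = np.asarray(self.decision_frame, int)
        trip = np.stack([self.first_frame, self.cue_onset_frame, self.decision_frame])
        if not np.all(np.diff(trip, axis=0) > 0):
            raise ValueError("sync frames must increase within each trial")
        if not np.all(np.diff(self.first_frame) > 0):
            raise ValueError("sync frames must increase across trials")

    def __len__(self):
        return len(self.trial_ids)

    def trial_end_frame(self, i: int, n_frames: int) -> int:
        return int(self.first_frame[i + 1]) if i + 1 < len(self) else int(n_frames)


@dataclass
class FluorescenceMovie:
    """A grayscale frame stack with acquisition metadata and trial sync."""

    frames: np.ndarray  # (T, H, W)
    frame_rate: float = 28.0
    um_per_px: float = 1.18
    sync: Optional[SyncMap] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape[1:]


@dataclass
class RoiMask:
    """A set of member pixels of one region of interest (0-based row, col)."""

    pixels: np.ndarray  # (N, 2) int array
    source: str = "manual"  # manual | refined | merged
    parent_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, int).reshape(-1, 2)
        if self.pixels.shape[0] == 0:
            raise ValueError("ROI must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def pixel_set(self) -> set:
        return set(map(tuple, self.pixels))

    def centroid_px(self) -> np.ndarray:
        return self.pixels.mean(axis=0)

    def centroid_um(self, um_per_px: float) -> np.ndarray:
        return self.centroid_px() * um_per_px

    def to_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m

    @classmethod
    def from_mask(cls, mask: np.ndarray, **kw) -> "RoiMask":
        return cls(pixels=np.argwhere(mask), **kw)


@dataclass
class CellTraceMatrix:
    """Per-cell time series (cells x frames), raw intensity or ΔF/F."""

    values: np.ndarray
    frame_rate: float
    kind: str = "raw"  # raw | dff
    sync: Optional[SyncMap] = None
    cell_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.kind not in ("raw", "dff"):
            raise ValueError("kind must be 'raw' or 'dff'")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EventTrain:
    """Binarized deconvolved events for one cell."""

    event_frames: np.ndarray
    amplitudes: np.ndarray
    binarization_threshold: float = 0.1
    ar_coefficient: float = 0.95

    def __post_init__(self):
        self.event_frames = np.asarray(self.event_frames, int)
        self.amplitudes = np.asarray(self.amplitudes, float)
        order = np.argsort(self.event_frames)
        self.event_frames = self.event_frames[order]
        self.amplitudes = self.amplitudes[order]
        if not 0.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in (0, 1)")

    @property
    def n_events(self) -> int:
        return self.event_frames.size
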