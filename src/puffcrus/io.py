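"""Round-trip I/O for sessions (CSV), traces (HDF5/CSV), movies
(TIFF/HDF5), and ROI masks (label-image TIFF / pixel-list CSV)."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import tifffile

from .types import (CellTraceMatrix, FluorescenceMovie, RoiMask, SessionTable,
                    SyncMap, TaskConfig, TrialRecord)

__all__ = [
    "session_to_csv", "session_from_csv",
    "traces_to_hdf5", "traces_from_hdf5",
    "movie_to_tiff", "movie_from_tiff",
    "movie_to_hdf5", "movie_from_hdf5",
    "sync_to_csv", "sync_from_csv",
    "rois_to_label_tiff", "rois_from_label_tiff",
    "rois_to_csv", "rois_from_csv",
]


def _join(times: np.ndarray) -> str:
    return ";".join(f"{t:.6f}" for t in np.asarray(times, float))


def _split(s) -> np.ndarray:
    if not isinstance(s, str) or s == "":
        return np.empty(0)
    return np.array([float(x) for x in s.split(";")])


def session_to_csv(session: SessionTable, path) -> None:
    """One row per trial; puff and lick times semicolon-joined seconds."""
    rows = []
    for t in session.trials:
        rows.append({
            "trial_id": t.trial_id,
            "cue_duration": t.cue_duration,
            "puffs_left": _join(t.puffs_left),
            "puffs_right": _join(t.puffs_right),
            "correct_side": t.correct_side,
            "choice": t.choice if t.choice is not None else "",
            "outcome": t.outcome if t.outcome is not None else "",
            "decision_time": t.decision_time,
            "lick_times_left": _join(t.lick_times_left),
            "lick_times_right": _join(t.lick_times_right),
            "condition": session.condition,
            "rng_seed": session.rng_seed,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def session_from_csv(path, task: Optional[TaskConfig] = None) -> SessionTable:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    trials = []
    for _, row in df.iterrows():
        trials.append(TrialRecord(
            trial_id=int(row["trial_id"]),
            cue_duration=float(row["cue_duration"]),
            puffs_left=_split(row["puffs_left"]),
            puffs_right=_split(row["puffs_right"]),
            correct_side=row["correct_side"],
            choice=row["choice"] or None,
            outcome=row["outcome"] or None,
            decision_time=(float(row["decision_time"])
                           if row["decision_time"] != "" else None),
            lick_times_left=_split(row["lick_times_left"]),
            lick_times_right=_split(row["lick_times_right"]),
        ))
    seed = df["rng_seed"].iloc[0]
    return SessionTable(trials=trials, condition=str(df["condition"].iloc[0]),
                        rng_seed=int(seed) if str(seed) != "" else None,
                        task=task)


def _write_sync(group: h5py.Group, sync: SyncMap) -> None:
    g = group.create_group("sync")
    g.create_dataset("trial_ids", data=sync.trial_ids)
    g.create_dataset("first_frame", data=sync.first_frame)
    g.create_dataset("cue_onset_frame", data=sync.cue_onset_frame)
    g.create_dataset("decision_frame", data=sync.decision_frame)


def _read_sync(group: h5py.Group) -> Optional[SyncMap]:
    if "sync" not in group:
        return None
    g = group["sync"]
    return SyncMap(trial_ids=g["trial_ids"][:], first_frame=g["first_frame"][:],
                   cue_onset_frame=g["cue_onset_frame"][:],
                   decision_frame=g["decision_frame"][:])


def traces_to_hdf5(traces: CellTraceMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        d = g.create_dataset(traces.kind, data=traces.values)
        d.attrs["frame_rate"] = traces.frame_rate
        g.create_dataset("cell_ids", data=np.asarray(traces.cell_ids))
        if traces.sync is not None:
            _write_sync(f, traces.sync)


def traces_from_hdf5(path, kind: str = "raw") -> CellTraceMatrix:
    with h5py.File(path, "r") as f:
        g = f["traces"]
        if kind not in g:
            kind = "dff" if "dff" in g else "raw"
        d = g[kind]
        return CellTraceMatrix(values=d[:], frame_rate=float(d.attrs["frame_rate"]),
                               kind=kind, cell_ids=g["cell_ids"][:],
                               sync=_read_sync(f))


def movie_to_tiff(movie: FluorescenceMovie, path) -> None:
    tifffile.imwrite(path, np.asarray(movie.frames, np.float32),
                     metadata={"frame_rate": movie.frame_rate,
                               "um_per_px": movie.um_per_px})


def movie_from_tiff(path, frame_rate: float = 28.0, um_per_px: float = 1.18,
                    sync: Optional[SyncMap] = None) -> FluorescenceMovie:
    frames = tifffile.imread(path)
    return FluorescenceMovie(frames=frames, frame_rate=frame_rate,
                             um_per_px=um_per_px, sync=sync)


def movie_to_hdf5(movie: FluorescenceMovie, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("movie")
        d = g.create_dataset("frames", data=np.asarray(movie.frames, np.float32))
        d.attrs["frame_rate"] = movie.frame_rate
        d.attrs["um_per_px"] = movie.um_per_px
        if movie.sync is not None:
            _write_sync(f, movie.sync)


def movie_from_hdf5(path) -> FluorescenceMovie:
    with h5py.File(path, "r") as f:
        d = f["movie"]["frames"]
        return FluorescenceMovie(frames=d[:], frame_rate=float(d.attrs["frame_rate"]),
                                 um_per_px=float(d.attrs["um_per_px"]),
                                 sync=_read_sync(f))


def sync_to_csv(sync: SyncMap, path) -> None:
    pd.DataFrame({
        "trial_id": sync.trial_ids, "first_frame": sync.first_frame,
        "cue_onset_frame": sync.cue_onset_frame,
        "decision_frame": sync.decision_frame}).to_csv(path, index=False)


def sync_from_csv(path) -> SyncMap:
    df = pd.read_csv(path)
    return SyncMap(trial_ids=df["trial_id"], first_frame=df["first_frame"],
                   cue_onset_frame=df["cue_onset_frame"],
                   decision_frame=df["decision_frame"])


def rois_to_label_tiff(rois: Sequence[RoiMask], shape: Tuple[int, int],
                       path) -> None:
    """16-bit label image; 0 = background, ROI i gets label i+1."""
    if len(rois) > 65535:
        raise ValueError("too many ROIs for a 16-bit label image")
    img = np.zeros(shape, np.uint16)
    for i, roi in enumerate(rois):
        img[roi.pixels[:, 0], roi.pixels[:, 1]] = i + 1
    tifffile.imwrite(path, img)


def rois_from_label_tiff(path) -> List[RoiMask]:
    img = tifffile.imread(path)
    return [RoiMask(np.argwhere(img == lbl), source="manual")
            for lbl in np.unique(img) if lbl != 0]


def rois_to_csv(rois: Sequence[RoiMask], path) -> None:
    rows = [{"roi": i, "row": r, "col": c}
            for i, roi in enumerate(rois) for r, c in roi.pixels]
    pd.DataFrame(rows).to_csv(path, index=False)


def rois_from_csv(path) -> List[RoiMask]:
    df = pd.read_csv(path)
    return [RoiMask(g[["row", "col"]].to_numpy(), source="manual")
            for _, g in df.groupby("roi", sort=True)]
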