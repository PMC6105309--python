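"""Imaging preprocessing: rigid motion correction, seeded ROI refinement,
graph-based ROI merging, trace extraction, ΔF/F, and behavioral-camera
movement indices.

The pipeline mirrors a standard seeded two-photon workflow: template
matching recovers integer-pixel rigid shifts; each manually seeded ROI is
refined by thresholding a correlation image of the movie against the seed
trace; refined ROIs are merged when their traces and pixel sets indicate a
common physiological source; ΔF/F uses a running median-filtered minimum
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.sparse.csgraph

from .simulate.movie import shift_frame
from .types import CellTraceMatrix, FluorescenceMovie, RoiMask

__all__ = [
    "MotionCorrection",
    "motion_correct",
    "RoiRefinement",
    "refine_roi",
    "merge_rois",
    "extract_traces",
    "remove_boundary_pixels",
    "compute_dff",
    "MovementTrace",
    "movement_index",
    "detect_onsets",
]


@dataclass
class MotionCorrection:
    """Motion-corrected movie, per-frame shifts, and the border band width."""

    movie: FluorescenceMovie
    shifts: np.ndarray  # (T, 2) integer (dy, dx) of each frame vs template
    boundary: int       # max |shift|; border pixels within it are invalid

    def valid_mask(self) -> np.ndarray:
        m = np.zeros(self.movie.shape, bool)
        b = self.boundary
        H, W = self.movie.shape
        m[b:H - b or None, b:W - b or None] = True
        return m


def motion_correct(movie: FluorescenceMovie, template: Optional[np.ndarray] = None,
                   search_radius: int = 15, template_frames: int = 500,
                   ) -> MotionCorrection:
    """Template-matching rigid motion correction with integer-pixel shifts.

    Per frame, the (dy, dx) displacement maximizing the circular
    cross-correlation with the template is found within ``search_radius``
    and undone.  The template defaults to the mean of the first
    ``template_frames`` frames.  Shifts at the search-radius edge trigger a
    warning (possible under-correction).
    """
    if movie.n_frames < 1:
        raise ValueError("movie must contain at least one frame")
    frames = np.asarray(movie.frames, float)
    if template is None:
        template = frames[: min(template_frames, len(frames))].mean(axis=0)
    tpl = template - template.mean()
    H, W = tpl.shape
    r = min(search_radius, H // 2 - 1, W // 2 - 1)
    ft_tpl = np.conj(np.fft.rfft2(tpl))
    # admissible wrapped shift indices
    offs = np.r_[0:r + 1, -r:0]
    shifts = np.zeros((len(frames), 2), int)
    corrected = np.empty_like(frames)
    at_edge = False
    for t, frame in enumerate(frames):
        xc = np.fft.irfft2(np.fft.rfft2(frame - frame.mean()) * ft_tpl, s=(H, W))
        window = xc[np.ix_(offs % H, offs % W)]
        iy, ix = np.unravel_index(np.argmax(window), window.shape)
        dy, dx = int(offs[iy]), int(offs[ix])
        shifts[t] = (dy, dx)
        at_edge |= max(abs(dy), abs(dx)) >= r
        fill = float(np.median(frame))
        corrected[t] = shift_frame(frame, -dy, -dx, fill) if (dy or dx) else frame
    if at_edge:
        warnings.warn("shift at search-radius edge; possible under-correction",
                      stacklevel=2)
    boundary = int(np.abs(shifts).max())
    out = FluorescenceMovie(frames=corrected, frame_rate=movie.frame_rate,
                            um_per_px=movie.um_per_px, sync=movie.sync)
    return MotionCorrection(movie=out, shifts=shifts, boundary=boundary)


@dataclass
class RoiRefinement:
    """Outcome of seeded ROI refinement (accepted ROI or a rejection reason)."""

    roi: Optional[RoiMask]
    accepted: bool
    reason: str = ""
    correlation_image: Optional[np.ndarray] = None


def _correlation_image(frames: np.ndarray, seed_trace: np.ndarray) -> np.ndarray:
    T = frames.shape[0]
    X = frames.reshape(T, -1)
    Xc = X - X.mean(axis=0)
    zc = seed_trace - seed_trace.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (zc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc * zc[:, None]).sum(axis=0) / denom
    corr[~np.isfinite(corr)] = 0.0
    return corr.reshape(frames.shape[1:])


def refine_roi(movie: FluorescenceMovie, manual_roi: RoiMask,
               median_size: int = 3, z_threshold: float = 2.0,
               size_bounds: Tuple[float, float] = (0.5, 3.5)) -> RoiRefinement:
    """Refine a manual ROI seed from the movie's pixelwise correlation structure.

    The seed trace (per-frame mean over manual pixels) is correlated with
    every pixel's time series; the correlation image is median filtered,
    thresholded at mean + ``z_threshold`` standard deviations (statistics
    over the whole filtered image), and 8-connected components are
    extracted.  The component overlapping the manual ROI most becomes the
    refined ROI, rejected if its size falls outside ``size_bounds`` times
    the manual pixel count.
    """
    frames = np.asarray(movie.frames, float)
    seed = frames[:, manual_roi.pixels[:, 0], manual_roi.pixels[:, 1]].mean(axis=1)
    cimg = _correlation_image(frames, seed)
    filt = scipy.ndimage.median_filter(cimg, size=median_size)
    thr = filt.mean() + z_threshold * filt.std()
    labels, n_comp = scipy.ndimage.label(filt > thr, structure=np.ones((3, 3)))
    if n_comp == 0:
        return RoiRefinement(None, False, "no supra-threshold component", cimg)
    manual_mask = manual_roi.to_mask(frames.shape[1:])
    overlaps = scipy.ndimage.sum_labels(manual_mask, labels,
                                        index=np.arange(1, n_comp + 1))
    best = int(np.argmax(overlaps)) + 1
    if overlaps[best - 1] == 0:
        return RoiRefinement(None, False, "no component overlaps the manual ROI",
                             cimg)
    size = int((labels == best).sum())
    lo, hi = size_bounds
    if not lo * manual_roi.n_pixels <= size <= hi * manual_roi.n_pixels:
        return RoiRefinement(
            None, False,
            f"component size {size} outside [{lo}, {hi}] x manual size", cimg)
    roi = RoiMask.from_mask(labels == best, source="refined")
    return RoiRefinement(roi, True, "", cimg)


def extract_traces(movie: FluorescenceMovie, rois: Sequence[RoiMask]
                   ) -> CellTraceMatrix:
    """Per-ROI raw traces: arithmetic mean of member pixels per frame."""
    if len(rois) == 0:
        raise ValueError("no ROIs to extract")
    frames = np.asarray(movie.frames, float)
    values = np.stack([
        frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
        for roi in rois])
    return CellTraceMatrix(values=values, frame_rate=movie.frame_rate,
                           kind="raw", sync=movie.sync)


def remove_boundary_pixels(rois: Sequence[RoiMask], boundary: int,
                           shape: Tuple[int, int]
                           ) -> Tuple[List[RoiMask], List[int]]:
    """Strip pixels within the motion boundary band from every ROI.

    ROIs left empty are dropped; their indices are returned alongside the
    surviving masks.
    """
    H, W = shape
    kept, dropped = [], []
    for i, roi in enumerate(rois):
        p = roi.pixels
        ok = ((p[:, 0] >= boundary) & (p[:, 0] < H - boundary)
              & (p[:, 1] >= boundary) & (p[:, 1] < W - boundary))
        if ok.any():
            kept.append(RoiMask(p[ok], source=roi.source,
                                parent_ids=list(roi.parent_ids)))
        else:
            dropped.append(i)
    return kept, dropped


def _pair_containment(a: RoiMask, b: RoiMask) -> float:
    inter = len(a.pixel_set() & b.pixel_set())
    return max(inter / a.n_pixels, inter / b.n_pixels)


def _merge_pair(rois: list, traces: np.ndarray, i: int, j: int,
                movie: Optional[FluorescenceMovie]):
    union = np.unique(np.vstack([rois[i].pixels, rois[j].pixels]), axis=0)
    parents = sorted(set(rois[i].parent_ids) | set(rois[j].parent_ids) | {i, j})
    merged = RoiMask(union, source="merged", parent_ids=parents)
    if movie is not None:
        frames = np.asarray(movie.frames, float)
        tr = frames[:, union[:, 0], union[:, 1]].mean(axis=1)
    else:  # pixel-count weighted mean approximates the union-pixel mean
        na, nb = rois[i].n_pixels, rois[j].n_pixels
        tr = (na * traces[i] + nb * traces[j]) / (na + nb)
    keep = [k for k in range(len(rois)) if k not in (i, j)]
    new_rois = [rois[k] for k in keep] + [merged]
    new_traces = np.vstack([traces[keep], tr[None]]) if keep else tr[None]
    return new_rois, new_traces


def merge_rois(rois: Sequence[RoiMask], raw_traces: CellTraceMatrix,
               movie: Optional[FluorescenceMovie] = None,
               corr_threshold: float = 0.5, containment: float = 0.5,
               high_corr: float = 0.8, max_dist_um: float = 5.0,
               um_per_px: Optional[float] = None,
               ) -> Tuple[List[RoiMask], CellTraceMatrix]:
    """Merge ROIs that correspond to a single physiological source.

    Stage 1: build an undirected graph with edges where trace correlation
    exceeds ``corr_threshold``; within each connected component, merge any
    pair where more than ``containment`` of either ROI's pixels lies inside
    the other.  Stage 2: merge any pair whose correlation exceeds
    ``high_corr`` with centroids within ``max_dist_um``.  Pairs are
    processed in descending correlation order and the two stages are
    repeated to a fixpoint; merging unions pixel sets and recomputes traces
    (from ``movie`` when given, else as a pixel-count weighted mean).
    """
    if um_per_px is None:
        um_per_px = movie.um_per_px if movie is not None else 1.18
        if movie is None:
            warnings.warn("um_per_px metadata absent; assuming 1.18 um/px",
                          stacklevel=2)
    rois = list(rois)
    traces = np.atleast_2d(np.asarray(raw_traces.values, float)).copy()

    def corrcoef(tr):
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(tr)
        return np.nan_to_num(np.atleast_2d(c), nan=0.0)

    changed = True
    while changed:
        changed = False
        n = len(rois)
        if n < 2:
            break
        # stage 1: correlation graph + containment merges within components
        C = corrcoef(traces)
        adj = (C > corr_threshold) & ~np.eye(n, dtype=bool)
        n_comp, labels = scipy.sparse.csgraph.connected_components(adj,
                                                                   directed=False)
        pairs = [(C[i, j], i, j) for i in range(n) for j in range(i + 1, n)
                 if labels[i] == labels[j] and adj[i, j]]
        for _, i, j in sorted(pairs, reverse=True):
            if _pair_containment(rois[i], rois[j]) > containment:
                rois, traces = _merge_pair(rois, traces, i, j, movie)
                changed = True
                break
        if changed:
            continue
        # stage 2: high-correlation near-neighbor merges
        pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if C[i, j] > high_corr:
                    d = np.linalg.norm((rois[i].centroid_px()
                                        - rois[j].centroid_px()) * um_per_px)
                    if d < max_dist_um:
                        pairs.append((C[i, j], i, j))
        for _, i, j in sorted(pairs, reverse=True):
            rois, traces = _merge_pair(rois, traces, i, j, movie)
            changed = True
            break
    out = CellTraceMatrix(values=traces, frame_rate=raw_traces.frame_rate,
                          kind=raw_traces.kind, sync=raw_traces.sync)
    return rois, out


def compute_dff(raw: CellTraceMatrix | np.ndarray, frame_rate: Optional[float] = None,
                baseline_window: float = 12.0, median_kernel: float = 1.0):
    """ΔF/F with a sliding median-filtered minimum baseline.

    F0(t) is the minimum, over the ``baseline_window`` seconds preceding
    (and including) each time point, of the trace median-filtered with a
    ``median_kernel``-second kernel; ΔF/F = (F - F0)/F0.  Shorter prefixes
    truncate the window to the available history.  Raw traces must be
    strictly positive intensities (F0 <= 0 is an error).
    """
    if isinstance(raw, CellTraceMatrix):
        values = np.stack([
            compute_dff(row, raw.frame_rate, baseline_window, median_kernel)
            for row in raw.values])
        return CellTraceMatrix(values=values, frame_rate=raw.frame_rate,
                               kind="dff", sync=raw.sync, cell_ids=raw.cell_ids)
    if frame_rate is None:
        raise ValueError("frame_rate required for array input")
    trace = np.asarray(raw, float)
    k = max(int(round(median_kernel * frame_rate)) | 1, 1)  # odd kernel
    filt = scipy.ndimage.median_filter(trace, size=k, mode="nearest")
    w = max(int(round(baseline_window * frame_rate)), 1)
    f0 = pd.Series(filt).rolling(w, min_periods=1).min().to_numpy()
    if np.any(f0 <= 0):
        raise ValueError("baseline F0 <= 0; traces must be strictly positive")
    return (trace - f0) / f0


@dataclass
class MovementTrace:
    """A normalized [0, 1] movement index for one behavioral feature."""

    feature: str
    values: np.ndarray
    sample_rate: float = 30.0
    degenerate: bool = False  # constant input; values are all zero


_DERIVATIVE_FEATURES = ("nose", "whiskers_L", "whiskers_R", "paw_L", "paw_R")


def _normalize01(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    span = np.ptp(x)
    if span == 0:
        return np.zeros_like(x), True
    return (x - x.min()) / span, False


def movement_index(camera_movie: FluorescenceMovie, roi: RoiMask, feature: str,
                   fiducial_roi: Optional[RoiMask] = None,
                   baseline_kernel: float = 0.5) -> MovementTrace:
    """Movement index of one measurement ROI in a behavioral-camera movie.

    Mouth/lick features use the absolute deviation of the normalized
    mean-subtracted ROI trace from a median-filtered (``baseline_kernel``
    seconds) drifting baseline; the remaining features use the absolute
    value of the trace derivative.  Both are normalized from 0 to 1.
    Brightness deviations are divided out by a fiducial ROI trace when one
    is provided.  Constant traces return an all-zero index with the
    ``degenerate`` flag set.
    """
    frames = np.asarray(camera_movie.frames, float)
    H, W = frames.shape[1:]
    if (roi.pixels[:, 0].max() >= H) or (roi.pixels[:, 1].max() >= W):
        raise ValueError("measurement ROI outside camera frame")
    trace = frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    if fiducial_roi is not None:
        fid = frames[:, fiducial_roi.pixels[:, 0], fiducial_roi.pixels[:, 1]].mean(axis=1)
        if np.any(fid <= 0):
            raise ValueError("fiducial trace must be strictly positive")
        trace = trace / (fid / fid.mean())
    rate = camera_movie.frame_rate
    if feature in ("mouth", "lick"):
        x, degen = _normalize01(trace - trace.mean())
        if degen:
            return MovementTrace(feature, np.zeros_like(trace), rate, True)
        k = max(int(round(baseline_kernel * rate)) | 1, 1)
        baseline = scipy.ndimage.median_filter(x, size=k, mode="nearest")
        idx, degen = _normalize01(np.abs(x - baseline))
    elif feature in _DERIVATIVE_FEATURES:
        deriv = np.abs(np.diff(trace, prepend=trace[0]))
        idx, degen = _normalize01(deriv)
    else:
        raise ValueError(f"unknown feature {feature!r}")
    return MovementTrace(feature, idx, rate, degen)


def detect_onsets(values: np.ndarray, z: float = 2.5) -> np.ndarray:
    """Frames where a trace first exceeds mean + ``z`` standard deviations.

    Returns the upward-crossing frames (a sample at/above threshold whose
    predecessor is below it).
    """
    x = np.asarray(values, float)
    thr = x.mean() + z * x.std()
    above = x >= thr
    onsets = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    return onsets
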