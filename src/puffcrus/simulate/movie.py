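"""Pixel-level rendering of synthetic two-photon movies.

A movie frame is background + sum of footprint x trace contributions plus
Gaussian pixel noise, optionally jittered by an integer-pixel random-walk
rigid motion trajectory (returned as ground truth so motion correction can
be validated against planted shifts).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..types import CellTraceMatrix, FluorescenceMovie

__all__ = ["make_footprints", "render_movie", "shift_frame"]


def make_footprints(n_cells: int, shape: Tuple[int, int],
                    rng: np.random.Generator, radius: int = 3,
                    margin: int = 6) -> List[np.ndarray]:
    """Place ``n_cells`` disk-shaped, non-overlapping footprints on a grid.

    Cells are laid out on a jittered grid with at least ``margin`` pixels
    from the frame border so that small rigid shifts keep them in view.
    The pitch leaves a >=3 px gap between neighbors even after jitter, so
    a 3x3 median filter cannot bridge adjacent footprints.
    """
    H, W = shape
    pitch = 2 * radius + 5
    rows = np.arange(margin + radius, H - margin - radius + 1, pitch)
    cols = np.arange(margin + radius, W - margin - radius + 1, pitch)
    sites = [(r, c) for r in rows for c in cols]
    if len(sites) < n_cells:
        raise ValueError(f"field of view too small for {n_cells} footprints")
    idx = rng.choice(len(sites), size=n_cells, replace=False)
    yy, xx = np.mgrid[0:H, 0:W]
    footprints = []
    for i in idx:
        r, c = sites[i]
        r += int(rng.integers(-1, 2))
        c += int(rng.integers(-1, 2))
        footprints.append((yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2)
    return footprints


def shift_frame(frame: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Rigidly translate a frame by integer pixels, filling vacated pixels."""
    out = np.full_like(frame, fill)
    H, W = frame.shape
    ys_src = slice(max(0, -dy), min(H, H - dy))
    xs_src = slice(max(0, -dx), min(W, W - dx))
    ys_dst = slice(max(0, dy), min(H, H + dy))
    xs_dst = slice(max(0, dx), min(W, W + dx))
    out[ys_dst, xs_dst] = frame[ys_src, xs_src]
    return out


def render_movie(footprints: Sequence[np.ndarray], traces: CellTraceMatrix,
                 background: float = 100.0, noise_sd: float = 0.0,
                 motion_amplitude_px: int = 0,
                 rng: Optional[np.random.Generator] = None,
                 um_per_px: float = 1.18, cell_baseline: float = 0.0,
                 ) -> Tuple[FluorescenceMovie, np.ndarray]:
    """Render traces into a movie; returns (movie, planted shifts).

    ``frame(t) = background + sum_i footprint_i * (cell_baseline +
    trace_i(t)) + noise``, then shifted by a random-walk trajectory of
    integer-pixel steps clipped to ``motion_amplitude_px``.  The first
    frame always has zero shift.  A non-zero ``cell_baseline`` gives cells
    a resting fluorescence (static anatomical structure), which template
    matching needs on frames where all cells are silent.
    """
    rng = np.random.default_rng() if rng is None else rng
    fps = [np.asarray(f, bool) for f in footprints]
    if len(fps) != traces.n_cells:
        raise ValueError("one footprint per trace row is required")
    shape = fps[0].shape
    for f in fps:
        if f.shape != shape:
            raise ValueError("footprints must share the field-of-view shape")
        if not f.any():
            raise ValueError("empty footprint")
    T = traces.n_frames
    frames = np.full((T,) + shape, background, np.float32)
    for f, tr in zip(fps, traces.values):
        frames[:, f] += (cell_baseline + tr[:, None]).astype(np.float32)
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    shifts = np.zeros((T, 2), int)
    if motion_amplitude_px > 0:
        steps = rng.integers(-1, 2, size=(T, 2))
        steps[0] = 0
        shifts = np.clip(np.cumsum(steps, axis=0), -motion_amplitude_px,
                         motion_amplitude_px)
        for t in range(T):
            dy, dx = shifts[t]
            if dy or dx:
                frames[t] = shift_frame(frames[t], dy, dx, background)
    movie = FluorescenceMovie(frames=frames, frame_rate=traces.frame_rate,
                              um_per_px=um_per_px, sync=traces.sync)
    return movie, shifts
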