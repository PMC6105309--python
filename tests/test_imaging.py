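"""Imaging pipeline: motion correction, ROI refinement and merging, ΔF/F
against a brute-force oracle, and movement indices."""

import numpy as np
import pytest

from puffcrus import BehaviorParams, TaskConfig
from puffcrus.imaging import (compute_dff, detect_onsets, extract_traces,
                              merge_rois, motion_correct, movement_index,
                              refine_roi, remove_boundary_pixels)
from puffcrus.simulate import (make_footprints, make_soma_population,
                               render_movie, simulate_session,
                               synthesize_soma_activity)
from puffcrus.types import CellTraceMatrix, FluorescenceMovie, RoiMask

FR = 28.0


@pytest.fixture(scope="module")
def rendered():
    """A small rendered movie with planted footprints and a clean template."""
    session = simulate_session(TaskConfig(), BehaviorParams(), 8, rng_seed=31)
    cells = make_soma_population(
        6, np.random.default_rng(0), gain=1.0, noise_sd=0.0,
        proportions={"ramp+": 0.5, "ramp-": 0.3, "evidence_L": 0.2})
    traces = synthesize_soma_activity(cells, session,
                                      rng=np.random.default_rng(1))
    fps = make_footprints(6, (56, 56), np.random.default_rng(2))
    clean, _ = render_movie(fps, traces, cell_baseline=20.0)
    return fps, traces, clean


# ------------------------------------------------------- motion correction

def test_zero_motion_movie_yields_zero_shifts(rendered):
    _, _, clean = rendered
    mc = motion_correct(clean)
    assert np.all(mc.shifts == 0)
    assert mc.boundary == 0
    assert np.array_equal(mc.movie.frames, clean.frames)


def test_planted_integer_shifts_recovered_exactly(rendered):
    fps, traces, clean = rendered
    moved, shifts = render_movie(fps, traces, cell_baseline=20.0,
                                 motion_amplitude_px=3,
                                 rng=np.random.default_rng(3))
    mc = motion_correct(moved, template=clean.frames.mean(axis=0))
    assert np.array_equal(mc.shifts, shifts)
    assert mc.boundary == np.abs(shifts).max()


def test_boundary_pixels_removed_from_rois(rendered):
    fps, _, _ = rendered
    rois = [RoiMask.from_mask(f) for f in fps]
    border = RoiMask(np.array([[0, 0], [1, 1], [30, 30]]))
    kept, dropped = remove_boundary_pixels(rois + [border], boundary=3,
                                           shape=(56, 56))
    assert len(kept) == len(rois) + 1
    assert all((r.pixels >= 3).all() and (r.pixels <= 52).all() for r in kept)
    only_border = RoiMask(np.array([[0, 0], [1, 1]]))
    kept2, dropped2 = remove_boundary_pixels([only_border], 3, (56, 56))
    assert kept2 == [] and dropped2 == [0]


# ----------------------------------------------------------- ROI refinement

def test_refine_recovers_planted_footprint(rendered):
    fps, traces, clean = rendered
    noisy = FluorescenceMovie(
        frames=clean.frames + np.random.default_rng(4).normal(
            0, 1.0, clean.frames.shape).astype(np.float32),
        frame_rate=FR, sync=clean.sync)
    true_px = np.argwhere(fps[0])
    manual = RoiMask(true_px[: int(0.6 * len(true_px))])
    out = refine_roi(noisy, manual)
    assert out.accepted
    got = out.roi.pixel_set()
    want = set(map(tuple, true_px))
    jaccard = len(got & want) / len(got | want)
    assert jaccard >= 0.5


def test_pure_noise_movie_rejected():
    """A thin (1-px wide, dendrite-like) seed on pure noise leaves no
    supra-threshold component once the median filter removes the seed's own
    correlation artifact."""
    rng = np.random.default_rng(5)
    movie = FluorescenceMovie(frames=rng.normal(0, 1, (400, 32, 32)),
                              frame_rate=FR)
    manual = RoiMask(np.array([[15, c] for c in range(8, 24)]))
    out = refine_roi(movie, manual)
    assert not out.accepted


def test_size_gate_rejects_small_components(rendered):
    """A component smaller than half the manual pixel count is excluded."""
    fps, traces, clean = rendered
    true_px = np.argwhere(fps[0])
    # manual ROI ~3x larger than the true footprint -> component < 0.5x manual
    r, c = true_px.mean(axis=0).astype(int)
    yy, xx = np.mgrid[0:56, 0:56]
    big = (yy - r) ** 2 + (xx - c) ** 2 <= 36
    out = refine_roi(clean, RoiMask.from_mask(big))
    assert not out.accepted
    assert "size" in out.reason


def test_refinement_invariant_to_affine_intensity_rescaling(rendered):
    fps, traces, clean = rendered
    manual = RoiMask(np.argwhere(fps[1])[:15])
    a = refine_roi(clean, manual)
    scaled = FluorescenceMovie(frames=clean.frames * 3.0 + 7.0, frame_rate=FR)
    b = refine_roi(scaled, manual)
    assert a.accepted == b.accepted
    assert a.roi.pixel_set() == b.roi.pixel_set()


# ---------------------------------------------------------------- merging

def _corr_traces(rng, corrs, n=2000):
    base = rng.normal(size=n)
    rows = [base]
    for c in corrs:
        rows.append(c * base + np.sqrt(1 - c ** 2) * rng.normal(size=n))
    return np.stack(rows)


def test_disjoint_uncorrelated_rois_unchanged():
    rng = np.random.default_rng(6)
    tr = np.stack([rng.normal(size=1000), rng.normal(size=1000)])
    rois = [RoiMask(np.array([[5, c] for c in range(5)])),
            RoiMask(np.array([[20, c] for c in range(5)]))]
    merged, out = merge_rois(rois, CellTraceMatrix(tr, FR), um_per_px=1.18)
    assert len(merged) == 2
    assert all(r.source == "manual" for r in merged)


def test_high_correlation_nearby_rois_merge():
    """Correlation 0.9 with centroids ~3 um apart triggers the stage-2 merge."""
    rng = np.random.default_rng(7)
    tr = _corr_traces(rng, [0.95])  # realized corr > 0.8
    rois = [RoiMask(np.array([[10, c] for c in range(4)])),
            RoiMask(np.array([[12, c] for c in range(4)]))]  # 2 px ~ 2.4 um
    merged, _ = merge_rois(rois, CellTraceMatrix(tr, FR), um_per_px=1.18)
    assert len(merged) == 1 and merged[0].source == "merged"
    assert merged[0].n_pixels == 8


def test_high_correlation_distant_rois_do_not_merge():
    rng = np.random.default_rng(8)
    tr = _corr_traces(rng, [0.95])
    rois = [RoiMask(np.array([[5, c] for c in range(4)])),
            RoiMask(np.array([[40, c] for c in range(4)]))]  # ~41 um apart
    merged, _ = merge_rois(rois, CellTraceMatrix(tr, FR), um_per_px=1.18)
    assert len(merged) == 2


def test_containment_chain_merges_only_contained_pair():
    """Hand-traced case: chain A-B-C with trace correlations ~0.6 each and
    containments 60% (A,B) and 10% (A,C): only the A,B pair merges."""
    rng = np.random.default_rng(9)
    base = rng.normal(size=4000)
    mk = lambda c: c * base + np.sqrt(1 - c ** 2) * rng.normal(size=4000)
    tr = np.stack([base, mk(0.62), mk(0.62)])
    C = np.corrcoef(tr)
    assert 0.5 < C[0, 1] < 0.8 and 0.5 < C[0, 2] < 0.8  # stage-1 edges only
    A = RoiMask(np.array([[10, c] for c in range(10)]))
    B = RoiMask(np.array([[10, c] for c in range(4, 10)]
                         + [[11, c] for c in range(4)]))   # 6/10 inside A
    Cr = RoiMask(np.array([[40, c] for c in range(9)] + [[10, 0]]))  # 1/10
    merged, _ = merge_rois([A, B, Cr], CellTraceMatrix(tr, FR), um_per_px=1.18)
    assert len(merged) == 2
    srcs = sorted(r.source for r in merged)
    assert srcs == ["manual", "merged"]
    assert {r.n_pixels for r in merged} == {10, 14}  # A|B union (16-2 overlap) and C


def test_merge_is_idempotent():
    rng = np.random.default_rng(10)
    tr = _corr_traces(rng, [0.95, 0.1])
    rois = [RoiMask(np.array([[10, c] for c in range(4)])),
            RoiMask(np.array([[11, c] for c in range(4)])),
            RoiMask(np.array([[40, c] for c in range(4)]))]
    merged, out = merge_rois(rois, CellTraceMatrix(tr, FR), um_per_px=1.18)
    again, out2 = merge_rois(merged, out, um_per_px=1.18)
    assert len(again) == len(merged)
    assert [r.pixel_set() for r in again] == [r.pixel_set() for r in merged]


# ------------------------------------------------------------------- ΔF/F

def dff_oracle(trace, fr, window_s=12.0, kernel_s=1.0):
    """Brute-force rolling median + trailing min baseline."""
    k = max(int(round(kernel_s * fr)) | 1, 1)
    half = k // 2
    n = trace.size
    padded = np.r_[np.full(half, trace[0]), trace, np.full(half, trace[-1])]
    filt = np.array([np.median(padded[i:i + k]) for i in range(n)])
    w = int(round(window_s * fr))
    f0 = np.array([filt[max(0, i - w + 1): i + 1].min() for i in range(n)])
    return (trace - f0) / f0


def test_constant_trace_gives_zero_dff():
    assert np.allclose(compute_dff(np.full(600, 3.0), FR), 0.0)


def test_transient_dff_matches_brute_force_oracle():
    """A 0.3 s unit transient on a unit baseline: the 1 s median kernel
    absorbs it, so F0 stays ~1 and peak ΔF/F ~ 1."""
    rng = np.random.default_rng(11)
    trace = np.ones(800) + 0.01 * rng.standard_normal(800)
    k = int(0.3 * FR)
    trace[400:400 + k] += 1.0
    got = compute_dff(trace, FR)
    want = dff_oracle(trace, FR)
    assert np.allclose(got, want)
    assert got[400 + k // 2] == pytest.approx(1.0, abs=0.05)
    assert abs(got[350]) < 0.05


def test_drifting_trace_baseline_tracks_with_lag():
    t = np.arange(2000) / FR
    trace = 1.0 + 0.01 * t  # slow upward drift
    got = compute_dff(trace, FR)
    # F0 lags by at most the 12 s window: dF/F bounded by drift over 12 s
    assert got.max() <= 0.01 * 12.0 / 1.0 + 1e-6
    assert np.all(got >= -1e-9)


def test_nonpositive_baseline_rejected():
    with pytest.raises(ValueError):
        compute_dff(np.linspace(-1, 1, 500), FR)


# ------------------------------------------------------- movement indices

def _camera(frames):
    return FluorescenceMovie(frames=frames, frame_rate=30.0)


def test_static_movie_gives_zero_index():
    movie = _camera(np.full((200, 20, 20), 7.0))
    roi = RoiMask(np.array([[5, 5], [5, 6]]))
    for feature in ("mouth", "nose"):
        mt = movement_index(movie, roi, feature)
        assert mt.degenerate and np.all(mt.values == 0)


def test_step_change_spikes_derivative_index_at_step_frame():
    frames = np.full((300, 16, 16), 1.0)
    frames[150:] += 5.0
    movie = _camera(frames)
    roi = RoiMask(np.array([[8, 8]]))
    mt = movement_index(movie, roi, "nose")
    # finite-difference oracle: |diff| of the ROI trace, normalized
    trace = frames[:, 8, 8]
    oracle = np.abs(np.diff(trace, prepend=trace[0]))
    oracle = oracle / oracle.max()
    assert np.allclose(mt.values, oracle)
    assert mt.values.argmax() == 150 and mt.values[150] == 1.0


def test_planted_onset_detected_at_2p5_sd():
    rng = np.random.default_rng(12)
    x = rng.normal(0, 1.0, 1000)
    x[400:404] += 5.0 * x.std()
    onsets = detect_onsets(x, z=2.5)
    assert 400 in onsets


def test_fiducial_normalization_divides_out_brightness():
    rng = np.random.default_rng(13)
    bright = 1.0 + 0.2 * np.sin(np.arange(400) / 20.0)
    frames = np.ones((400, 10, 10)) * bright[:, None, None]
    frames[:, 2, 2] *= 1.0 + 0.5 * (np.arange(400) == 200)
    movie = _camera(frames)
    roi = RoiMask(np.array([[2, 2]]))
    fid = RoiMask(np.array([[8, 8]]))
    mt = movement_index(movie, roi, "nose", fiducial_roi=fid)
    assert mt.values.argmax() == 200
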