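"""Somatic per-cell statistics: modulation index, choice selectivity,
puff-triggered responses, the evidence linear model, and baseline return."""

import numpy as np
import pytest

from puffcrus import BehaviorParams, CellGroundTruth, TaskConfig
from puffcrus.simulate import (make_soma_population, simulate_session,
                               synthesize_soma_activity)
from puffcrus.somatic import (baseline_return_test, choice_selectivity,
                              compare_category_rates, evidence_linear_model,
                              modulation_fraction_test, modulation_index,
                              puff_triggered_response, window_means)
from tests.conftest import make_session, make_trial

FR = 28.0


@pytest.fixture(scope="module")
def session():
    return simulate_session(TaskConfig(), BehaviorParams(2.5, 0.2, 0.3, 0.0),
                            150, rng_seed=77)


# --------------------------------------------------------- modulation index

def test_linear_trace_has_unit_modulation():
    assert modulation_index(np.arange(10.0)) == pytest.approx(1.0)
    assert modulation_index(-np.arange(10.0)) == pytest.approx(-1.0)


def test_time_symmetric_trace_has_zero_modulation():
    assert modulation_index(np.array([0.0, 1.0, 0.0, 1.0, 0.0])) == pytest.approx(0.0, abs=1e-12)


def test_degenerate_windows_return_nan():
    assert np.isnan(modulation_index(np.full(20, 2.0)))  # zero variance
    assert np.isnan(modulation_index(np.array([1.0, 2.0])))  # too short


def test_modulation_matches_direct_covariance_formula():
    rng = np.random.default_rng(0)
    x = np.arange(200) / 50.0 + rng.normal(0, 0.5, 200)
    t = np.arange(200.0)
    direct = ((x - x.mean()) * (t - t.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum())
    assert modulation_index(x) == pytest.approx(direct, abs=1e-12)


def test_modulation_invariant_to_sign_preserving_affine_transform():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100).cumsum()
    assert modulation_index(3.0 * x + 5.0) == pytest.approx(
        modulation_index(x), abs=1e-12)


def test_all_null_population_fraction_near_half():
    rng = np.random.default_rng(2)
    r_cue = rng.uniform(-0.5, 0.5, 1000)
    r_pre = rng.uniform(-0.5, 0.5, 1000)
    res = modulation_fraction_test(r_cue, r_pre, n_boot=1000,
                                   rng=np.random.default_rng(3))
    assert res.fraction == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(1000))
    assert res.ci[0] < 0.5 < res.ci[1]


def test_small_population_flagged_unreliable():
    res = modulation_fraction_test(np.ones(5), np.zeros(5), n_boot=100,
                                   rng=np.random.default_rng(4))
    assert not res.reliable


# -------------------------------------------------------- choice selectivity

def test_null_cells_nominal_false_positive_rate(session):
    cells = [CellGroundTruth(kind="null") for _ in range(400)]
    tr = synthesize_soma_activity(cells, session, rng=np.random.default_rng(5))
    res = choice_selectivity(tr, session)
    rate = res["significant"].mean()
    assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / 400))


def test_planted_choice_cells_detected_and_ramps_same_direction(session):
    cells = ([CellGroundTruth(kind="choice_selective", pref_side="R",
                              noise_sd=0.02) for _ in range(40)]
             + [CellGroundTruth(kind="ramp+", noise_sd=0.02)
                for _ in range(20)])
    tr = synthesize_soma_activity(cells, session, rng=np.random.default_rng(6))
    res = choice_selectivity(tr, session)
    assert res["significant"][:40].mean() > 0.95
    # ramp cells rise regardless of choice: same-direction classification
    assert (res["direction"][40:] == "same").mean() > 0.9


# ---------------------------------------------------- puff-triggered average

def test_half_decay_of_planted_exponential_kernel():
    """An exponential response with tau=0.586 s has t_half = tau*ln2 ~ 406 ms."""
    tau = 0.586
    task = TaskConfig()
    trials = [make_trial(i, 1, 8, "R") for i in range(6)]
    session = make_session(trials, task=task)
    cell = CellGroundTruth(kind="evidence_L", kinetics_tau=tau, noise_sd=0.0,
                           gain=1.0)
    tr = synthesize_soma_activity([cell], session, frame_rate=FR,
                                  sampling="expected")
    res = puff_triggered_response(tr.values[0], session, tr, side="L")
    assert res.ok
    assert res.t_half_decay == pytest.approx(tau * np.log(2), abs=0.03)


def test_triangular_response_half_decay_matches_hand_geometry():
    """Synthetic trace rising 0->1 over 0.25 s then falling linearly to 0
    over 1 s: the half point lies 0.5 s after the peak."""
    task = TaskConfig()
    trials = [make_trial(i, 1, 8, "R") for i in range(6)]
    session = make_session(trials, task=task)
    cells = [CellGroundTruth(kind="null", noise_sd=0.0)]
    tr = synthesize_soma_activity(cells, session, frame_rate=FR,
                                  sampling="expected")
    trace = np.zeros(tr.n_frames)
    rise, fall = int(0.25 * FR), int(1.0 * FR)
    for i in range(len(trials)):
        f = int(tr.sync.cue_onset_frame[i]) + int(trials[i].puffs_left[1] * FR)
        trace[f:f + rise] = np.linspace(0, 1, rise, endpoint=False)
        trace[f + rise:f + rise + fall] = np.linspace(1, 0, fall)
    res = puff_triggered_response(trace, session, tr, side="L")
    assert res.ok
    assert res.t_half_decay == pytest.approx(0.5, abs=2.0 / FR)


def test_flat_response_flagged(session):
    tr = synthesize_soma_activity([CellGroundTruth(kind="null", noise_sd=0.0)],
                                  session, sampling="expected")
    res = puff_triggered_response(np.zeros(tr.n_frames), session, tr, side="L")
    assert not res.ok and not np.isfinite(res.t_half_decay)


def test_too_few_qualifying_puffs_reported(session):
    tr = synthesize_soma_activity([CellGroundTruth(kind="null")], session,
                                  rng=np.random.default_rng(7))
    res = puff_triggered_response(tr.values[0], session, tr, side="L",
                                  max_puffs=1)
    if not res.ok:
        assert "few" in res.reason


# ------------------------------------------------------ evidence linear model

def test_planted_left_evidence_cells_categorized(session):
    """Cells with fluorescence = 0.1*n_L + noise land in +L with high power."""
    idx = [i for i, t in enumerate(session.trials)
           if np.isclose(t.cue_duration, 3.8)]
    cells = [CellGroundTruth(kind="null", noise_sd=0.05) for _ in range(60)]
    tr = synthesize_soma_activity(cells, session, rng=np.random.default_rng(8))
    # plant the dependence directly in the pre-decision window
    n_l = {i: session.trials[i].n_left for i in range(len(session.trials))}
    for i in range(len(session.trials)):
        a = int(tr.sync.cue_onset_frame[i])
        b = tr.sync.trial_end_frame(i, tr.n_frames)
        tr.values[:, a:b] += 0.1 * n_l[i]
    res = evidence_linear_model(tr, session)
    assert (res.table["category"] == "+L").mean() > 0.9
    assert res.fraction_modulated() > 0.9


def test_null_cells_per_coefficient_rejection_at_nominal_level(session):
    cells = [CellGroundTruth(kind="null") for _ in range(500)]
    tr = synthesize_soma_activity(cells, session, rng=np.random.default_rng(9))
    res = evidence_linear_model(tr, session)
    tol = 3 * np.sqrt(0.05 * 0.95 / 500)
    assert (res.table["p_L"] < 0.05).mean() == pytest.approx(0.05, abs=tol)
    assert (res.table["p_R"] < 0.05).mean() == pytest.approx(0.05, abs=tol)


def test_planted_difference_cell_categorized_as_L_minus_R(session):
    cells = [CellGroundTruth(kind="null", noise_sd=0.02) for _ in range(20)]
    tr = synthesize_soma_activity(cells, session, rng=np.random.default_rng(10))
    for i in range(len(session.trials)):
        a = int(tr.sync.cue_onset_frame[i])
        b = tr.sync.trial_end_frame(i, tr.n_frames)
        t = session.trials[i]
        tr.values[:, a:b] += 0.1 * (t.n_left - t.n_right)
    res = evidence_linear_model(tr, session)
    assert (res.table["category"] == "+(L,-R)").mean() > 0.9


def test_shuffle_destroys_evidence_but_preserves_choice_coding(session):
    """The choice-held shuffle removes puff-count coding while retaining any
    choice-mediated association: evidence cells collapse toward the nominal
    rate, pure choice cells keep similar category rates."""
    rng = np.random.default_rng(11)
    ev_cells = [CellGroundTruth(kind="evidence_L", noise_sd=0.05)
                for _ in range(80)]
    tr_ev = synthesize_soma_activity(ev_cells, session, rng=rng)
    real = evidence_linear_model(tr_ev, session)
    shuf = evidence_linear_model(tr_ev, session, shuffle=True,
                                 rng=np.random.default_rng(12))
    # the shuffle keeps only the choice-mediated part of the association:
    # fitted puff coefficients collapse toward it
    assert (np.abs(real.table["coef_L"]).mean()
            > 2 * np.abs(shuf.table["coef_L"]).mean())
    z = compare_category_rates(real, shuf)
    assert z.set_index("category").loc["+L", "p"] < 1e-3

    ch_cells = [CellGroundTruth(kind="choice_selective", pref_side="R",
                                noise_sd=0.05) for _ in range(80)]
    tr_ch = synthesize_soma_activity(ch_cells, session,
                                     rng=np.random.default_rng(13))
    real_ch = evidence_linear_model(tr_ch, session)
    shuf_ch = evidence_linear_model(tr_ch, session, shuffle=True,
                                    rng=np.random.default_rng(14))
    # choice-mediated rates should be comparable, not destroyed
    assert shuf_ch.fraction_modulated() > 0.5 * real_ch.fraction_modulated() - 0.1


# ----------------------------------------------------------- baseline return

def test_null_baseline_return_p_uniform():
    """On stationary noise, the paired pre-cue vs post-ITI test is calibrated:
    p-values over repeated null populations are uniform."""
    session = simulate_session(TaskConfig(), BehaviorParams(), 25, rng_seed=20)
    cells = [CellGroundTruth(kind="null") for _ in range(8)]
    template = synthesize_soma_activity(cells, session,
                                        rng=np.random.default_rng(21))
    rng = np.random.default_rng(22)
    ps = []
    for _ in range(200):
        template.values[:] = rng.normal(0, 0.05, template.values.shape)
        ps.append(baseline_return_test(template, session)[1])
    frac = np.mean(np.array(ps) < 0.05)
    assert frac == pytest.approx(0.05, abs=0.05)


def test_persistent_offset_detected(session):
    cells = [CellGroundTruth(kind="null") for _ in range(10)]
    tr = synthesize_soma_activity(cells, session, rng=np.random.default_rng(23))
    # plant a persistent post-trial offset
    for i in range(len(session.trials)):
        end = tr.sync.trial_end_frame(i, tr.n_frames)
        tr.values[:, end - int(1.5 * FR):end] += 0.2
    stat, p, n = baseline_return_test(tr, session)
    assert p < 0.01


def test_identical_windows_give_zero_statistic(session):
    cells = [CellGroundTruth(kind="null", noise_sd=0.0) for _ in range(3)]
    tr = synthesize_soma_activity(cells, session, sampling="expected")
    stat, p, n = baseline_return_test(tr, session)
    assert stat == 0.0 and p == 1.0
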