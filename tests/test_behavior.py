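"""Sleep and responsiveness metrics against direct oracles and the spec'd
boundary conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepswitch import behavior
from sleepswitch.behavior import (
    SleepBout, call_responder, detect_sleep_bouts, fit_response_peak,
    intensity_by_inactivity_bin, kernel_peak, response_kernel,
    sleep_intensity, stimulus_locked_mean, summarize_sleep,
)
from sleepswitch.errors import ContractError, EmptySelectionError
from sleepswitch.traces import ActivityTrace

from conftest import make_trace, schedule, trace_from_speed


# ---------------------------------------------------------------------- speed

def test_speed_constant_position_is_zero():
    tr = make_trace(np.full(100, 10.0))
    assert np.all(tr.speed == 0)


def test_speed_uniform_advance():
    tr = make_trace(np.arange(0.0, 60.0, 2.0))
    assert tr.speed[0] == 0
    assert np.allclose(tr.speed[1:], 2.0)


def test_speed_equals_finite_difference_oracle():
    rng = np.random.default_rng(3)
    x = np.cumsum(rng.normal(0, 1, 500)) % 65.0
    tr = make_trace(x, dt=0.5)
    oracle = np.abs(np.diff(x)) / 0.5
    assert np.array_equal(tr.speed[1:], oracle)


def test_nonuniform_grid_rejected():
    from sleepswitch.errors import FormatError
    with pytest.raises(FormatError):
        ActivityTrace(fly_id="f", t=np.array([0.0, 1.0, 3.0]), x=np.zeros(3))


# ---------------------------------------------------------------------- bouts

def bruteforce_bouts(speeds, dt=1.0, eps=0.5, min_s=300.0):
    """Independent oracle: scan every maximal run of sub-threshold frames."""
    quiet = np.asarray(speeds) <= eps
    out, i, n = [], 0, len(quiet)
    while i < n:
        if quiet[i]:
            j = i
            while j + 1 < n and quiet[j + 1]:
                j += 1
            if (j - i + 1) * dt >= min_s:
                out.append((i * dt, (j + 1) * dt))
            i = j + 1
        else:
            i += 1
    return out


def test_one_hour_of_quiet_is_one_bout():
    tr = trace_from_speed(np.zeros(3600))
    bouts = detect_sleep_bouts(tr)
    assert len(bouts) == 1
    assert bouts[0].duration_s == 3600.0


def test_interrupted_quiet_yields_no_bout():
    s = np.zeros(481)
    s[240] = 5.0  # one moving frame splits two 4-min runs
    tr = trace_from_speed(s)
    assert detect_sleep_bouts(tr) == []


@pytest.mark.parametrize("seed", range(10))
def test_bouts_match_bruteforce_scan(seed):
    rng = np.random.default_rng(seed)
    speeds = np.where(rng.random(7200) < 0.97, 0.0, 2.0)
    speeds[0] = 0.0
    tr = trace_from_speed(speeds)
    got = [(b.start_s, b.end_s) for b in detect_sleep_bouts(tr)]
    assert got == bruteforce_bouts(speeds)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.booleans(), min_size=2, max_size=2000), st.integers(2, 20))
def test_bouts_match_bruteforce_property(active, min_frames):
    speeds = np.where(active, 2.0, 0.0).astype(float)
    speeds[0] = 0.0
    tr = trace_from_speed(speeds)
    got = [(b.start_s, b.end_s) for b in detect_sleep_bouts(tr, min_bout_s=float(min_frames))]
    assert got == bruteforce_bouts(speeds, min_s=float(min_frames))


# -------------------------------------------------------------------- summary

def test_single_bout_single_hour():
    bouts = [SleepBout("f", 600.0, 2400.0)]  # 30 min inside hour 0
    s = summarize_sleep(bouts, 7200.0)
    assert s.hourly_min[0] == 30.0
    assert s.hourly_min[1] == 0.0


def test_bout_split_at_hour_boundary():
    bouts = [SleepBout("f", 2400.0, 5400.0)]  # minute 40 of hour 0 -> minute 30 of hour 1
    s = summarize_sleep(bouts, 7200.0)
    assert s.hourly_min[0] == 20.0
    assert s.hourly_min[1] == 30.0


def test_fully_excluded_hour_is_missing_not_zero():
    s = summarize_sleep([SleepBout("f", 0.0, 600.0)], 7200.0,
                        exclusion_windows=[(3600.0, 7200.0)])
    assert np.isnan(s.hourly_min[1])
    assert s.hourly_min[0] == 10.0


def test_exclusion_rescales_to_min_per_hr():
    # 30 min excluded; fly asleep the whole remaining half hour -> 60 min/hr
    s = summarize_sleep([SleepBout("f", 1800.0, 3600.0)], 3600.0,
                        exclusion_windows=[(0.0, 1800.0)])
    assert s.hourly_min[0] == pytest.approx(60.0)


def _oracle_included_sleep(w0, w1, bouts, exclusions, step=0.25):
    """Brute-force interval oracle on a fine grid."""
    grid = np.arange(w0, w1, step) + step / 2
    incl = np.ones(len(grid), dtype=bool)
    for e0, e1 in exclusions:
        incl &= ~((grid >= e0) & (grid < e1))
    asleep = np.zeros(len(grid), dtype=bool)
    for b in bouts:
        asleep |= (grid >= b.start_s) & (grid < b.end_s)
    return (asleep & incl).sum() * step, incl.sum() * step


@pytest.mark.parametrize("seed", range(5))
def test_summary_matches_interval_oracle(seed):
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.uniform(0, 6600, 6))
    bouts = []
    prev_end = 0.0
    for s0 in starts:
        s0 = max(s0, prev_end + 1.0)
        dur = rng.uniform(300, 900)
        if s0 + dur > 7200:
            break
        bouts.append(SleepBout("f", round(s0, 2), round(s0 + dur, 2)))
        prev_end = s0 + dur
    exclusions = [(900.0, 1500.0), (4000.0, 4300.0)]
    summary = summarize_sleep(bouts, 7200.0, exclusion_windows=exclusions)
    for h in range(2):
        a, inc = _oracle_included_sleep(h * 3600.0, (h + 1) * 3600.0, bouts, exclusions)
        expect = 60.0 * a / inc
        assert summary.hourly_min[h] == pytest.approx(expect, abs=0.05)


def test_hourly_totals_match_included_bout_time():
    bouts = [SleepBout("f", 100.0, 700.0), SleepBout("f", 3000.0, 4200.0)]
    s = summarize_sleep(bouts, 7200.0)
    assert s.hourly_min.sum() * 60.0 == pytest.approx(sum(b.duration_s for b in bouts))


# ------------------------------------------------------------ response curves

def test_single_trial_curve_equals_aligned_speed():
    rng = np.random.default_rng(0)
    speeds = rng.uniform(0, 3, 1300)
    speeds[0] = 0.0
    tr = trace_from_speed(speeds)
    sched = schedule([150.0])
    c = stimulus_locked_mean([tr], sched, pre_s=120, post_s=900)
    assert c.n == 1
    assert np.allclose(c.mean_speed, tr.speed[30:1051])


def test_mean_of_identical_flies_is_idempotent():
    speeds = np.zeros(1300)
    speeds[200:260] = 2.0
    t1, t2 = trace_from_speed(speeds, "a"), trace_from_speed(speeds, "b")
    sched = schedule([150.0])
    c1 = stimulus_locked_mean([t1], sched)
    c12 = stimulus_locked_mean([t1, t2], sched)
    assert c12.n == 2
    assert np.allclose(c12.mean_speed, c1.mean_speed)


def test_curve_equals_pointwise_mean_oracle():
    rng = np.random.default_rng(1)
    traces = [trace_from_speed(np.abs(rng.normal(0, 1, 1300)), f"f{i}") for i in range(8)]
    sched = schedule([150.0])
    c = stimulus_locked_mean(traces, sched)
    oracle = np.mean([tr.speed[30:1051] for tr in traces], axis=0)
    assert np.allclose(c.mean_speed, oracle)


def test_empty_selection_raises():
    tr = trace_from_speed(np.zeros(1300))
    with pytest.raises(EmptySelectionError):
        stimulus_locked_mean([tr], schedule([150.0]), trial_filter=lambda t, e: False)


# ------------------------------------------------------------------ peak fits

def _curve_from_kernel(B, A, rise, decay, noise_sd=0.0, seed=0, dt=1.0):
    from sleepswitch.behavior import ResponseCurve
    rel_t = np.arange(-120, 901, dt)
    y = B + response_kernel(rel_t, A, rise, decay)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(y))
    return ResponseCurve(rel_t=rel_t, mean_speed=y, n=1)


def test_noiseless_kernel_recovered_within_1pct():
    fit = fit_response_peak(_curve_from_kernel(0.5, 2.0, 2.0, 60.0))
    planted = kernel_peak(2.0, 2.0, 60.0)
    assert fit.converged
    assert fit.peak_mm_s == pytest.approx(planted, rel=0.01)
    assert fit.baseline == pytest.approx(0.5)


def test_flat_curve_has_zero_peak():
    fit = fit_response_peak(_curve_from_kernel(0.7, 0.0, 2.0, 60.0))
    assert fit.peak_mm_s == pytest.approx(0.0, abs=1e-9)


def test_peak_is_linear_in_amplitude():
    f1 = fit_response_peak(_curve_from_kernel(0.0, 1.5, 2.0, 60.0))
    f2 = fit_response_peak(_curve_from_kernel(0.0, 3.0, 2.0, 60.0))
    assert f2.peak_mm_s == pytest.approx(2.0 * f1.peak_mm_s, rel=1e-6)


def test_analytic_peak_matches_grid_maximum():
    t = np.linspace(0, 600, 600001)
    for A, r, d in [(2.0, 2.0, 60.0), (1.0, 5.0, 20.0), (4.0, 0.5, 100.0)]:
        assert kernel_peak(A, r, d) == pytest.approx(
            response_kernel(t, A, r, d).max(), rel=1e-6)


# ------------------------------------------------------------ responder calls

def _call_trace(pre_speeds, post_speeds, dt=1.0):
    """Trace with an onset at t=120 s flanked by specified speeds."""
    speeds = np.zeros(300)
    speeds[61:121] = pre_speeds
    speeds[121:181] = post_speeds
    return trace_from_speed(speeds, dt=dt), 120.0


def test_responder_above_threshold():
    tr, onset = _call_trace(0.0, 0.1)  # 0.1 mm/frame for 60 frames = 6 mm
    call = call_responder(tr, onset)
    assert call.displacement_mm == pytest.approx(6.0)
    assert call.responder and call.immobile_at_stim


def test_non_responder_below_threshold():
    post = np.zeros(60)
    post[:29] = 0.1  # 2.9 mm total
    tr, onset = _call_trace(0.0, post)
    call = call_responder(tr, onset)
    assert call.displacement_mm == pytest.approx(2.9)
    assert not call.responder


def test_displacement_equals_path_length_oracle():
    rng = np.random.default_rng(7)
    x = np.cumsum(rng.normal(0, 0.4, 300))
    tr = make_trace(x)
    call = call_responder(tr, 120.0)
    oracle = np.sum(np.abs(np.diff(x[120:181])))
    assert call.displacement_mm == pytest.approx(oracle, abs=1e-12)


def test_threshold_is_a_step_function():
    for d, expect in [(2.999, False), (3.0, True), (3.001, True)]:
        post = np.zeros(60)
        post[0] = d
        tr, onset = _call_trace(0.0, post)
        assert call_responder(tr, onset).responder is expect


def test_truncated_window_excluded():
    tr = trace_from_speed(np.zeros(100))
    assert call_responder(tr, 50.0) is None


def test_moved_prior_min_flags_awake():
    tr, onset = _call_trace(1.0, 0.0)
    call = call_responder(tr, onset)
    assert call.moved_prior_min and not call.immobile_at_stim


# --------------------------------------------------------------- intensity

def _mk_call(responder, immobile=True, immobility_min=10.0):
    from sleepswitch.behavior import ResponderCall
    return ResponderCall(
        fly_id="f", stim_id=0, immobile_at_stim=immobile,
        moved_prior_min=not immobile, displacement_mm=5.0 if responder else 0.0,
        responder=responder, immobility_duration_s=immobility_min * 60.0)


def test_sleep_intensity_exact_ratio():
    calls = [_mk_call(True)] * 4 + [_mk_call(False)] * 6
    assert sleep_intensity(calls) == pytest.approx(0.4)


def test_sleep_intensity_empty_is_missing():
    assert np.isnan(sleep_intensity([]))


def test_sleep_intensity_rejects_awake_calls():
    with pytest.raises(ContractError):
        sleep_intensity([_mk_call(True), _mk_call(True, immobile=False)])


def test_bin_assignment_16min():
    df = intensity_by_inactivity_bin([_mk_call(True, immobility_min=16.0)])
    row = df[df.n > 0].iloc[0]
    assert row.bin == "[15,20)"


def test_bin_boundary_is_half_open():
    df = intensity_by_inactivity_bin([_mk_call(True, immobility_min=5.0)])
    assert df[df.n > 0].iloc[0].bin == "[5,10)"


def test_overflow_bin_reported_separately():
    df = intensity_by_inactivity_bin([_mk_call(True, immobility_min=45.0)])
    assert df[df.n > 0].iloc[0].bin == "30+"


# -------------------------------------------------- awake peak responsiveness

def test_awake_filter_composes_with_manual_pipeline(small_cohort):
    traces, sched, _ = small_cohort
    fit = behavior.awake_peak_responsiveness(traces, sched)
    curve = stimulus_locked_mean(traces, sched,
                                 trial_filter=behavior.awake_trial_filter())
    manual = fit_response_peak(curve)
    assert fit.peak_mm_s == pytest.approx(manual.peak_mm_s)


def test_awake_filter_on_always_moving_cohort_matches_unfiltered():
    rng = np.random.default_rng(9)
    traces = [trace_from_speed(rng.uniform(1.0, 3.0, 1300), f"f{i}") for i in range(4)]
    sched = schedule([150.0])
    filtered = behavior.awake_peak_responsiveness(traces, sched)
    unfiltered = fit_response_peak(stimulus_locked_mean(traces, sched))
    assert filtered.peak_mm_s == pytest.approx(unfiltered.peak_mm_s)


def test_all_asleep_cohort_raises_empty_selection():
    traces = [trace_from_speed(np.zeros(1300), f"f{i}") for i in range(3)]
    with pytest.raises(EmptySelectionError):
        behavior.awake_peak_responsiveness(traces, schedule([150.0]))
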