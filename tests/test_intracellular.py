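"""Membrane-potential analysis against planted ground truth and brute-force
window means."""

import numpy as np
import pytest

from sleepswitch import intracellular as ic
from sleepswitch.errors import ConfigurationError, InsufficientDataError
from sleepswitch.synth import VmSimConfig, simulate_step_protocol, simulate_vm_trace
from sleepswitch.synth.ephys import _add_spike, _spike_template
from sleepswitch.traces import LightAnnotation, VmTrace

FS = 10000.0


def _trace(vm, light=None):
    return VmTrace(fs=FS, vm=vm, light=light or LightAnnotation(mode="none"))


def _with_spikes(times_s, duration_s=10.0, rest=-40.0, envelope=None):
    vm = np.full(int(duration_s * FS), rest)
    if envelope is not None:
        vm += envelope
    tpl, peak = _spike_template(FS, 45.0)
    for t in times_s:
        _add_spike(vm, int(round(t * FS)), tpl, peak)
    return _trace(vm)


# ------------------------------------------------------------ spike detection

def test_flat_trace_has_no_spikes():
    assert ic.detect_spikes(_trace(np.full(50000, -40.0))) == []


def test_seven_planted_spikes_detected_at_planted_times():
    times = [0.5, 1.2, 2.0, 3.3, 5.1, 7.7, 9.0]
    spikes = ic.detect_spikes(_with_spikes(times))
    assert len(spikes) == 7
    for sp, t in zip(spikes, times):
        assert sp.peak_time_s == pytest.approx(t, abs=2e-4)


def test_refractory_merges_peaks_1ms_apart():
    spikes = ic.detect_spikes(_with_spikes([1.0, 1.001]))
    assert len(spikes) == 1


def test_low_sampling_rate_rejected():
    tr = VmTrace(fs=500.0, vm=np.zeros(1000), light=LightAnnotation(mode="none"))
    with pytest.raises(ConfigurationError):
        ic.detect_spikes(tr)


def test_detection_matches_generator_ground_truth():
    cfg = VmSimConfig(cell_class="single", noise_sd_mv=0.8, light_mode="none",
                      duration_s=120.0, seed=13)
    tr, gt = simulate_vm_trace(cfg)
    spikes = ic.detect_spikes(tr)
    planted = gt["spike_times_s"]
    assert len(spikes) == len(planted)
    for sp, t in zip(spikes, planted):
        assert sp.peak_time_s == pytest.approx(t, abs=2e-4)


# ------------------------------------------------------------- classification

def test_two_spikes_on_plateau_form_burst():
    env = np.zeros(int(10 * FS))
    env[int(0.9 * FS): int(1.2 * FS)] = 10.0  # held 10 mV above rest
    tr = _with_spikes([1.0, 1.05], envelope=env)
    cls = ic.classify_cell(tr, resting_vm=-40.0)
    assert cls.label == "burst"
    assert (cls.n_single, cls.n_burst) == (0, 1)


def test_silent_cell_with_silent_steps_is_non_spiking():
    tr = _trace(np.full(int(10 * FS), -40.0))
    steps = simulate_step_protocol("non_spiking")
    cls = ic.classify_cell(tr, step_protocol=steps)
    assert cls.label == "non_spiking"
    assert np.all(steps.currents_pa == np.arange(10.0, 151.0, 10.0))


def test_silent_cell_without_steps_is_indeterminate():
    cls = ic.classify_cell(_trace(np.full(int(10 * FS), -40.0)))
    assert cls.label == "indeterminate" and cls.flagged


def test_planted_mixture_counts():
    # 5 isolated singles + 3 bursts of 2 spikes on plateaus
    env = np.zeros(int(30 * FS))
    times = [2.0, 5.0, 8.0, 11.0, 14.0]
    for start in (18.0, 21.0, 24.0):
        env[int((start - 0.05) * FS): int((start + 0.15) * FS)] = 10.0
        times += [start, start + 0.05]
    tr = _with_spikes(times, duration_s=30.0, envelope=env)
    cls = ic.classify_cell(tr, resting_vm=-40.0)
    assert cls.label == "single_and_burst"
    assert (cls.n_single, cls.n_burst) == (5, 3)


def test_classification_invariant_to_constant_offset():
    cfg = VmSimConfig(cell_class="single_and_burst", noise_sd_mv=0.5,
                      light_mode="none", duration_s=60.0, seed=3)
    tr, _ = simulate_vm_trace(cfg)
    base = ic.classify_cell(tr)
    shifted = VmTrace(fs=tr.fs, vm=tr.vm + 12.5, light=tr.light)
    assert ic.classify_cell(shifted).label == base.label


# ------------------------------------------------------------- dVm summaries

def test_noiseless_plateau_dvm():
    cfg = VmSimConfig(cell_class="non_spiking", noise_sd_mv=0.0,
                      evoked_depolarization_mv=8.0, evoked_rise_tau_s=0.01,
                      evoked_decay_tau_s=0.01, duration_s=250.0, seed=0)
    tr, _ = simulate_vm_trace(cfg)
    s = ic.vm_response_constant(tr)
    assert s.dvm_stim_mv == pytest.approx(8.0, abs=0.01)
    assert s.dvm_post_mv == pytest.approx(0.0, abs=0.01)


def test_no_light_effect_gives_zero_dvm():
    cfg = VmSimConfig(cell_class="non_spiking", noise_sd_mv=0.5,
                      evoked_depolarization_mv=0.0, seed=1)
    tr, _ = simulate_vm_trace(cfg)
    assert ic.vm_response_constant(tr).dvm_stim_mv == pytest.approx(0.0, abs=0.1)


def test_window_means_equal_bruteforce_slices():
    cfg = VmSimConfig(cell_class="single", noise_sd_mv=1.0, seed=7)
    tr, _ = simulate_vm_trace(cfg)
    s = ic.vm_response_constant(tr)
    fs = int(FS)
    assert s.pre_mean_mv == np.mean(tr.vm[: 60 * fs])
    assert s.stim_mean_mv == np.mean(tr.vm[60 * fs: 120 * fs])
    assert s.post_mean_mv == np.mean(tr.vm[-60 * fs:])


def test_insufficient_post_window_reports_nan_but_keeps_stim():
    cfg = VmSimConfig(cell_class="non_spiking", noise_sd_mv=0.0,
                      duration_s=185.0, seed=0)
    tr, _ = simulate_vm_trace(cfg)
    s = ic.vm_response_constant(tr)
    assert np.isnan(s.post_mean_mv)
    assert np.isfinite(s.dvm_stim_mv)


# --------------------------------------------------------- pulse composites

def _pulsed_trace(n_pulses=120, amp=3.0, noise=0.0, seed=0):
    cfg = VmSimConfig(cell_class="non_spiking", light_mode="pulsed_1hz_5ms",
                      evoked_depolarization_mv=amp, noise_sd_mv=noise,
                      light_duration_s=float(n_pulses), duration_s=n_pulses + 120.0,
                      seed=seed)
    return simulate_vm_trace(cfg)


def test_identical_pulses_composite_equals_single_epoch():
    tr, gt = _pulsed_trace(n_pulses=30)
    comp = ic.composite_pulse_vm(tr)
    fs = int(FS)
    onset = int(gt["pulses"][0]["pulse_onset_s"] * fs) if gt["pulses"] else int(60 * fs)
    epoch = tr.vm[onset: onset + fs]
    assert np.allclose(comp.composite_mv, epoch, atol=1e-9)
    assert comp.n_pulses == 30


def test_composite_first100ms_under_noise_matches_averaging_prediction():
    tr0, _ = _pulsed_trace(amp=3.0, noise=0.0)
    noiseless = ic.composite_pulse_vm(tr0).first100ms_mean_mv
    cfg = VmSimConfig(cell_class="non_spiking", light_mode="pulsed_1hz_5ms",
                      evoked_depolarization_mv=3.0, noise_sd_mv=1.0, seed=21)
    tr, _ = simulate_vm_trace(cfg)
    got = ic.composite_pulse_vm(tr).first100ms_mean_mv
    # var of the mean of band-limited noise averaged over 120 trials x 100 ms
    sem = 1.0 * np.sqrt(2 * cfg.noise_tau_s / 0.1) / np.sqrt(120)
    assert abs(got - noiseless) < 4 * sem


def test_single_epoch_raises():
    tr, _ = _pulsed_trace(n_pulses=30)
    tr.light.pulse_onsets_s = tr.light.pulse_onsets_s[:1]
    with pytest.raises(InsufficientDataError):
        ic.composite_pulse_vm(tr)


# ---------------------------------------------------------- secondary spikes

def _pulsed_with_planted_secondaries(offset_s):
    """10 pulses, evoked spike at +8 ms, planted extra spike at a fixed
    offset after the evoked one."""
    n = int(100 * FS)
    vm = np.full(n, -40.0)
    tpl, pk = _spike_template(FS, 45.0)
    onsets = 60.0 + np.arange(10.0)
    for p in onsets:
        _add_spike(vm, int((p + 0.008) * FS), tpl, pk)
        _add_spike(vm, int((p + 0.008 + offset_s) * FS), tpl, pk)
    light = LightAnnotation(mode="pulsed_1hz_5ms", onset_s=60.0, duration_s=10.0,
                            pulse_onsets_s=onsets)
    return VmTrace(fs=FS, vm=vm, light=light)


def test_secondary_spikes_within_window_reliability_one():
    s = ic.detect_secondary_spikes(_pulsed_with_planted_secondaries(0.2))
    assert s.reliability == 1.0
    assert s.n_evoked_pulses == 10


def test_secondary_spikes_outside_window_reliability_zero():
    s = ic.detect_secondary_spikes(_pulsed_with_planted_secondaries(0.6))
    assert s.reliability == 0.0


def test_secondary_reliability_matches_planted_probability():
    cfg = VmSimConfig(cell_class="single", light_mode="pulsed_1hz_5ms",
                      single_rate_hz=0.0, secondary_spike_prob=0.4,
                      noise_sd_mv=0.5, seed=17)
    tr, gt = simulate_vm_trace(cfg)
    s = ic.detect_secondary_spikes(tr)
    planted = np.mean([p["secondary"] for p in gt["pulses"] if p["evoked"]])
    assert s.reliability == pytest.approx(planted, abs=1e-9)
    # and the planted rate sits inside the binomial 95% CI of 0.4
    n = s.n_evoked_pulses
    assert abs(planted - 0.4) < 2.5 * np.sqrt(0.4 * 0.6 / n)


# -------------------------------------------------------------------- ISIs

def test_burst_isi_planted_18_75ms():
    tr = _with_spikes([1.0, 1.01875], envelope=None)
    spikes = ic.detect_spikes(tr)
    assert ic.burst_isi_ms(spikes) == pytest.approx(18.75, abs=0.11)


def test_burst_isi_10ms():
    spikes = ic.detect_spikes(_with_spikes([2.0, 2.010]))
    assert ic.burst_isi_ms(spikes) == pytest.approx(10.0, abs=0.11)


def test_burst_isi_matches_first_difference_oracle():
    rng = np.random.default_rng(5)
    for _ in range(5):
        t0 = rng.uniform(1, 5)
        isi = rng.uniform(0.005, 0.05)
        spikes = ic.detect_spikes(_with_spikes([t0, t0 + isi, t0 + 3 * isi]))
        assert ic.burst_isi_ms(spikes[:2]) == pytest.approx(isi * 1000, abs=0.11)


def test_single_spike_isi_is_missing():
    spikes = ic.detect_spikes(_with_spikes([1.0]))
    assert np.isnan(ic.burst_isi_ms(spikes))
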