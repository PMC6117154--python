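"""Electrophysiology simulators: membrane-potential and LFP traces with
planted light-evoked responses.

Vm traces emulate whole-cell current-clamp recordings from sleep-switch
soma: a resting potential in the −50..−30 mV range, Gaussian recording
noise, optional spontaneous single spikes and burst volleys (fixed
intra-volley interval), and a light-evoked depolarization applied either as
a constant-light plateau or as per-pulse transients under 1 Hz / 5 ms
pulsed light.

LFP traces are 1/f broadband noise; during light-on the 1–15 Hz component
is scaled by a planted amplitude gain, and in pulsed mode a deterministic
deflection of fixed latency/width follows each pulse onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..errors import ConfigurationError
from ..traces import LFPTrace, LightAnnotation, VmTrace
from ..intracellular import StepProtocolResult


# ---------------------------------------------------------------------------
# membrane potential
# ---------------------------------------------------------------------------

@dataclass
class VmSimConfig:
    fs: float = 10000.0
    duration_s: float = 240.0
    resting_vm_mv: float = -40.0          # stabilized range is -50..-30 mV
    noise_sd_mv: float = 0.5
    cell_class: str = "single"            # non_spiking | single | burst | single_and_burst
    light_mode: str = "constant"          # constant | pulsed_1hz_5ms | none
    light_onset_s: float = 60.0
    light_duration_s: float = 120.0
    evoked_depolarization_mv: float = 8.0
    evoked_rise_tau_s: float = 0.5
    evoked_decay_tau_s: float = 2.0
    burst_isi_ms: float = 18.75           # intra-volley interspike interval
    burst_size: int = 3
    single_rate_hz: float = 0.5           # spontaneous isolated spikes
    burst_rate_hz: float = 0.1            # spontaneous volleys
    spike_amp_mv: float = 45.0
    pulse_evoked_spike_prob: float = 0.9  # evoked spike per light pulse (spiking cells)
    secondary_spike_prob: float = 0.0     # extra spike 100-500 ms after the evoked one
    noise_tau_s: float = 0.005            # membrane low-pass time constant of the noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.evoked_depolarization_mv < 0:
            raise ConfigurationError("evoked depolarization must be >= 0")
        if self.cell_class not in ("non_spiking", "single", "burst", "single_and_burst"):
            raise ConfigurationError(f"unknown cell_class {self.cell_class!r}")
        if self.light_mode not in ("constant", "pulsed_1hz_5ms", "none"):
            raise ConfigurationError(f"unknown light_mode {self.light_mode!r}")
        if self.light_mode != "none" and (
                self.duration_s < self.light_onset_s + self.light_duration_s):
            raise ConfigurationError("duration must cover light onset + duration")
        if not 0.0 <= self.secondary_spike_prob <= 1.0:
            raise ConfigurationError("secondary_spike_prob must lie in [0, 1]")


def _spike_template(fs: float, amp_mv: float) -> tuple[np.ndarray, int]:
    """Action-potential waveform: fast Gaussian depolarization (SD 0.4 ms)
    with a shallow after-hyperpolarization; returns (template, peak index)."""
    t = np.arange(-0.002, 0.008, 1.0 / fs)
    spike = amp_mv * np.exp(-(t ** 2) / (2 * 0.0004 ** 2))
    ahp = -4.0 * np.exp(-((t - 0.003) ** 2) / (2 * 0.0015 ** 2))
    tpl = spike + ahp
    return tpl, int(np.argmax(tpl))


def _add_spike(vm: np.ndarray, peak_idx: int, tpl: np.ndarray, tpl_peak: int) -> None:
    start = peak_idx - tpl_peak
    lo, hi = max(0, start), min(len(vm), start + len(tpl))
    vm[lo:hi] += tpl[lo - start: hi - start]


def simulate_vm_trace(config: VmSimConfig):
    """Simulate a Vm recording; returns (VmTrace, ground_truth dict).

    Ground truth records planted spike peak times (s), volley membership,
    and the secondary-spike outcome per light pulse.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    vm = np.full(n, config.resting_vm_mv)
    if config.noise_sd_mv > 0:
        # membrane-filtered (OU-like) noise: white noise through a first-order
        # low-pass with the membrane time constant, rescaled to noise_sd
        white = rng.normal(0.0, 1.0, n)
        if config.noise_tau_s > 0:
            alpha = 1.0 / (config.noise_tau_s * fs)
            noise = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], white)
            sd = noise.std()
            noise = noise / sd if sd > 0 else noise
        else:
            noise = white
        vm += config.noise_sd_mv * noise

    on, dur = config.light_onset_s, config.light_duration_s
    off = on + dur
    pulse_onsets = None

    # light-evoked depolarization envelope
    if config.light_mode == "constant":
        rise, decay = config.evoked_rise_tau_s, config.evoked_decay_tau_s
        d = config.evoked_depolarization_mv
        during = (t >= on) & (t < off)
        vm[during] += d * (1.0 - np.exp(-(t[during] - on) / rise))
        after = t >= off
        d_off = d * (1.0 - math.exp(-dur / rise))
        vm[after] += d_off * np.exp(-(t[after] - off) / decay)
    elif config.light_mode == "pulsed_1hz_5ms":
        n_pulses = int(math.floor(dur))
        pulse_onsets = on + np.arange(n_pulses, dtype=float)
        # per-pulse depolarizing transient: 5 ms rise, ~80 ms decay
        k_t = np.arange(0.0, 0.5, 1.0 / fs)
        k = (1.0 - np.exp(-k_t / 0.005)) * np.exp(-k_t / 0.08)
        k *= config.evoked_depolarization_mv / k.max() if k.max() > 0 else 0.0
        for p in pulse_onsets:
            i0 = int(round(p * fs))
            hi = min(n, i0 + len(k))
            vm[i0:hi] += k[: hi - i0]

    # spontaneous spiking
    tpl, tpl_peak = _spike_template(fs, config.spike_amp_mv)
    spike_times: list[float] = []
    volley_ids: list[int] = []
    volley = 0

    def plant_spike(time_s: float, vid: int) -> None:
        idx = int(round(time_s * fs))
        if not 0 <= idx < n:
            return
        _add_spike(vm, idx, tpl, tpl_peak)
        spike_times.append(idx / fs)
        volley_ids.append(vid)

    spiking = config.cell_class != "non_spiking"
    wants_single = config.cell_class in ("single", "single_and_burst")
    wants_burst = config.cell_class in ("burst", "single_and_burst")

    if spiking and wants_single and config.single_rate_hz > 0:
        n_singles = rng.poisson(config.single_rate_hz * config.duration_s)
        for time_s in np.sort(rng.uniform(0.5, config.duration_s - 1.0, n_singles)):
            plant_spike(float(time_s), volley)
            volley += 1
    if spiking and wants_burst and config.burst_rate_hz > 0:
        n_volleys = rng.poisson(config.burst_rate_hz * config.duration_s)
        isi = config.burst_isi_ms / 1000.0
        for start in np.sort(rng.uniform(0.5, config.duration_s - 1.0, n_volleys)):
            # depolarized plateau so the inter-peak Vm fails to return to rest
            span = config.burst_size * isi + 0.03
            i0, i1 = int(round((start - 0.01) * fs)), int(round((start + span) * fs))
            i0, i1 = max(0, i0), min(n, i1)
            vm[i0:i1] += 8.0
            for k_sp in range(config.burst_size):
                plant_spike(float(start + k_sp * isi), volley)
            volley += 1

    # light-evoked spikes under pulsed light
    secondary_outcomes = []
    if spiking and pulse_onsets is not None:
        for p in pulse_onsets:
            evoked = rng.random() < config.pulse_evoked_spike_prob
            secondary = False
            if evoked:
                first = p + 0.008
                plant_spike(float(first), volley)
                volley += 1
                if rng.random() < config.secondary_spike_prob:
                    secondary = True
                    plant_spike(float(first + rng.uniform(0.12, 0.4)), volley)
                    volley += 1
            secondary_outcomes.append({"pulse_onset_s": float(p), "evoked": evoked,
                                       "secondary": secondary})

    light = LightAnnotation(
        mode=config.light_mode,
        onset_s=on if config.light_mode != "none" else 0.0,
        duration_s=dur if config.light_mode != "none" else 0.0,
        pulse_onsets_s=pulse_onsets,
    )
    order = np.argsort(spike_times)
    gt = {
        "spike_times_s": np.asarray(spike_times)[order] if spike_times else np.array([]),
        "volley_ids": np.asarray(volley_ids)[order] if spike_times else np.array([], dtype=int),
        "pulses": secondary_outcomes,
        "config": config,
    }
    return VmTrace(fs=fs, vm=vm, light=light), gt


def simulate_step_protocol(cell_class: str, seed: int = 0,
                           max_pa: float = 150.0) -> StepProtocolResult:
    """Depolarizing current-step record (+10 pA steps up to +150 pA):
    non-spiking cells stay silent, spiking cells fire above a rheobase."""
    rng = np.random.default_rng(seed)
    currents = np.arange(10.0, max_pa + 1.0, 10.0)
    if cell_class == "non_spiking":
        counts = np.zeros_like(currents, dtype=int)
    else:
        rheobase = rng.uniform(20.0, 60.0)
        counts = np.maximum(0, ((currents - rheobase) / 15.0)).astype(int)
        counts[currents > rheobase] = np.maximum(counts[currents > rheobase], 1)
    return StepProtocolResult(currents_pa=currents, spike_counts=counts)


# ---------------------------------------------------------------------------
# local field potential
# ---------------------------------------------------------------------------

@dataclass
class LfpSimConfig:
    fs: float = 500.0
    duration_s: float = 240.0
    noise_exponent: float = 1.0          # 1/f^alpha spectral shape
    noise_amplitude: float = 10.0        # overall SD, recording units
    stim_band_gain: float = 1.0          # amplitude gain on 1-15 Hz during light-on
    light_mode: str = "constant"         # constant | pulsed_1hz_5ms | none
    light_onset_s: float = 60.0
    light_duration_s: float = 120.0
    erp_amplitude: float = -50.0         # signed deflection, units
    erp_latency_ms: float = 20.0
    erp_width_ms: float = 10.0           # FWHM of the deflection
    n_pulses: int = 120
    carrier_hz: float | None = None      # optional pure tone (tests)
    carrier_amplitude: float = 0.0
    slow_drift_sd: float = 0.1           # fractional baseline nonstationarity
    slow_drift_tau_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.stim_band_gain < 0:
            raise ConfigurationError("band gain must be >= 0")
        if self.n_pulses < 1:
            raise ConfigurationError("n_pulses must be >= 1")
        if not 0.0 <= self.erp_latency_ms < 1000.0:
            raise ConfigurationError("erp_latency_ms must lie in [0, 1000)")
        if self.light_mode not in ("constant", "pulsed_1hz_5ms", "none"):
            raise ConfigurationError(f"unknown light_mode {self.light_mode!r}")
        if self.light_mode != "none" and (
                self.duration_s < self.light_onset_s + self.light_duration_s):
            raise ConfigurationError("duration must cover light onset + duration")
        if self.light_mode == "pulsed_1hz_5ms" and self.n_pulses > self.light_duration_s:
            raise ConfigurationError("light window too short for n_pulses at 1 Hz")


def _one_over_f_noise(n: int, fs: float, exponent: float, rng) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit variance."""
    white = rng.normal(0.0, 1.0, n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = (f[nz] / 1.0) ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_lfp_trace(config: LfpSimConfig):
    """Simulate an LFP recording; returns (LFPTrace, ground_truth dict).

    Constant mode: the 1-15 Hz component of the baseline noise is scaled by
    ``stim_band_gain`` during light-on.  Pulsed mode: a deterministic
    Gaussian deflection (planted amplitude, latency, FWHM) follows each of
    ``n_pulses`` 1 Hz pulse onsets.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    if config.noise_amplitude > 0:
        x = config.noise_amplitude * _one_over_f_noise(n, fs, config.noise_exponent, rng)
        if config.slow_drift_sd > 0:
            # slow multiplicative drift of the background amplitude (brain
            # state is not stationary over minutes)
            n_env = int(config.duration_s) + 2
            alpha = 1.0 / config.slow_drift_tau_s
            env = np.zeros(n_env)
            innov = rng.normal(0.0, 1.0, n_env)
            for i in range(1, n_env):
                env[i] = env[i - 1] * (1 - alpha) + np.sqrt(2 * alpha) * \
                    config.slow_drift_sd * innov[i]
            drift = np.interp(t, np.arange(n_env, dtype=float), env)
            x = x * np.clip(1.0 + drift, 0.1, None)
    else:
        x = np.zeros(n)
    if config.carrier_hz is not None and config.carrier_amplitude != 0.0:
        x = x + config.carrier_amplitude * np.sin(2 * np.pi * config.carrier_hz * t)

    on, dur = config.light_onset_s, config.light_duration_s
    off = on + dur
    pulse_onsets = None

    if config.light_mode == "constant" and config.stim_band_gain != 1.0:
        sos = sps.butter(4, [1.0, 15.0], btype="bandpass", fs=fs, output="sos")
        in_band = sps.sosfiltfilt(sos, x)
        during = (t >= on) & (t < off)
        x = x + (config.stim_band_gain - 1.0) * np.where(during, in_band, 0.0)
    elif config.light_mode == "pulsed_1hz_5ms":
        pulse_onsets = on + np.arange(config.n_pulses, dtype=float)
        sd_s = (config.erp_width_ms / 1000.0) / 2.355
        lat = config.erp_latency_ms / 1000.0
        k_t = np.arange(0.0, lat + 6 * sd_s, 1.0 / fs)
        bump = config.erp_amplitude * np.exp(-((k_t - lat) ** 2) / (2 * sd_s ** 2))
        for p in pulse_onsets:
            i0 = int(round(p * fs))
            hi = min(n, i0 + len(bump))
            if i0 < n:
                x[i0:hi] += bump[: hi - i0]

    light = LightAnnotation(
        mode=config.light_mode,
        onset_s=on if config.light_mode != "none" else 0.0,
        duration_s=dur if config.light_mode != "none" else 0.0,
        pulse_onsets_s=pulse_onsets,
    )
    gt = {"config": config, "pulse_onsets_s": pulse_onsets}
    return LFPTrace(fs=fs, signal=x, light=light), gt
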