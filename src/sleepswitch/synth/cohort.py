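"""Behavioral cohort simulator: circadian two-state activity with
vibration-evoked responses and planted sleep/responsiveness correlations.

The activity model is a two-state semi-Markov chain (active/quiescent) on a
minute grid with geometric dwell times and a circadian switch at ZT0/ZT12.
Each fly carries three correlated latent traits: a day sleep propensity, a
night sleep propensity, and a response amplitude; the propensity-amplitude
correlations are the planted quantities that the downstream correlation
analysis must recover.  Propensities act on the *asleep fraction* scale
(linear in the latent), so the planted Pearson correlation survives the
chain's dynamics approximately intact.

Responses to a vibration train are Bernoulli draws whose probability
declines with the fly's prior immobility duration (5-min bins); responders
wake up and superimpose a single-inactivation exponential speed kernel,
``A (1 - e^{-t/tau_r}) e^{-t/tau_d}``, on their baseline walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from ..traces import ActivityTrace, StimulusEvent, StimulusSchedule

#: Default decline of response probability with prior immobility (5-min
#: bins, first 30 min); awake flies use the first bin, >=30 min the last.
DEFAULT_RESPONSE_PROB = {0: 0.95, 5: 0.85, 10: 0.75, 15: 0.65, 20: 0.55, 25: 0.50}


@dataclass
class CohortConfig:
    n_flies: int
    days: int = 3              # recording days (after acclimatization)
    frame_rate: float = 1.0                      # Hz
    day_window_zt: tuple[float, float] = (0.0, 12.0)
    p_fall_asleep_day: float = 0.02              # per-minute, cohort mean
    p_fall_asleep_night: float = 0.08
    sleep_dwell_mean_day: float = 12.0           # minutes, geometric dwell
    sleep_dwell_mean_night: float = 25.0
    sleep_fraction_sd_day: float = 0.07          # per-fly spread of asleep fraction
    sleep_fraction_sd_night: float = 0.12
    response_amplitude_mean: float = 2.5         # mm/s
    response_amplitude_sd: float = 1.2           # broad inter-fly spread (peaks ~0-8 mm/s)
    response_kernel: tuple[float, float] = (2.0, 60.0)   # (rise_tau s, decay_tau s)
    response_prob_by_immobility: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_PROB))
    planted_R_day: float = 0.0
    planted_R_night: float = -0.372
    day_night_propensity_corr: float = 0.5
    dfb_activation_factor: float = 1.0           # amplitude multiplier during light-on
    stimulus_protocol: str = "hourly"            # or "acute_15min"
    acute_n_trials: int = 6
    light_windows: list[tuple[float, float]] = field(default_factory=list)
    baseline_step_sd_mm: float = 1.25            # awake per-frame step scale
    tracking_noise_mm: float = 0.02   # keeps the noise path-length well under the 3 mm call
    tube_length_mm: float = 65.0
    response_window_s: float = 300.0             # kernel support / forced-wake span
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ConfigurationError("cohort needs at least one fly")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        for name in ("p_fall_asleep_day", "p_fall_asleep_night"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        for name in ("planted_R_day", "planted_R_night", "day_night_propensity_corr"):
            v = getattr(self, name)
            if abs(v) > 1.0:
                raise ConfigurationError(f"|{name}| must be <= 1, got {v}")
        if any(not 0.0 <= p <= 1.0 for p in self.response_prob_by_immobility.values()):
            raise ConfigurationError("response probabilities must lie in [0, 1]")
        if self.response_amplitude_mean < 0 or self.response_amplitude_sd < 0:
            raise ConfigurationError("amplitudes must be nonnegative")
        if not 0.0 <= self.dfb_activation_factor <= 1.0:
            raise ConfigurationError("dfb_activation_factor must lie in [0, 1]")
        if self.stimulus_protocol not in ("hourly", "acute_15min"):
            raise ConfigurationError(f"unknown protocol {self.stimulus_protocol!r}")
        # latent correlation matrix must be positive semidefinite
        c = self._latent_corr()
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ConfigurationError(
                "planted correlations and day/night propensity correlation "
                "do not form a valid correlation matrix")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        """Rebuild a config from its JSON round trip (tuples and int keys
        are not preserved by JSON)."""
        d = dict(d)
        for key in ("day_window_zt", "response_kernel"):
            if key in d:
                d[key] = tuple(d[key])
        if "light_windows" in d:
            d["light_windows"] = [tuple(w) for w in d["light_windows"]]
        if "response_prob_by_immobility" in d:
            d["response_prob_by_immobility"] = {
                int(k): float(v) for k, v in d["response_prob_by_immobility"].items()}
        return cls(**d)

    def _latent_corr(self) -> np.ndarray:
        rd, rn, dn = self.planted_R_day, self.planted_R_night, self.day_night_propensity_corr
        return np.array([[1.0, rd, rn], [rd, 1.0, dn], [rn, dn, 1.0]])


@dataclass
class CohortGroundTruth:
    """Planted per-fly traits and per-stimulus outcomes."""

    flies: pd.DataFrame      # fly_id, amplitude, f_day, f_night, latents
    stimuli: pd.DataFrame    # stim_id, fly_id, onset_s, light_on, immobility_s, p_response, responder
    config: CohortConfig


def wildtype_like_config(n_flies: int = 225, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort emulating an inbred wildtype background: little daytime sleep,
    substantial night sleep, sleep/responsiveness correlated only at night
    (planted day R = 0, night R = -0.372)."""
    kw = dict(n_flies=n_flies, planted_R_day=0.0, planted_R_night=-0.372, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def activated_like_config(n_flies: int = 51, seed: int = 0, **overrides) -> CohortConfig:
    """Cohort emulating chronic sleep-switch activation: daytime sleep is
    elevated toward night-like levels, and sleep and responsiveness are
    negatively coupled in both windows (planted day R = -0.410, night
    R = -0.554)."""
    kw = dict(
        n_flies=n_flies, planted_R_day=-0.410, planted_R_night=-0.554,
        p_fall_asleep_day=0.05, sleep_dwell_mean_day=20.0,
        sleep_fraction_sd_day=0.12, seed=seed,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


def _stationary_fraction(q_per_min: float, dwell_min: float) -> float:
    """Asleep fraction of the alternating process: dwell / (dwell + 1/q)."""
    return dwell_min * q_per_min / (1.0 + dwell_min * q_per_min)


def _fall_asleep_prob(frac: float, dwell_min: float) -> float:
    """Invert the stationary fraction for a per-fly per-minute probability."""
    return min(1.0, frac / (dwell_min * (1.0 - frac)))


def _schedule(config: CohortConfig) -> tuple[StimulusSchedule, float]:
    """Stimulus events and total trace duration for the chosen protocol."""
    if config.stimulus_protocol == "hourly":
        duration = config.days * 86400.0
        onsets = [h * 3600.0 + 1800.0 for h in range(config.days * 24)]
        events = []
        for i, onset in enumerate(onsets):
            light = any(a <= onset < b for a, b in config.light_windows)
            events.append(StimulusEvent(stim_id=i, onset_s=onset, light_on=light))
        return StimulusSchedule(events=events, light_windows=list(config.light_windows)), duration
    # acute protocol: a trial every 15 min, alternating 1 min of light before
    # (and 3 min after) the stimulus with no-light trials
    events, windows = [], []
    for i in range(config.acute_n_trials):
        onset = (i + 1) * 900.0
        light = i % 2 == 0
        if light:
            windows.append((onset - 60.0, onset + 180.0))
        events.append(StimulusEvent(stim_id=i, onset_s=onset, light_on=light))
    duration = (config.acute_n_trials + 1) * 900.0
    return StimulusSchedule(events=events, light_windows=windows), duration


def simulate_cohort(config: CohortConfig):
    """Simulate a cohort; returns (traces, schedule, ground_truth).

    Identical seeds give identical output.  Ground truth records every
    planted quantity that a downstream analysis estimates: per-fly response
    amplitudes and sleep propensities (asleep fractions), and each
    stimulus's responder outcome with the immobility duration that set its
    response probability.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_flies
    fr = config.frame_rate
    schedule, duration_s = _schedule(config)
    n_min = int(math.ceil(duration_s / 60.0))
    frames_per_min = int(round(60.0 * fr))
    n_frames = n_min * frames_per_min
    dt = 1.0 / fr

    # --- per-fly latent traits -------------------------------------------
    z = rng.multivariate_normal(np.zeros(3), config._latent_corr(), size=n,
                                method="cholesky")
    z_amp, z_day, z_night = z[:, 0], z[:, 1], z[:, 2]
    amplitude = np.maximum(
        config.response_amplitude_mean + config.response_amplitude_sd * z_amp, 0.05)
    f_day_base = _stationary_fraction(config.p_fall_asleep_day, config.sleep_dwell_mean_day)
    f_night_base = _stationary_fraction(config.p_fall_asleep_night, config.sleep_dwell_mean_night)
    f_day = np.clip(f_day_base + config.sleep_fraction_sd_day * z_day, 0.0, 0.98)
    f_night = np.clip(f_night_base + config.sleep_fraction_sd_night * z_night, 0.0, 0.98)
    q_day = np.array([_fall_asleep_prob(f, config.sleep_dwell_mean_day) for f in f_day])
    q_night = np.array([_fall_asleep_prob(f, config.sleep_dwell_mean_night) for f in f_night])
    p_wake_day = min(1.0, 1.0 / config.sleep_dwell_mean_day)
    p_wake_night = min(1.0, 1.0 / config.sleep_dwell_mean_night)

    # --- two-state chain on the minute grid ------------------------------
    zt0, zt1 = config.day_window_zt
    minute_zt = (np.arange(n_min) / 60.0) % 24.0
    is_day_min = (minute_zt >= zt0) & (minute_zt < zt1)
    asleep = np.zeros((n, n_min), dtype=bool)
    u = rng.random((n, n_min))
    state = u[:, 0] < (f_day if is_day_min[0] else f_night)  # start near stationarity
    asleep[:, 0] = state
    for m in range(1, n_min):
        day = is_day_min[m]
        q = q_day if day else q_night
        p_wake = p_wake_day if day else p_wake_night
        fall = ~state & (u[:, m] < q)
        wake = state & (u[:, m] < p_wake)
        state = (state & ~wake) | fall
        asleep[:, m] = state

    awake_frames = ~np.repeat(asleep, frames_per_min, axis=1)

    # --- stimulus outcomes (sequential: responders are woken) ------------
    prob_map = sorted(config.response_prob_by_immobility.items())
    bin_edges = np.array([lo for lo, _ in prob_map], dtype=float) * 60.0
    bin_probs = np.array([p for _, p in prob_map])
    lookback = int(round((bin_edges[-1] + 900.0) * fr))  # beyond last edge -> overflow
    wake_frames = int(round(config.response_window_s * fr))
    rise, decay = config.response_kernel
    kern_t = (np.arange(1, wake_frames + 1)) * dt
    kernel = (1.0 - np.exp(-kern_t / rise)) * np.exp(-kern_t / decay)

    stim_rows = []
    responder_events: list[tuple[int, float, np.ndarray]] = []  # (i_on, factor, responder mask)
    for ev in schedule.events:
        i_on = int(round(ev.onset_s * fr))
        lo = max(0, i_on - lookback)
        window = awake_frames[:, lo:i_on]
        any_awake = window.any(axis=1)
        last_awake = window.shape[1] - 1 - np.argmax(window[:, ::-1], axis=1)
        frames_immobile = np.where(any_awake, window.shape[1] - 1 - last_awake,
                                   lookback + 1)
        immobility_s = frames_immobile * dt
        awake_now = frames_immobile == 0
        idx = np.minimum(np.searchsorted(bin_edges, immobility_s, side="right") - 1,
                         len(bin_probs) - 1)
        p_resp = bin_probs[np.maximum(idx, 0)]
        p_resp = np.where(awake_now, bin_probs[0], p_resp)
        responder = rng.random(n) < p_resp
        factor = config.dfb_activation_factor if ev.light_on else 1.0
        # response movement occupies (onset, onset + window]: frame i_on + 1
        # onward, so the pre-stimulus minute stays clean for the awake filter
        start = i_on + 1
        hi = min(n_frames, start + wake_frames)
        if hi > start:
            resp_idx = np.flatnonzero(responder)
            awake_frames[resp_idx, start:hi] = True
            responder_events.append((start, factor, responder.copy()))
        # a sleeping fly the stimulus failed to rouse stays put through the
        # scoring minute, so its responder call reflects the planted draw
        still = np.flatnonzero(~responder & ~awake_now)
        hi60 = min(n_frames, start + int(round(60.0 * fr)) + 1)
        awake_frames[still, start:hi60] = False
        for j in range(n):
            stim_rows.append({
                "stim_id": ev.stim_id, "fly_id": f"fly{j:03d}",
                "onset_s": ev.onset_s, "light_on": ev.light_on,
                "immobility_s": float(immobility_s[j]),
                "awake_at_stim": bool(awake_now[j]),
                "p_response": float(p_resp[j]),
                "responder": bool(responder[j]),
            })

    # --- positions: reflected random walk + response kernel --------------
    traces = []
    child_seeds = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)).spawn(n)
    L = config.tube_length_mm
    for j in range(n):
        frng = np.random.default_rng(child_seeds[j])
        steps = np.zeros(n_frames)
        aw = awake_frames[j]
        n_aw = int(aw.sum())
        if n_aw:
            steps[aw] = np.abs(frng.normal(0.0, config.baseline_step_sd_mm, n_aw)) * dt
        for start, factor, mask in responder_events:
            if mask[j]:
                hi = min(n_frames, start + wake_frames)
                steps[start:hi] += factor * amplitude[j] * kernel[: hi - start] * dt
        signs = frng.integers(0, 2, n_frames) * 2.0 - 1.0
        cum = L / 2.0 + np.cumsum(signs * steps)
        folded = np.mod(cum, 2.0 * L)
        x = L - np.abs(folded - L)
        if config.tracking_noise_mm > 0:
            x = np.clip(x + frng.normal(0.0, config.tracking_noise_mm, n_frames), 0.0, L)
        t = np.arange(n_frames) * dt
        traces.append(ActivityTrace(fly_id=f"fly{j:03d}", t=t, x=x,
                                    tube_length_mm=L))

    flies = pd.DataFrame({
        "fly_id": [f"fly{j:03d}" for j in range(n)],
        "amplitude": amplitude,
        "f_day": f_day,
        "f_night": f_night,
        "z_amp": z_amp, "z_day": z_day, "z_night": z_night,
        "q_day": q_day, "q_night": q_night,
    })
    gt = CohortGroundTruth(flies=flies, stimuli=pd.DataFrame(stim_rows), config=config)
    return traces, schedule, gt
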