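"""Time-frequency analysis of dFB local field potentials.

The LFP signature of sleep-switch activation lives in low frequencies:
power between 1 and 15 Hz (0.1 Hz bins) rises during optogenetic activation,
and 1 Hz light pulses evoke an event-related potential (ERP).  The analysis
is a Morlet-wavelet transform (30 cycles per wavelet, Gaussian envelope
truncated at +/-3 SD), baseline-normalized per frequency bin into wavelet
ratios, with the baseline zeroed so positive values mean increased power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InsufficientDataError
from .traces import LFPTrace

#: Analysis frequency grid: 1.0-15.0 Hz inclusive in 0.1 Hz bins (141 rows).
BAND_FREQS_HZ = np.round(np.arange(10, 151) * 0.1, 1)

MORLET_WIDTH_CYCLES = 30.0
GAUSS_SD_CUTOFF = 3.0

#: Wavelet analysis runs on a decimated trace; 1-15 Hz needs nothing near
#: the native 10 kHz rate.
ANALYSIS_FS_HZ = 500.0


def morlet_wavelet(freq_hz: float, fs: float, width: float = MORLET_WIDTH_CYCLES,
                   sd_cutoff: float = GAUSS_SD_CUTOFF) -> np.ndarray:
    """Complex Morlet wavelet of ``width`` cycles at ``freq_hz``, Gaussian
    envelope truncated at ``sd_cutoff`` standard deviations, normalized to
    unit L2 norm (so power is comparable across frequencies)."""
    sd_t = width / (2.0 * np.pi * freq_hz)
    half = int(np.floor(sd_cutoff * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t ** 2) / (2.0 * sd_t ** 2))
    return w / np.linalg.norm(w)


@dataclass
class WaveletSpectrogram:
    freqs: np.ndarray        # Hz, 141 rows for the standard band
    times: np.ndarray        # s, analysis-rate grid
    power: np.ndarray        # |coefficient|^2, shape (n_freqs, n_times)
    valid: np.ndarray        # bool mask; False where wavelet support ran off an edge
    fs: float

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ConfigurationError("power array shape mismatch")


def decimate_for_analysis(trace: LFPTrace, target_fs: float = ANALYSIS_FS_HZ) -> LFPTrace:
    """Anti-aliased downsample to the analysis rate (no-op if already there)."""
    if trace.fs <= target_fs:
        return trace
    factor = trace.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError("sampling rate must be an integer multiple of the analysis rate")
    sig = sps.resample_poly(trace.signal, 1, int(round(factor)))
    return LFPTrace(fs=target_fs, signal=sig, light=trace.light)


def morlet_spectrogram(
    trace: LFPTrace,
    freqs: np.ndarray | None = None,
    width: float = MORLET_WIDTH_CYCLES,
    sd_cutoff: float = GAUSS_SD_CUTOFF,
    decimate: bool = True,
) -> WaveletSpectrogram:
    """Morlet power spectrogram over the 1-15 Hz grid.

    Each row is the squared magnitude of the complex convolution with the
    unit-energy Morlet wavelet at that frequency.  Samples closer to a trace
    edge than half the wavelet support are masked invalid (never zero-padded
    into means).  A trace shorter than the 1 Hz wavelet support yields an
    all-masked row with a warning rather than an error.
    """
    if freqs is None:
        freqs = BAND_FREQS_HZ
    freqs = np.asarray(freqs, dtype=float)
    if decimate:
        trace = decimate_for_analysis(trace)
    x = trace.signal
    n = len(x)
    power = np.empty((len(freqs), n))
    valid = np.zeros((len(freqs), n), dtype=bool)
    import warnings
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, trace.fs, width, sd_cutoff)
        half = (len(w) - 1) // 2
        coeff = sps.fftconvolve(x, np.conj(w[::-1]), mode="same")
        power[i] = np.abs(coeff) ** 2
        if n > 2 * half:
            valid[i, half: n - half] = True
        else:
            warnings.warn(
                f"trace shorter than the {f:g} Hz wavelet support; row fully masked",
                stacklevel=2,
            )
    return WaveletSpectrogram(freqs=freqs, times=trace.t, power=power,
                              valid=valid, fs=trace.fs)


def normalize_to_baseline(
    spec: WaveletSpectrogram,
    baseline_window: tuple[float, float],
    per_frequency: bool = True,
) -> WaveletSpectrogram:
    """Baseline-zeroed wavelet ratios: ``power / mean(baseline) - 1``.

    ``per_frequency=True`` normalizes each 0.1 Hz bin by its own baseline
    mean (the statistics convention); ``False`` divides everything by the
    grand baseline mean (the display convention used before averaging
    spectrograms across flies).  Frequencies with zero baseline power are
    masked.
    """
    t0, t1 = baseline_window
    in_base = (spec.times >= t0) & (spec.times < t1)
    valid = spec.valid.copy()
    ratios = np.full_like(spec.power, np.nan)
    if per_frequency:
        for i in range(len(spec.freqs)):
            sel = in_base & valid[i]
            if not sel.any():
                valid[i] = False
                continue
            mu = float(np.mean(spec.power[i, sel]))
            if mu <= 0:
                valid[i] = False
                continue
            ratios[i] = spec.power[i] / mu - 1.0
    else:
        sel = in_base & valid
        if not sel.any():
            raise InsufficientDataError("no valid baseline samples")
        mu = float(np.mean(spec.power[sel]))
        ratios = spec.power / mu - 1.0
    return WaveletSpectrogram(freqs=spec.freqs, times=spec.times,
                              power=ratios, valid=valid, fs=spec.fs)


def band_power_ratio(
    ratio_spec: WaveletSpectrogram,
    stim_window: tuple[float, float],
    band_hz: tuple[float, float] = (1.0, 15.0),
) -> float:
    """Mean baseline-zeroed wavelet ratio over the band x stimulation window
    (one scalar per fly).  Missing (NaN) if the window is fully masked."""
    t0, t1 = stim_window
    in_stim = (ratio_spec.times >= t0) & (ratio_spec.times < t1)
    in_band = (ratio_spec.freqs >= band_hz[0]) & (ratio_spec.freqs <= band_hz[1])
    sel = ratio_spec.valid[in_band][:, in_stim]
    vals = ratio_spec.power[in_band][:, in_stim]
    if not sel.any():
        return float("nan")
    return float(np.mean(vals[sel]))


@dataclass
class ERPSummary:
    trial_peaks: np.ndarray    # max |deviation| per trial, recording units
    mean_peak: float
    n_trials: int
    low_n: bool                # flagged when fewer than 10 complete trials


def erp_peak_amplitude(
    trace: LFPTrace,
    pulse_onsets_s: np.ndarray | None = None,
    window_s: float = 0.05,
    baseline_s: float = 0.05,
) -> ERPSummary:
    """Per-trial ERP peak: each trial is re-zeroed by its 50 ms pre-pulse
    mean, and the peak is the maximum absolute deviation in the 50 ms after
    pulse onset; the summary averages across trials (120 nominal)."""
    if pulse_onsets_s is None:
        if trace.light.pulse_onsets_s is None:
            raise ConfigurationError("pulse onsets required")
        pulse_onsets_s = trace.light.pulse_onsets_s
    fs = trace.fs
    n_win = int(round(window_s * fs))
    n_base = int(round(baseline_s * fs))
    peaks = []
    for onset in np.asarray(pulse_onsets_s, dtype=float):
        i0 = int(round(onset * fs))
        if i0 - n_base < 0 or i0 + n_win > len(trace.signal):
            continue
        zero = float(np.mean(trace.signal[i0 - n_base: i0]))
        seg = trace.signal[i0: i0 + n_win] - zero
        peaks.append(float(np.max(np.abs(seg))))
    peaks = np.asarray(peaks)
    if peaks.size == 0:
        raise InsufficientDataError("no complete ERP trials in trace")
    return ERPSummary(trial_peaks=peaks, mean_peak=float(np.mean(peaks)),
                      n_trials=int(peaks.size), low_n=peaks.size < 10)
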