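# Methods

This note documents the models, conventions and parameter choices behind
`sleepswitch` — what each analysis computes, what the synthetic generators
emulate (and deliberately do not), and where the design was genuinely open.

## Behavioral metrics

**Speed and immobility.** Positions are 1-D tube coordinates on a uniform
grid (default 1 Hz; tracking hardware rates are rig-specific, so the rate
is configurable). Speed is the forward-difference magnitude |Δx|/Δt, with
the first frame defined as 0. *Immobile* means speed ≤ ε, ε = 0.5 mm/s by
default — on the scale of tracking jitter, well below walking speed
(~1 mm/s). Tracking pipelines rarely state this floor explicitly; ours is
a declared, configurable default.

**Sleep bouts.** A bout is a maximal run of immobile frames spanning at
least 300 s. The field convention is "more than 5 minutes of inactivity";
at 1 Hz the difference between > and ≥ is a single frame, and we use ≥.
A run of k frames spans k·Δt seconds (each speed sample accounts for the
interval that precedes it), so a bout covers `[t_first, t_last + Δt)`.

**Sleep duration (min/hr).** Bouts are split at clock-hour boundaries.
Stimulus-response epochs — `[onset, onset + 900 s]` for every vibration
train — are excluded from both the numerator and the denominator, and the
hourly value is rescaled to min/hr, so sleep is averaged over unstimulated
time only. An hour with no included time is reported missing (NaN), never
as zero. Day is ZT 0–12 under a 12:12 cycle with traces starting at ZT0.

**Responsiveness.** Mean speed across (fly, trial) pairs aligned to each
train onset, 120 s before to 900 s after (vibration trains — five 0.2 s,
2.4 g pulses 0.8 s apart — are collapsed to their onset, the train being
short relative to the response). The mean curve is fitted for t ≥ 0 with
the single-inactivation exponential `B + A(1 − e^(−t/τ_r))e^(−t/τ_d)`;
B is fixed at the pre-window mean rather than fitted, and the onset t₀ is
fixed at the known train onset. Peak responsiveness is the analytic
maximum above B, at `t* = τ_r ln(1 + τ_d/τ_r)`. Whether the published
metric subtracts baseline is ambiguous; we subtract B and record that as a
convention. Non-convergent fits fall back to the maximum of the 5-s
smoothed curve above B and are flagged; negative fitted amplitudes are
clipped to zero and flagged.

**Responder calls.** A fly responded to a stimulus if its cumulative path
length Σ|Δx| over `(onset, onset + 60 s]` is at least 3 mm (~3 body
lengths). Path length, not net displacement, is used: a fly that runs out
and back has responded (configurable). A fly is *immobile at stimulus* if
no frame in the preceding minute exceeded ε; trials whose windows are
truncated by a trace edge are excluded, not defaulted. Prior-immobility
duration is the time since the last supra-threshold frame.

**Sleep intensity.** Fraction of immobile flies responding; undefined
(NaN, never 0) when no fly was immobile. The by-bin variant uses half-open
5-min bins `[0,5) … [25,30)` minutes of prior immobility plus a separately
reported `30+` overflow bin.

**Awake responsiveness** restricts the stimulus-locked mean to trials
where the fly moved in the prior minute, then fits the same curve.

## Intracellular analysis

Traces are current-clamp recordings at 10 kHz. Spikes are local maxima
with prominence ≥ 5 mV preceded within 1 ms by dV/dt ≥ 10 mV/ms, with a
2 ms refractory (thresholds are declared defaults; recordings below 1 kHz
are rejected). Resting V_m is the median of the pre-light minute with
±5 ms around spike peaks removed — robust to spontaneous firing.

**Burst grouping.** Consecutive spikes whose inter-peak minimum stays more
than 2 mV above resting ("fails to return to rest"; the 2 mV margin covers
the noise floor) share a volley. Cells with only multi-spike volleys are
*burst*, only isolated spikes *single*, both *single_and_burst*; a cell
with no spikes is *non_spiking* only if it also stayed silent through
depolarizing current steps of +10 pA up to +150 pA, and *indeterminate*
(flagged) without that record. Because a light-evoked depolarization keeps
V_m above rest for its whole duration, classification uses spontaneous
(light-off) spikes only. Classification is invariant to adding a constant
offset to the trace, as all criteria are relative to resting V_m.

**ΔV_m.** Constant light: pre = mean over the 60 s before onset, stim =
mean over the first 60 s of light, post = mean over the final 60 s of the
recording (reported only if it starts at or after light-off). Spike
waveforms are *not* excised from window means; at the rates simulated they
shift a 60-s mean by ~0.02 mV. Results are reported as ΔV_m relative to
pre, because somatic recordings from these unipolar cells blur the
absolute resting potential. Pulsed light: the 1-s epochs after each of the
(nominally 120) pulse onsets are averaged pointwise into a composite, and
ΔV_m is the composite's first-100-ms mean minus the pre-light baseline.
Missing post-light data leaves the post fields NaN without losing
ΔV_m(stim); fewer than two complete pulse epochs is an error.

**Secondary spikes.** A pulse is *evoked* if its first spike falls within
50 ms of pulse onset; secondary spikes are additional spikes 100–500 ms
after that first spike. Reliability is the fraction of evoked pulses with
at least one secondary spike; "reliable" at the cell level (a reliability
of ≥ 0.5 in the analysis scripts) is a declared convention — the original
qualitative observation was never quantified. Intra-burst ISI is the time
between the first and second peaks of a volley, in ms.

## LFP analysis

Signals are decimated to 500 Hz (polyphase anti-aliased) before
time–frequency analysis; the band of interest is 1–15 Hz. The Morlet
wavelet at frequency f has 30 cycles (σ_t = 30/2πf) with its Gaussian
envelope truncated at ±3 SD, and is normalized to unit L2 norm so power is
comparable across frequencies — the original toolbox's internal scaling is
not re-specifiable, so this convention is declared and all downstream
quantities are ratios, which cancel it. Power is the squared magnitude of
the complex convolution, on the 141-bin grid 1.0, 1.1, …, 15.0 Hz.
Samples closer to a trace edge than half the wavelet support are masked
and excluded from every mean (never zero-padded); a trace shorter than the
1 Hz support yields an all-masked row with a warning.

**Wavelet ratios.** Each frequency row is divided by its own baseline-
window mean and 1 is subtracted, so the baseline maps to exactly 0 and
positive values mean increased power; rows with zero baseline power are
masked. (A display-mode variant divides by the grand baseline mean before
averaging spectrograms across flies, mirroring the per-fly normalization
used when recordings differ in overall magnitude.) The per-fly band-power
summary is the mean ratio over the 1–15 Hz × stimulation-window region.
Note that normalizing by a *short* baseline mean carries a small positive
bias (Jensen's inequality over the few independent wavelet samples at the
lowest frequencies, ~τ_wavelet/T_baseline); validation protocols therefore
use baselines of a few minutes, where the bias is negligible.

**ERP.** Each 1 Hz, 5 ms light pulse defines a trial; the trial is
re-zeroed by its 50 ms pre-pulse mean (the published "deviation from zero"
never defines its zero, so this is a declared convention), and its peak is
the maximum absolute deviation in the 50 ms after onset. The summary
averages trials (120 nominal; fewer than 10 flags the result low-n).

## Statistics

Correlations between per-fly sleep (min/hr) and peak responsiveness are
Pearson with two-tailed p (the published figures report "R" without naming
the estimator) and listwise exclusion of flies missing either value; fewer
than 3 pairs is an error. Group comparisons run by declared design:
Friedman with Dunn's post hoc (within-block rank z-statistics, Bonferroni
family adjustment over the declared contrasts — the Dunn variant is not
re-specifiable, so this standard form is declared) for within-cell
pre/stim/post; Wilcoxon signed-rank against zero for ratios; Mann-Whitney
for two strains; paired/unpaired t with a Shapiro-Wilk screen (p < 0.05
forces the nonparametric analogue, recorded in the result); two-way ANOVA
(type-II sums of squares) with Dunnett's many-to-one comparisons against
the declared control for genotype designs. All tests are two-tailed at
α = 0.05. The report builder writes tidy CSVs, a sorted deterministic
`statistics.json`, and figures; every reported p-value is recomputable
from the emitted per-observation tables.

## Synthetic data: what is emulated

**Behavioral cohorts.** Activity is a two-state (active/quiescent)
semi-Markov chain on a minute grid with geometric dwell times and a
circadian switch at ZT0/ZT12 — the simplest model producing day/night
sleep structure. Each fly draws three correlated standard-normal latents
(response amplitude, day propensity, night propensity); the planted
`planted_R_day` and `planted_R_night` are the amplitude–propensity
correlations (two separate propensities, because one latent pair cannot
carry two different correlations; the day–night propensity correlation
defaults to 0.5 and the joint matrix is validated positive-semidefinite).
Propensity acts linearly on the *stationary asleep fraction* (clipped to
[0, 0.98]), from which the per-minute fall-asleep probability is inverted
given the dwell mean — keeping the planted Pearson correlation
interpretable on the min/hr scale the analysis measures.

Defaults are chosen to look like a wildtype tube assay: 3 recording days
(the standard protocol length), 1 Hz frames, day fall-asleep probability
0.02/min with 12-min dwells (~12 min/hr day sleep), night 0.08/min with
25-min dwells (~40 min/hr), per-fly asleep-fraction spreads 0.07 (day) /
0.12 (night), awake steps |N(0, 1.25 mm)| per frame with random direction
reflected in a 65-mm tube, and 0.02 mm tracking jitter (small enough that
a still fly's noise path stays far below the 3 mm responder threshold).
Response amplitudes are N(2.5, 1.2²) mm/s truncated at 0.05 — a broad
inter-fly spread matching the ~0–8 mm/s range such assays report — with
kernel (τ_r, τ_d) = (2 s, 60 s). Response probability declines with prior
immobility (0.95 → 0.50 across the 5-min bins); a responder is woken and
its kernel speed added starting the frame *after* onset (so the
pre-stimulus minute stays clean for the awake filter), while an immobile
non-responder stays put through the scoring minute so responder calls
reflect the planted Bernoulli draw exactly. `dfb_activation_factor`
scales amplitudes during light-on trials; an acute protocol (trials every
15 min alternating 1 min of light before / 3 min after the stimulus) is
available. One root seed drives cohort-level draws, with per-fly child
streams for movement, so generation is reproducible and order-independent.
The `wildtype_like_config` / `activated_like_config` factories encode the
two study conditions; the activated-like cohort additionally sleeps more
by day (fall-asleep 0.05/min, 20-min dwells, spread 0.12), as chronic
sleep-switch activation produces.

**Vm traces.** Resting potential −40 mV (configurable within the
stabilized −50…−30 mV range), band-limited Gaussian noise (white noise
through a first-order low-pass at the 5 ms membrane time constant — raw
white noise at 10 kHz would have unphysical dV/dt), Gaussian-shaped spikes
(45 mV, ~1 ms) with a shallow AHP, spontaneous singles (Poisson 0.5 Hz)
and/or volleys (0.1 Hz) of `burst_size` spikes at the planted 18.75 ms
interval riding a +8 mV plateau so the burst criterion is met by
construction. Constant light adds a rise/decay exponential plateau of the
planted amplitude; pulsed light adds a fast per-pulse transient, an evoked
spike 8 ms post pulse with probability 0.9, and a secondary spike 120–400
ms later with the planted probability.

**LFP traces.** 1/f-shaped Gaussian noise (configurable exponent and
amplitude) with a slow multiplicative amplitude drift (OU, τ = 30 s,
fractional SD 0.1) — real baselines are not stationary over minutes, and
without this between-fly variability a cohort of statistically identical
flies makes even tiny estimator biases "significant". During light-on the
1–15 Hz component (4th-order Butterworth decomposition) is scaled by a
planted amplitude gain g, so baseline-zeroed ratios recover ≈ g² − 1; in
pulsed mode a deterministic Gaussian deflection (planted amplitude,
latency, FWHM) follows each pulse onset.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: positional tracking artifacts (occlusion, jumps,
multi-fly identity swaps), non-Markovian sleep architecture and
homeostatic rebound, habituation or sensitization across stimuli,
electrode drift and spike-shape variability, line noise, movement
artifacts in LFP, and any coupling between the behavioral and
electrophysiological layers.

## Problem sizes and numerical choices

Validation runs at desk scale: correlation-pattern checks use 20 seeds ×
225 flies × 3 days (wildtype-like) and 20 × 51 (activated-like); bout
detection is checked against an exhaustive run-length oracle on 100
day-long 1 Hz sequences; ΔV_m recovery uses planted 2–15 mV at 1 mV noise
over 20 cells; wavelet output is checked against a naive per-frequency
convolution oracle to 1e-6 relative error. The activated-pattern check
requires significance in a majority of seeds and a seed-mean R inside the
planted value's 95% sampling band — at n = 51 even perfect recovery of
|R| = 0.41 is significant in only ~86% of draws, so an all-seeds
requirement would be statistically unattainable. Curve fits use trust-
region least squares with analytic Jacobian, bounds τ_r ∈ [1 ms, 300 s],
τ_d ∈ [10 ms, 3000 s], and a data-driven start (A₀ = max/0.8, τ_r = 2 s,
τ_d = 60 s). Interval arithmetic for sleep summaries is exact (no grid
discretization); bin edges are half-open everywhere; degenerate inputs
(empty immobile sets, fully tied Friedman blocks, all-masked spectrogram
windows) return missing values or p = 1 rather than raising, except where
the contract demands an error (empty selections, insufficient epochs).

## Known limitations

Peak-responsiveness estimates for a single fly rest on ~36 trials and are
noisy at low amplitudes; recovered correlations are attenuated by a few
percent relative to the planted latents (quantified in the acceptance
outputs). The wavelet implementation follows the declared width-30 /
±3 SD / unit-energy convention; numerical agreement with other toolboxes'
absolute power values is not expected, only ratio-level agreement. The
two-state activity model has geometric dwells, so simulated bout-length
distributions are lighter-tailed than real fly sleep.
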