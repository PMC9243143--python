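# Methods

This note documents the models, parameter choices and known limitations of
`eegsonify`. It is written for users who need to understand what each
stage assumes before trusting the audio or the statistics it produces.

## Signal model and scope

The tool targets multichannel neonatal scalp EEG sampled at 256 Hz in a
referential 10–20 montage. Essentially all clinically relevant neonatal
EEG content lies between 0.5 and 13 Hz; seizures appear as rhythmic
discharges of at least 10 s with evolving frequency and amplitude.
Amplitudes are handled in µV throughout. The tool answers one question per
recording — is a seizure audible/present? — and is not designed to
delineate individual events or report their durations.

## Pipeline stages

### Band-pass (preprocess.bandpass)

Zero-phase (forward–backward) 4th-order Butterworth, 0.5–13 Hz. Zero-phase
filtering is used so that no group delay desynchronizes channels before
stereo mixing; the effective magnitude response is the square of the
one-pass response, which is why the stop-band test budget (≥20 dB at
30 Hz) is conservative.

### ECG artifact attenuation (preprocess.attenuate_ecg)

The cardiac artifact is a QRS-locked, quasi-periodic waveform that is
*coherent across electrodes* (one source, fixed projections), unlike the
EEG background. Removal is beat-locked template subtraction: average the
±150 ms windows around each beat per channel, estimate per-beat
least-squares gains against that template, and subtract.

Two measured design decisions:

* **Pooled gain.** The per-beat gains are pooled by their median rather
  than applied individually. At EEG-level SNR a free per-beat gain fits
  background into the template: on synthetic records with a known injected
  artifact, per-beat gains *increased* the artifact residual (reductions
  of −0.3 to −1.0) while the pooled gain removed 83–91 % of it at oracle
  beat times.
* **Beat detection.** With a dedicated ECG lead (`ecg_ref`, the standard
  clinical setup) beats are detected on the reference and removal is
  nearly complete (≥70 % residual RMS reduction in tests). Without a
  reference, beats are tracked on the cross-channel mean via a
  QRS-emphasis envelope (rectified 4–16 Hz, 30 ms smoothing), a
  matched-filter score, and quasi-periodic tracking constrained to ±15 %
  of the autocorrelation-estimated beat period. This path is gated on the
  envelope's comb autocorrelation in the 1.5–3.5 Hz beat band
  (`min_comb = 0.10`): below the gate the input is returned unchanged,
  because blind subtraction at low confidence measurably adds noise.
  Scalp-only removal has an intrinsic ceiling — matched-filter timing
  jitter at sub-unit artifact SNR limits the achievable reduction to
  roughly 30 % — which is why a real deployment should record an ECG
  channel.

### Baseline detector (detector.baseline_probability)

A deterministic, training-free stand-in for a learned seizure model, good
enough to drive the attention mechanism: per channel and 1 s epoch it
computes in-band power, line length, and *rhythmicity* — the largest
normalized autocorrelation peak at lags 0.25–2 s of a 4 s context window
centred on the epoch (context edges use wrap padding so all epochs are
treated exchangeably). Each feature is standardized per record with a
median/MAD robust z-score (clipped at ±6) and combined as

    p = sigmoid(1.2·z_rhythm + 1.0·z_logpower + 0.5·z_linelength − 3.0)

The negative bias keeps pure-background records below a 0.5 record score;
the robust per-record baseline assumes background is the majority of the
record (it degrades once seizure burden exceeds roughly 40 %).
Rhythmicity is amplitude-invariant by construction, so the detector's
scale sensitivity enters only through the power feature. This detector
makes no claim of clinical-grade accuracy; external per-second
probabilities can be injected via CSV.

### Attention (attention)

Pooling is max over channels; the record score is the max over time of the
60 s moving-average-smoothed pooled trace (centred window, shrunken at the
edges). The smoothed pooled trace also drives the speed schedule — the
smoothing window is a single concept reused for both purposes. Optional
reshaping redistributes the pooled probabilities order-preservingly
(`uniform`: midrank transform; `ushape`: ranks through the Beta(½, ½)
quantile function); the default is no reshaping, matching the
configuration that performed best in listening tests of this class of
system.

The probability→speed map is geometric, s(p) = s_max^(1−p)·s_min^p:
log-linear in p, so equal probability increments give equal multiplicative
(perceptual) rate steps. `s_min = 60` is the seizure-epoch speed;
`s_max = 3000` is calibrated so that a seizure-free hour renders to 1.2 s
and an hour with two one-minute seizures to ≈3.2 s, i.e. a whole-night
screen stays in the seconds range. A linear interpolation mode is kept as
configuration.

The induced time map τ(t) = Σ epoch_len/s(u) is piecewise linear, strictly
increasing, and is the single source of truth for audio durations.

### Denoising (denoise)

Probability-gated spectral subtraction on an STFT with 256-sample Hann
windows and hop 64 (the same geometry the vocoder analyses, so both stages
see the same frames): per frame |Y| = max(|X| − α(1−p)B, β|X|), phases
untouched, B the per-bin median magnitude over all frames of the channel.
The median is robust to a minority of seizure frames. Defaults α = 1,
β = 0.1. The multiplicative floor (rather than an additive one) avoids
zeroed bins — the source of "musical noise" in speech enhancement — and
preserves the waveform's character in confident background. p = 1 frames
pass through bit-exactly.

### Variable-rate phase vocoder (vocoder.pv_render)

`fixed_pitch` (default): the EEG sample stream is declared at P× its rate
(P = 64), lifting every frequency f to P·f; the residual compression
s(t)/P is classic phase-vocoder time-scale modification with a
time-varying analysis hop. The implementation places analysis frames
through the **inverse time map**: synthesis frame k at audio time
k·H_s/(P·rate) reads the EEG position where the schedule says that much
audio has been emitted. This conserves total duration exactly across
abrupt speed changes (a naive per-epoch hop can leap over a seizure onset
— an earlier implementation of this module did, shortening the audio by
~8 %). Phases are propagated per bin by instantaneous-frequency estimates
(heterodyned phase increments over the realized hop); synthesis overlap-add
uses Hann² normalization floored at 1 % of its maximum so window edges are
attenuated, never amplified. The signal is reflect-padded by one window so
the final frames read continuous data.

Contracts (all tested): identity configuration (s ≡ 1, P = 1) reconstructs
with SNR well above 30 dB; a pure tone at constant speed keeps its lifted
frequency P·f within one FFT bin regardless of speed and within 3 dB of
the identity-rendering amplitude; realized duration equals the time-map
total within one analysis window (15.6 ms at the 16 384 Hz contract rate)
for arbitrary schedules.

`coupled` mode is variable-rate playback through the same time map
(frequency scales with s(t)); it is retained as configuration because both
couplings are legitimate sonification choices — fixed pitch is the default
because pitch changes then reflect true EEG frequency evolution rather
than the attention signal.

### Stereo mixing (mixer)

Each channel is a point on the unit head circle (standard planar 10–20
projection; bipolar derivations at the midpoint of their electrodes).
The only spatial cue is the Woodworth interaural time delay
ITD(θ) = (r/c)(θ + sin θ) for |θ| ≤ π/2, mirrored front-to-back,
r = 8.75 cm, c = 343 m/s (max ≈0.66 ms). Delays are rounded to whole
samples at the output rate (0.061 ms at 16 384 Hz, ≈9 % of the maximum
ITD) to avoid fractional-delay filtering. Gains are ear-equal (no level
difference), and the sum is peak-normalized to 0.9 full scale.

## Synthetic data (synthdata)

The generator is the package's test-bed, not a physiological simulator.
Background is 1/f colored Gaussian noise band-limited to 0.5–13 Hz and
scaled exactly to the configured RMS (default 30 µV). Seizures are
amplitude-modulated sinusoids with a linear instantaneous-frequency sweep
inside the band, a 0.3-weight second-harmonic (sharp-wave flavor), 2 s
cosine edge tapers, slow (0.1 Hz) waxing–waning modulation, and exact
window RMS; the defaults use 67.8 µV (the clearly-detected amplitude
regime) with 18.6 µV as the canonical low-SNR hard case. Events are at
least 10 s long, written on a configurable channel subset to emulate
focality. ECG artifact is a 60 ms triangular QRS with an exponential
recovery tail repeated at the configured heart rate with ±5 % inter-beat
jitter and fixed per-channel projections. Simulated annotators keep each
true event with a logistic detection probability in event RMS and duration
and inject Poisson false events.

What this does *not* emulate: non-stationary background states
(trace alternant, burst suppression), spatial propagation of seizures,
electrode artifacts other than ECG, and gestational-age dependence.
Passing tests therefore demonstrate the *mechanics* of the pipeline —
duration conservation, attention routing, artifact subtraction against a
known truth — not clinical detection performance on real neonatal EEG.
The default test-bed (`default_dataset`) uses 10 records of 600 s with a
60 % seizure prevalence and per-record seizure burden below ~30 %,
matching the robust-baseline assumption above; these sizes keep the full
suite in the tens of seconds while leaving the statistics stable across
seeds.

## Evaluation statistics (evaluation)

Fleiss' κ uses the standard definitions: p is the mean per-subject
pairwise agreement Σ_j n_ij(n_ij−1)/(N(N−1)), p_e = Σ_j p_j² over category
marginals. The asymptotic SD_κ = √(p(1−p))/(1−p_e) and the CI
κ ± z_(1−α/2)·SD_κ/√n use the normal quantile (1.96 at α = 0.05). When
every vote lands in one category p_e = 1 and κ is reported as undefined
(NaN), not 0. A subject-resampling percentile bootstrap (2000 reps) is
provided as a cross-check; on simulated ratings it overlaps the asymptotic
interval. The two-κ t-test t = (κ₁−κ₂)/√((SD₁²+SD₂²)/n) is referred to a
Student t with n degrees of freedom, two-sided. ROC AUC is the
Mann–Whitney pair statistic computed from midranks (ties count ½), which
equals the trapezoidal area under the empirical ROC curve. Majority vote
labels a record positive when at least ⌈N/2⌉ annotators marked an event.

## Numerical and degenerate-input choices

* EDF writing scales each channel's physical range to its observed
  min/max (16-bit), so round-trip error is bounded by range/2¹⁶; an
  all-constant channel gets a ±1 µV synthetic range to avoid zero scale.
* Speed schedules must cover the recording; a short schedule clips
  analysis to its last epoch with a warning rather than failing mid-render.
* The moving average at trace edges divides by the number of available
  epochs (no zero-padding bias).
* Records shorter than one epoch, single-class label vectors, empty track
  lists and mismatched STFT bin counts raise errors rather than guessing.
* One known quantitative subtlety of the attention design: the audio-time
  amplification of seizure epochs relative to their EEG-time share
  approaches s_max/s_min only as the seizure fraction → 0; at 120 s of
  seizure per hour the exact factor is 19.0. The property suite asserts
  the closed form, not a folklore bound.

## Limitations

* The baseline detector is a rhythmicity heuristic; on real EEG, rhythmic
  artifacts (patting, ventilation) will raise false attention. Use an
  external model's probabilities for anything beyond pipeline exercise.
* Scalp-only ECG removal is confidence-gated and intentionally
  conservative; recordings with a dedicated ECG lead get much better
  artifact suppression.
* The electrode coordinate table is a standard planar approximation, not
  digitized positions; mixing uses ITD only, so elevation and
  front–back disambiguation are not rendered.
* EDF+ annotations, video, and vendor formats are out of scope.
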