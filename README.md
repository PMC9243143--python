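# eegsonify

AI-attention-driven sonification of multichannel neonatal EEG.

Neonatal seizures are rare, evolving rhythmic discharges buried in hours of
multichannel EEG; detecting them reliably normally requires a
neurophysiologist, who is rarely available cot-side around the clock.
`eegsonify` turns a 1–2 h EEG recording into a few **seconds** of stereo
audio in which likely seizures are played slowly enough to *hear* — as
evolving tones with shifting pitch — while denoised background is raced
through almost instantly. A per-second seizure-probability trace (from any
detection model, or from the built-in training-free baseline) acts as an
attention signal that continuously modulates the playback speed.

## The method in brief

For each 1 s epoch *t*, a probability AI[ch, t] of seizure is available per
channel. The pooled trace AI[t] = max_ch AI[ch, t] is smoothed with a 60 s
moving average and mapped to a **speed factor** (seconds of EEG per second
of audio):

    s(p) = s_max^(1−p) · s_min^p        (defaults s_min = 60, s_max = 3000)

so a confident seizure epoch plays at 60× real time and confident
background at 3000×. A **variable-rate phase vocoder** (256-sample Hann
analysis windows placed through the inverse of the induced time map,
per-bin phase propagation by instantaneous frequency, overlap-add at hop
64) performs the compression while a fixed pitch lift P = 64 raises the
0.5–13 Hz EEG band to an audible 32–832 Hz, independent of playback speed.
Before the vocoder, each channel is band-passed (0.5–13 Hz, zero-phase),
the cardiac (QRS) artifact is attenuated by beat-locked template
subtraction, and background content is suppressed by probability-gated
spectral subtraction:

    |Y(f,t)| = max(|X(f,t)| − α·(1−p(t))·B(f),  β·|X(f,t)|)

with B(f) the per-bin median magnitude over the recording. Channels are
then placed on a virtual 2D head and mixed to stereo using only the
Woodworth interaural time delay, ITD(θ) = (r/c)(θ + sin θ).

The record-level probabilistic score is AI = max_t of the smoothed pooled
trace, and the evaluation module implements the agreement statistics used
for this kind of reader study: Fleiss' κ = (p − p_e)/(1 − p_e) with
SD_κ = √(p(1−p))/(1−p_e) and CI κ ± z·SD_κ/√n, the two-κ t-test
t = (κ₁−κ₂)/√((SD₁²+SD₂²)/n), sensitivity/specificity, the Mann–Whitney
ROC AUC, and majority-vote ground-truth pooling.

## Worked example

Generate a synthetic 10 min, 8-channel record with two seizure events,
sonify it, and run the baseline detector:

```bash
$ eegsonify synth --out-edf example.edf --out-truth truth.csv \
      --duration 600 --channels 8 --seizures 2 --seed 7
wrote example.edf (600 s, 8 ch, 2 events) and truth.csv

$ eegsonify sonify --edf example.edf --out example.wav
wrote example.wav: 2.71 s audio (predicted 2.70 s), record score 1.000

$ eegsonify detect --edf example.edf --out probs.csv
wrote probs.csv: 600 epochs x 8 channels, record score 1.000
```

Ten minutes of EEG collapse to 2.71 s of stereo audio: the two seizures
occupy most of it as slow evolving tones, the background flashes past at
~3000× real time. The *record score* of 1.000 is the pooled, smoothed
maximum seizure probability — this record would rank first in a screening
queue. An external model's probabilities can replace the baseline detector
via `--prob-csv` (schema `record_id,channel,epoch_index,probability`), and
`eegsonify evaluate --annotations ann.csv` computes Fleiss' κ with its CI,
majority-vote counts and, given per-record scores, the ROC AUC.

As a calibration anchor: one hour of EEG containing two one-minute
seizures renders to ≈3.2 s of audio at the defaults (3480 s/3000 +
120 s/60), and a seizure-free hour to 1.2 s.

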