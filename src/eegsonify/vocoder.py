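"""Variable-rate phase vocoder: EEG time-compression plus pitch lift.

The renderer turns one EEG channel into one audio track under a per-epoch
speed schedule s(t) ("seconds of EEG per second of audio"). Two couplings
between time and pitch are provided:

``fixed_pitch`` (default)
    The EEG samples are reinterpreted at ``P`` times their sampling rate,
    which lifts every EEG frequency f to an audible P*f and on its own
    would compress time by exactly P. The remaining compression s(t)/P is
    done by a phase vocoder: STFT analysis frames are taken with a
    time-varying analysis hop H_a(t) = H_s * s(t)/P, per-bin phases are
    propagated by instantaneous-frequency estimates (horizontal phase
    coherence), and frames are overlap-added at the fixed synthesis hop
    H_s. Perceived pitch therefore tracks the true EEG frequency content
    regardless of how fast a segment is played.

``coupled``
    Plain variable-rate playback through the time map: frequency f is
    heard at s(t)*f, so faster segments also sound higher.

With the defaults (256-sample Hann window, H_s = 64, P = 64 at a 256 Hz
processing rate) the contract output rate is 16384 Hz and a segment of L
seconds of EEG occupies L/s seconds of audio; the realized duration equals
the time-map total to within one synthesis frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .attention import SpeedSchedule, time_map

logger = logging.getLogger(__name__)

__all__ = ["VocoderConfig", "AudioTrack", "pv_render"]


@dataclass
class VocoderConfig:
    window: int = 256
    synthesis_hop: int = 64
    pitch_lift: int = 64
    mode: str = "fixed_pitch"    # {"fixed_pitch", "coupled"}
    resample_to: float | None = None

    def __post_init__(self):
        if not self.window > self.synthesis_hop > 0:
            raise ValueError("require window > synthesis_hop > 0")
        if self.pitch_lift < 1:
            raise ValueError("pitch_lift must be >= 1")
        if self.mode not in ("fixed_pitch", "coupled"):
            raise ValueError(f"unknown vocoder mode {self.mode!r}")

    @property
    def output_rate_factor(self) -> int:
        return self.pitch_lift


@dataclass
class AudioTrack:
    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


def _render_fixed_pitch(x: np.ndarray, schedule: SpeedSchedule, rate: float,
                        cfg: VocoderConfig) -> np.ndarray:
    N, Hs, P = cfg.window, cfg.synthesis_hop, cfg.pitch_lift
    win = sps.get_window("hann", N, fftbins=True)
    n = x.size
    if n < N:
        raise ValueError(f"signal shorter than one analysis window ({N})")
    omega = 2.0 * np.pi * np.arange(N // 2 + 1) / N  # rad per input sample

    # Analysis frame positions come from the inverse time map: synthesis
    # frame k sits at audio time k*Hs/(P*rate), and its analysis window is
    # centered where the schedule says that much audio has been emitted.
    # This conserves duration exactly even across abrupt speed changes.
    tm = time_map(schedule)
    fs_out = P * rate
    total_audio = min(tm.total_audio, tm.audio_time(n / rate))
    n_frames = max(int(np.ceil(total_audio * fs_out / Hs)), 1)
    tau = np.arange(n_frames) * Hs / fs_out
    positions = np.minimum(tm.eeg_time(tau) * rate, n)
    hops = np.diff(positions)
    # reflect-pad so the last windows read continuous data instead of
    # clamping (clamped repeats would corrupt the phase estimates)
    x = np.concatenate([x, x[-2:-N - 2:-1]])

    out_len = (n_frames - 1) * Hs + N
    out = np.zeros(out_len)
    norm = np.zeros(out_len)
    win_sq = win * win

    prev_phase = None
    synth_phase = None
    for k in range(n_frames):
        i0 = int(round(positions[k]))
        X = np.fft.rfft(x[i0:i0 + N] * win)
        mag = np.abs(X)
        phase = np.angle(X)
        if prev_phase is None:
            synth_phase = phase.copy()
        else:
            ha = hops[k - 1]
            if ha > 1e-6:
                delta = phase - prev_phase - omega * ha
                delta = delta - 2.0 * np.pi * np.round(delta / (2.0 * np.pi))
                inst_freq = omega + delta / ha
            else:  # clamped at the signal end: advance at bin frequency
                inst_freq = omega
            synth_phase = synth_phase + inst_freq * Hs
        prev_phase = phase
        y = np.fft.irfft(mag * np.exp(1j * synth_phase), N) * win
        j0 = k * Hs
        out[j0:j0 + N] += y
        norm[j0:j0 + N] += win_sq
    # floor the OLA normalization so window-edge bins never get amplified
    out /= np.maximum(norm, 1e-2 * norm.max())
    return out


def _render_coupled(x: np.ndarray, schedule: SpeedSchedule, rate: float,
                    cfg: VocoderConfig) -> np.ndarray:
    tm = time_map(schedule)
    fs_out = cfg.pitch_lift * rate
    n_out = int(np.floor(tm.total_audio * fs_out))
    tau = np.arange(n_out) / fs_out
    t_eeg = tm.eeg_time(tau)
    return np.interp(t_eeg * rate, np.arange(x.size), x)


def pv_render(x: np.ndarray, schedule: SpeedSchedule, rate: float,
              cfg: VocoderConfig | None = None, label: str = "") -> AudioTrack:
    """Render one EEG channel (µV samples at ``rate``) to an audio track.

    The schedule must cover the signal; analysis positions past the end
    are clipped to the last full window with a logged warning. Output is
    declared at ``pitch_lift * rate`` Hz (optionally resampled to
    ``cfg.resample_to``); amplitude units follow the input.
    """
    cfg = cfg or VocoderConfig()
    x = np.asarray(x, dtype=float)
    covered = schedule.values.size * schedule.epoch_len * rate
    if covered < x.size - rate * schedule.epoch_len:
        logger.warning("schedule covers %.1f s of a %.1f s signal; "
                       "trailing samples clipped to the last epoch",
                       covered / rate, x.size / rate)
    if cfg.mode == "fixed_pitch":
        y = _render_fixed_pitch(x, schedule, rate, cfg)
    else:
        y = _render_coupled(x, schedule, rate, cfg)
    fs_out = float(cfg.pitch_lift * rate)
    if cfg.resample_to and cfg.resample_to != fs_out:
        y = sps.resample_poly(y, int(cfg.resample_to), int(fs_out))
        fs_out = float(cfg.resample_to)
    return AudioTrack(samples=y, rate=fs_out, label=label)
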