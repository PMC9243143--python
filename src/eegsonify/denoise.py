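"""Probability-modulated spectral subtraction.

Borrowed from speech enhancement: estimate a per-bin background magnitude
spectrum B(f) for each channel (median over STFT frames, robust to a
seizure minority), then attenuate each frame toward that background with a
gain controlled by the seizure probability of its epoch:

    |Y(f, t)| = max(|X(f, t)| - alpha * (1 - p(t)) * B(f),  beta * |X(f, t)|)

Phases are untouched. Frames inside likely seizures (p -> 1) pass through
unchanged; confident background (p -> 0) is pushed down to the
multiplicative floor beta*|X|, which avoids the zeroed bins that cause
musical noise. The STFT geometry (256-sample Hann, hop 64 at 256 Hz)
matches the vocoder's analysis so both stages see the same frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io_formats import Recording

__all__ = [
    "DenoiseConfig",
    "SpectralFrames",
    "stft_frames",
    "istft_frames",
    "estimate_background",
    "subtract",
    "denoise_recording",
]


@dataclass
class DenoiseConfig:
    alpha: float = 1.0
    beta: float = 0.1
    window: int = 256
    hop: int = 64
    enabled: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")


@dataclass
class SpectralFrames:
    """Multichannel STFT: magnitudes/phases are (channels, bins, frames)."""

    magnitudes: np.ndarray
    phases: np.ndarray
    frame_times: np.ndarray      # s, frame centers
    rate: float
    window: int
    hop: int
    n_samples: int = 0           # original signal length, for resynthesis

    @property
    def complex(self) -> np.ndarray:
        return self.magnitudes * np.exp(1j * self.phases)


def _stft_object(rate: float, window: int, hop: int) -> "sps.ShortTimeFFT":
    win = sps.get_window("hann", window, fftbins=True)
    return sps.ShortTimeFFT(win, hop=hop, fs=rate, fft_mode="onesided")


def stft_frames(rec: Recording, cfg: DenoiseConfig | None = None) -> SpectralFrames:
    cfg = cfg or DenoiseConfig()
    stft = _stft_object(rec.rate, cfg.window, cfg.hop)
    Z = stft.stft(rec.samples, axis=1)          # ch x bins x frames
    times = stft.t(rec.n_samples)
    return SpectralFrames(
        magnitudes=np.abs(Z), phases=np.angle(Z), frame_times=times,
        rate=rec.rate, window=cfg.window, hop=cfg.hop,
        n_samples=rec.n_samples)


def istft_frames(frames: SpectralFrames) -> np.ndarray:
    stft = _stft_object(frames.rate, frames.window, frames.hop)
    return stft.istft(frames.complex, k1=frames.n_samples)


def estimate_background(frames: SpectralFrames) -> np.ndarray:
    """Per-channel, per-bin median magnitude across frames (channels x bins)."""
    if frames.magnitudes.shape[-1] < 10:
        raise ValueError("need at least 10 frames to estimate background")
    return np.median(frames.magnitudes, axis=-1)


def subtract(frames: SpectralFrames, background: np.ndarray,
             pooled_p: np.ndarray, alpha: float = 1.0, beta: float = 0.1,
             epoch_len: float = 1.0) -> SpectralFrames:
    """Apply the probability-gated subtraction; returns new frames.

    ``pooled_p`` is the per-epoch pooled seizure probability; each frame
    takes the probability of the epoch containing its center time.
    """
    if background.shape != frames.magnitudes.shape[:2]:
        raise ValueError(
            f"background shape {background.shape} does not match frames "
            f"{frames.magnitudes.shape[:2]}")
    pooled_p = np.asarray(pooled_p, dtype=float)
    idx = np.clip((frames.frame_times / epoch_len).astype(int),
                  0, pooled_p.size - 1)
    p = pooled_p[idx]                                      # per frame
    X = frames.magnitudes
    removed = alpha * (1.0 - p)[None, None, :] * background[:, :, None]
    Y = np.maximum(X - removed, beta * X)
    return SpectralFrames(
        magnitudes=Y, phases=frames.phases.copy(),
        frame_times=frames.frame_times, rate=frames.rate,
        window=frames.window, hop=frames.hop, n_samples=frames.n_samples)


def denoise_recording(rec: Recording, pooled_p: np.ndarray,
                      cfg: DenoiseConfig | None = None,
                      epoch_len: float = 1.0) -> Recording:
    """STFT -> background estimate -> gated subtraction -> resynthesis."""
    cfg = cfg or DenoiseConfig()
    if not cfg.enabled:
        return rec
    frames = stft_frames(rec, cfg)
    bg = estimate_background(frames)
    out = subtract(frames, bg, pooled_p, cfg.alpha, cfg.beta, epoch_len)
    samples = istft_frames(out)
    return Recording(list(rec.channel_labels), rec.rate, samples,
                     montage=rec.montage, start_time=rec.start_time)
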