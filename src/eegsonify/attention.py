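"""AI attention signal: pooling, smoothing, reshaping and the speed schedule.

The seizure-probability trace (one value per channel per 1 s epoch) drives
the variable time-compression rate of the sonification. High-probability
epochs are played slowly (speed factor down to ``s_min`` seconds of EEG per
second of audio) and low-probability background is raced through at up to
``s_max``. The record-level probabilistic score pools the trace by taking
the maximum over channels and then, after a 60 s moving average, over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ProbabilityTrace",
    "AttentionConfig",
    "SpeedSchedule",
    "TimeMap",
    "smooth",
    "record_score",
    "reshape",
    "speed_schedule",
    "time_map",
    "attention_pipeline",
]


@dataclass
class ProbabilityTrace:
    """Per-channel seizure probabilities on a 1 s epoch grid.

    ``matrix`` has shape (channels, epochs), values in [0, 1].
    """

    matrix: np.ndarray
    channels: list[str]
    epoch_len: float = 1.0

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != len(self.channels):
            raise ValueError("one row per channel required")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.matrix.shape[1]

    def pooled(self) -> np.ndarray:
        """Max over channels, one value per epoch."""
        return self.matrix.max(axis=0)


@dataclass
class AttentionConfig:
    s_min: float = 60.0
    s_max: float = 3000.0
    reshaping: str = "none"          # {"none", "uniform", "ushape"}
    smooth_window: float = 60.0      # seconds
    interpolation: str = "geometric"  # {"geometric", "linear"}

    def __post_init__(self):
        if not 1 <= self.s_min < self.s_max:
            raise ValueError("require 1 <= s_min < s_max")
        if self.reshaping not in ("none", "uniform", "ushape"):
            raise ValueError(f"unknown reshaping {self.reshaping!r}")
        if self.interpolation not in ("geometric", "linear"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


@dataclass
class SpeedSchedule:
    """Per-epoch speed factor s(t): seconds of EEG per second of audio."""

    values: np.ndarray
    epoch_len: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 1):
            raise ValueError("speed factors must be >= 1")


@dataclass
class TimeMap:
    """Monotone EEG-time -> audio-time map induced by a speed schedule.

    ``knots_eeg[k]`` maps to ``knots_audio[k]``; both start at 0 and the
    map is piecewise linear (constant speed within each epoch).
    """

    knots_eeg: np.ndarray
    knots_audio: np.ndarray

    @property
    def total_audio(self) -> float:
        return float(self.knots_audio[-1])

    def audio_time(self, t_eeg) -> np.ndarray:
        return np.interp(t_eeg, self.knots_eeg, self.knots_audio)

    def eeg_time(self, t_audio) -> np.ndarray:
        return np.interp(t_audio, self.knots_audio, self.knots_eeg)


def smooth(values: np.ndarray, window: float = 60.0,
           epoch_len: float = 1.0) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available epochs."""
    values = np.asarray(values, dtype=float)
    w = max(int(round(window / epoch_len)), 1)
    if w == 1:
        return values.copy()
    kernel = np.ones(w)
    num = np.convolve(values, kernel, mode="same")
    cnt = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / cnt


def record_score(trace: ProbabilityTrace, window: float = 60.0) -> float:
    """Record-level seizure probability: max over channels, then the max
    over time of the ``window``-second smoothed pooled trace."""
    if trace.n_epochs == 0:
        raise ValueError("empty trace")
    return float(np.max(smooth(trace.pooled(), window, trace.epoch_len)))


def reshape(pooled: np.ndarray, mode: str = "none") -> np.ndarray:
    """Order-preserving redistribution of the pooled probabilities.

    ``none``    identity.
    ``uniform`` empirical-CDF rank transform: value i becomes its midrank
                (r_i - 0.5)/n, flattening the distribution to uniform.
    ``ushape``  uniform ranks pushed through the Beta(1/2, 1/2) quantile
                function, concentrating mass near 0 and 1.
    """
    pooled = np.asarray(pooled, dtype=float)
    if mode == "none":
        return pooled.copy()
    ranks = sstats.rankdata(pooled, method="average")
    uniform = (ranks - 0.5) / pooled.size
    if mode == "uniform":
        return uniform
    if mode == "ushape":
        return sstats.beta.ppf(uniform, 0.5, 0.5)
    raise ValueError(f"unknown reshaping mode {mode!r}")


def speed_schedule(pooled: np.ndarray, cfg: AttentionConfig | None = None,
                   epoch_len: float = 1.0) -> SpeedSchedule:
    """Map probabilities to per-epoch speed factors.

    Geometric (default): s(p) = s_max^(1-p) * s_min^p, log-linear in p so
    equal probability increments give equal perceptual rate steps; p=1
    plays at s_min, p=0 at s_max. Linear mode interpolates arithmetically.
    """
    cfg = cfg or AttentionConfig()
    p = np.clip(np.asarray(pooled, dtype=float), 0.0, 1.0)
    if cfg.interpolation == "geometric":
        s = cfg.s_max ** (1.0 - p) * cfg.s_min ** p
    else:
        s = cfg.s_max + p * (cfg.s_min - cfg.s_max)
    return SpeedSchedule(values=s, epoch_len=epoch_len)


def time_map(schedule: SpeedSchedule) -> TimeMap:
    """Cumulative audio time: each epoch of EEG contributes epoch_len/s(t)."""
    d_audio = schedule.epoch_len / schedule.values
    knots_audio = np.concatenate([[0.0], np.cumsum(d_audio)])
    knots_eeg = schedule.epoch_len * np.arange(schedule.values.size + 1.0)
    return TimeMap(knots_eeg=knots_eeg, knots_audio=knots_audio)


def attention_pipeline(trace: ProbabilityTrace,
                       cfg: AttentionConfig | None = None
                       ) -> tuple[np.ndarray, SpeedSchedule, TimeMap]:
    """Pooled -> smoothed -> reshaped probabilities, schedule and time map."""
    cfg = cfg or AttentionConfig()
    pooled = smooth(trace.pooled(), cfg.smooth_window, trace.epoch_len)
    pooled = reshape(pooled, cfg.reshaping)
    sched = speed_schedule(pooled, cfg, trace.epoch_len)
    return pooled, sched, time_map(sched)
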