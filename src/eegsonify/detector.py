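"""Per-second seizure-probability providers.

The sonification pipeline only needs a probability per channel per 1 s
epoch; where those probabilities come from is pluggable. Two providers are
included:

* ``load_probability`` injects traces computed elsewhere (e.g. a trained
  deep seizure-detection model) from the CSV schema in
  :mod:`eegsonify.io_formats`.
* ``baseline_probability`` is a deterministic, training-free detector
  built on the classic rhythmicity/energy signature of neonatal seizures.
  It is not a clinical-grade detector; it exists so the attention
  mechanism can be exercised self-contained.

Baseline score
--------------
For each channel and epoch three features are computed: in-band power,
line length, and rhythmicity (the largest normalized autocorrelation peak
at lags 0.25-2 s of a context window centered on the epoch). Power and
line length are standardized per record with a median/MAD robust z-score;
rhythmicity is standardized the same way so a uniformly rhythmic record
does not saturate. The probability is a logistic squash of a fixed
weighted sum of the three standardized features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import ProbabilityTrace
from .io_formats import Recording, read_probability_csv

__all__ = [
    "DetectorConfig",
    "epoch_features",
    "baseline_probability",
    "load_probability",
]


@dataclass
class DetectorConfig:
    epoch_len: float = 1.0
    context: float = 4.0          # s, window for autocorrelation features
    lag_range: tuple[float, float] = (0.25, 2.0)
    w_rhythm: float = 1.2
    w_power: float = 1.0
    w_linelength: float = 0.5
    bias: float = -3.0
    z_cap: float = 6.0            # robust z-scores clipped to ±z_cap


def epoch_features(rec: Recording, cfg: DetectorConfig | None = None) -> dict[str, np.ndarray]:
    """Per-channel, per-epoch feature arrays (each channels x epochs).

    Returns ``power`` (µV²), ``linelength`` (µV per sample step, summed),
    ``rhythmicity`` (in [0, 1]) and ``sef`` (spectral edge frequency, Hz).
    """
    cfg = cfg or DetectorConfig()
    rate = rec.rate
    ep = int(round(cfg.epoch_len * rate))
    n_epochs = rec.n_samples // ep
    if n_epochs < 1:
        raise ValueError("record shorter than one epoch")
    half_ctx = int(round(cfg.context * rate / 2))

    x = rec.samples[:, : n_epochs * ep]
    segs = x.reshape(rec.n_channels, n_epochs, ep)

    power = np.mean(segs ** 2, axis=2)
    linelength = np.sum(np.abs(np.diff(segs, axis=2)), axis=2)

    # spectral edge frequency (95% power) per epoch
    freqs = np.fft.rfftfreq(ep, 1.0 / rate)
    psd = np.abs(np.fft.rfft(segs - segs.mean(axis=2, keepdims=True),
                             axis=2)) ** 2
    total = psd.sum(axis=2, keepdims=True)
    cum = np.cumsum(psd, axis=2) / np.where(total > 0, total, 1.0)
    sef_idx = np.argmax(cum >= 0.95, axis=2)
    sef = freqs[sef_idx]
    sef[total[..., 0] <= 0] = 0.0

    # rhythmicity: normalized autocorrelation of a context window centered
    # on each epoch (edges reflected), peak over the cardiac-free lag range
    half_ctx = max(min(half_ctx, x.shape[1] // 2), 1)  # short records
    ctx_len = 2 * half_ctx
    # wrap padding keeps edge epochs statistically exchangeable with
    # interior ones (a periodic record yields identical contexts everywhere)
    pad = np.pad(x, ((0, 0), (half_ctx, half_ctx)), mode="wrap")
    mids = np.arange(n_epochs) * ep + ep // 2 + half_ctx
    offsets = np.arange(-half_ctx, half_ctx)
    nfft = int(2 ** np.ceil(np.log2(2 * ctx_len)))
    lo = max(int(cfg.lag_range[0] * rate), 1)
    hi = min(int(cfg.lag_range[1] * rate), ctx_len - 1)
    rhythmicity = np.empty((rec.n_channels, n_epochs))
    chunk = 512  # epochs per FFT batch, bounds working memory
    for c in range(rec.n_channels):
        for t0 in range(0, n_epochs, chunk):
            m = mids[t0:t0 + chunk]
            ctx = pad[c][m[:, None] + offsets[None, :]]
            ctx = ctx - ctx.mean(axis=1, keepdims=True)
            spec = np.fft.rfft(ctx, nfft, axis=1)
            ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :ctx_len]
            ac0 = ac[:, 0]
            peak = ac[:, lo:hi + 1].max(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(ac0 > 0, peak / np.where(ac0 > 0, ac0, 1.0), 0.0)
            rhythmicity[c, t0:t0 + chunk] = np.clip(r, 0.0, 1.0)

    return {"power": power, "linelength": linelength,
            "rhythmicity": rhythmicity, "sef": sef}


def _robust_z(x: np.ndarray, cap: float) -> np.ndarray:
    """Per-channel median/MAD z-score over epochs, clipped to ±cap."""
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    scale = 1.4826 * mad
    scale[scale <= 0] = 1.0
    return np.clip((x - med) / scale, -cap, cap)


def baseline_probability(rec: Recording,
                         cfg: DetectorConfig | None = None) -> ProbabilityTrace:
    """Training-free per-second seizure probability (channels x epochs)."""
    cfg = cfg or DetectorConfig()
    feats = epoch_features(rec, cfg)
    z_power = _robust_z(np.log(feats["power"] + 1e-12), cfg.z_cap)
    z_ll = _robust_z(feats["linelength"], cfg.z_cap)
    z_rhythm = _robust_z(feats["rhythmicity"], cfg.z_cap)
    score = (cfg.w_rhythm * z_rhythm + cfg.w_power * z_power
             + cfg.w_linelength * z_ll + cfg.bias)
    prob = 1.0 / (1.0 + np.exp(-score))
    return ProbabilityTrace(matrix=prob, channels=list(rec.channel_labels),
                            epoch_len=cfg.epoch_len)


def load_probability(path, n_epochs: int | None = None,
                     record_id: str | None = None) -> ProbabilityTrace:
    """Load an externally computed trace; epochs must cover the record.

    If ``record_id`` is omitted the CSV must contain exactly one record.
    With ``n_epochs`` given, a trace with missing or extra epochs is an
    alignment error.
    """
    traces = read_probability_csv(path)
    if record_id is None:
        if len(traces) != 1:
            raise ValueError(
                f"CSV holds {len(traces)} records; specify record_id")
        record_id = next(iter(traces))
    if record_id not in traces:
        raise KeyError(f"record {record_id!r} not in CSV")
    frame = traces[record_id]
    expected = list(range(frame.shape[1]))
    if list(frame.columns) != expected or frame.isna().any().any():
        raise ValueError(f"record {record_id!r} has missing epochs")
    if n_epochs is not None and frame.shape[1] != n_epochs:
        raise ValueError(
            f"trace has {frame.shape[1]} epochs but record has {n_epochs}")
    return ProbabilityTrace(matrix=frame.to_numpy(float),
                            channels=[str(c) for c in frame.index])
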