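"""Standard-format I/O: EDF in, stereo WAV out, CSV annotations and probability traces.

EEG amplitudes are kept in microvolts (µV) throughout the package; audio
samples are floats in [-1, 1].
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "SeizureAnnotation",
    "StereoAudio",
    "EdfFormatError",
    "read_edf",
    "write_edf",
    "derive_montage",
    "DEFAULT_BIPOLAR_PAIRS",
    "write_wav",
    "read_wav",
    "read_annotations",
    "write_annotations",
    "read_probability_csv",
    "write_probability_csv",
]


class EdfFormatError(ValueError):
    """Raised when an EDF file cannot be parsed."""


@dataclass
class Recording:
    """Multichannel EEG segment.

    Parameters
    ----------
    channel_labels : list of str
        Electrode or derivation names, one per channel.
    rate : float
        Sampling frequency in Hz.
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in µV.
    montage : {"referential", "bipolar"}
    start_time : datetime, optional
    """

    channel_labels: list[str]
    rate: float
    samples: np.ndarray
    montage: str = "referential"
    start_time: _dt.datetime | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.montage not in ("referential", "bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.rate


@dataclass
class SeizureAnnotation:
    """Per-annotator seizure events for one record.

    Events are (onset_s, duration_s) pairs, 0-based seconds from record
    start, half-open intervals [onset, onset + duration).
    """

    record_id: str
    annotator_id: str
    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        for onset, dur in self.events:
            if onset < 0:
                raise ValueError(f"negative onset {onset}")
            if dur < 0:
                raise ValueError(f"negative duration {dur}")

    @property
    def has_seizure(self) -> bool:
        """Record-level binary label: any event present."""
        return len(self.events) > 0

    def mask(self, n_epochs: int, epoch_len: float = 1.0) -> np.ndarray:
        """Boolean per-epoch seizure mask of length ``n_epochs``."""
        m = np.zeros(n_epochs, dtype=bool)
        for onset, dur in self.events:
            i0 = int(np.floor(onset / epoch_len))
            i1 = int(np.ceil((onset + dur) / epoch_len))
            m[max(i0, 0):min(i1, n_epochs)] = True
        return m


@dataclass
class StereoAudio:
    """Two-channel audio; samples in [-1, 1]."""

    left: np.ndarray
    right: np.ndarray
    rate: float

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 1:
            raise ValueError("left/right must be equal-length 1-D arrays")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return self.left.size / self.rate

    @property
    def peak(self) -> float:
        if self.left.size == 0:
            return 0.0
        return float(max(np.max(np.abs(self.left)), np.max(np.abs(self.right))))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (amplitudes in µV).

    Channels with mixed sampling rates are resampled by the reader to the
    maximum rate (a warning is logged).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed headers
        raise EdfFormatError(f"cannot parse EDF file {path}: {exc}") from exc

    rates = {raw.info["sfreq"]}
    if len(rates) > 1:  # pragma: no cover - mne resamples internally
        logger.warning("mixed per-channel rates in %s; resampled to max", path)
    data = raw.get_data()  # Volts for EEG channel types
    # mne scales EEG-typed channels to V; non-EEG types may pass through.
    units = np.array([1e6 if raw.info["chs"][i]["unit"] != 0 else 1.0
                      for i in range(len(raw.ch_names))])
    samples = data * units[:, None]
    meas_date = raw.info.get("meas_date")
    start = None
    if meas_date is not None:
        start = _dt.datetime.fromtimestamp(meas_date.timestamp())
    return Recording(
        channel_labels=list(raw.ch_names),
        rate=float(raw.info["sfreq"]),
        samples=samples,
        montage="referential",
        start_time=start,
    )


def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a :class:`Recording` as a 16-bit EDF file.

    One data record per second; the sampling rate must be a positive
    integer. The physical range per channel is set to the observed data
    range, so the round-trip error is bounded by range/2^16.
    """
    rate = rec.rate
    if rate != int(rate) or rate <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(rate)
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / rate))
    data = np.zeros((n_ch, n_rec * rate))
    data[:, : rec.n_samples] = rec.samples

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    start = rec.start_time or _dt.datetime(2000, 1, 1)
    header = b"".join([
        _edf_ascii("0", 8),
        _edf_ascii("X X X X", 80),
        _edf_ascii("Startdate X X X X", 80),
        _edf_ascii(start.strftime("%d.%m.%y"), 8),
        _edf_ascii(start.strftime("%H.%M.%S"), 8),
        _edf_ascii(256 + 256 * n_ch, 8),
        _edf_ascii("", 44),
        _edf_ascii(n_rec, 8),
        _edf_ascii("1", 8),
        _edf_ascii(n_ch, 4),
    ])
    sig_header = b"".join([
        b"".join(_edf_ascii(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_edf_ascii("", 80) for _ in range(n_ch)),
        b"".join(_edf_ascii("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_ascii(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_ch)),
        b"".join(_edf_ascii(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_ch)),
        b"".join(_edf_ascii(dig_min, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii(dig_max, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii("", 80) for _ in range(n_ch)),
        b"".join(_edf_ascii(rate, 8) for _ in range(n_ch)),
        b"".join(_edf_ascii("", 32) for _ in range(n_ch)),
    ])
    # records are channel-major within each 1 s block
    blocks = digital.reshape(n_ch, n_rec, rate).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

#: Default 8-channel bipolar neonatal montage (pairs are configurable; a
#: common double-banana-style reduction over the central electrodes).
DEFAULT_BIPOLAR_PAIRS: list[tuple[str, str]] = [
    ("F4", "C4"), ("C4", "O2"), ("F3", "C3"), ("C3", "O1"),
    ("T4", "C4"), ("C4", "Cz"), ("Cz", "C3"), ("C3", "T3"),
]


def _normalize_label(label: str) -> str:
    """Map vendor-decorated labels like 'EEG Fp1-REF' onto bare '10-20' names."""
    s = label.strip()
    if s.upper().startswith("EEG "):
        s = s[4:]
    for suffix in ("-REF", "-Ref", "-ref", "-LE", "-AVG"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    return s.strip().upper()


def derive_montage(rec: Recording, pairs: list[tuple[str, str]] | None = None) -> Recording:
    """Re-reference a referential recording to bipolar derivations.

    Channel i of the result is ``anode_i - cathode_i`` with label "A-C".
    Label matching ignores case and vendor decorations ('EEG Fp1-REF').
    """
    if pairs is None:
        pairs = DEFAULT_BIPOLAR_PAIRS
    lookup = {_normalize_label(lbl): i for i, lbl in enumerate(rec.channel_labels)}
    out = np.empty((len(pairs), rec.n_samples))
    labels = []
    for k, (anode, cathode) in enumerate(pairs):
        try:
            ia = lookup[_normalize_label(anode)]
            ic = lookup[_normalize_label(cathode)]
        except KeyError as exc:
            raise KeyError(
                f"channel {exc.args[0]!r} not found; available: "
                f"{sorted(lookup)}"
            ) from None
        out[k] = rec.samples[ia] - rec.samples[ic]
        labels.append(f"{anode}-{cathode}")
    return Recording(labels, rec.rate, out, montage="bipolar",
                     start_time=rec.start_time)


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def write_wav(audio: StereoAudio, path, bit_depth: int = 16) -> None:
    """Write stereo PCM WAV (16-bit default, 32-bit float supported)."""
    from scipy.io import wavfile

    stacked = np.column_stack([audio.left, audio.right])
    stacked = np.clip(stacked, -1.0, 1.0)
    if bit_depth == 16:
        wavfile.write(path, int(audio.rate), np.round(stacked * 32767).astype(np.int16))
    elif bit_depth == 32:
        wavfile.write(path, int(audio.rate), stacked.astype(np.float32))
    else:
        raise ValueError("bit_depth must be 16 or 32")


def read_wav(path) -> StereoAudio:
    """Read a stereo WAV back into floats in [-1, 1]."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None].repeat(2, axis=1)
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483647.0
    else:
        data = data.astype(float)
    return StereoAudio(left=data[:, 0], right=data[:, 1], rate=float(rate))


# ---------------------------------------------------------------------------
# CSV annotations and probability traces
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["record_id", "annotator_id", "onset_s", "duration_s"]
PROBABILITY_COLUMNS = ["record_id", "channel", "epoch_index", "probability"]


def _merge_events(events: list[tuple[float, float]]) -> tuple[list[tuple[float, float]], bool]:
    events = sorted(events)
    merged: list[tuple[float, float]] = []
    overlapped = False
    for onset, dur in events:
        if merged and onset < merged[-1][0] + merged[-1][1]:
            prev_on, prev_dur = merged[-1]
            merged[-1] = (prev_on, max(prev_on + prev_dur, onset + dur) - prev_on)
            overlapped = True
        else:
            merged.append((onset, dur))
    return merged, overlapped


def read_annotations(path) -> list[SeizureAnnotation]:
    """Parse an annotation CSV (record_id,annotator_id,onset_s,duration_s).

    A row with empty onset/duration declares an event-free record for that
    annotator. Overlapping events of one annotator are merged with a
    warning; negative durations are an error.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "annotator_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    out = []
    for (rid, aid), grp in df.groupby(["record_id", "annotator_id"], sort=True):
        events = []
        for _, row in grp.iterrows():
            if pd.isna(row["onset_s"]) and pd.isna(row["duration_s"]):
                continue
            onset, dur = float(row["onset_s"]), float(row["duration_s"])
            if dur < 0:
                raise ValueError(
                    f"negative duration {dur} for record {rid}, annotator {aid}")
            events.append((onset, dur))
        events, overlapped = _merge_events(events)
        if overlapped:
            logger.warning("merged overlapping events for record %s annotator %s",
                           rid, aid)
        out.append(SeizureAnnotation(rid, aid, events))
    return out


def write_annotations(annotations: list[SeizureAnnotation], path) -> None:
    rows = []
    for ann in annotations:
        if not ann.events:
            rows.append((ann.record_id, ann.annotator_id, np.nan, np.nan))
        for onset, dur in ann.events:
            rows.append((ann.record_id, ann.annotator_id, onset, dur))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_probability_csv(path) -> dict[str, "pd.DataFrame"]:
    """Parse a probability CSV into one channels x epochs frame per record.

    Schema: record_id,channel,epoch_index,probability. Values outside
    [0, 1] are clamped with a warning.
    """
    df = pd.read_csv(path, dtype={"record_id": str, "channel": str})
    missing = set(PROBABILITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probability CSV missing columns {sorted(missing)}")
    if ((df["probability"] < 0) | (df["probability"] > 1)).any():
        logger.warning("probabilities outside [0, 1] clamped in %s", path)
        df["probability"] = df["probability"].clip(0.0, 1.0)
    out = {}
    for rid, grp in df.groupby("record_id", sort=True):
        pivot = grp.pivot_table(index="channel", columns="epoch_index",
                                values="probability", sort=False)
        out[rid] = pivot
    return out


def write_probability_csv(matrix: np.ndarray, channels: list[str], path,
                          record_id: str = "rec") -> None:
    """Write a channels x epochs probability matrix in the CSV schema."""
    matrix = np.asarray(matrix, dtype=float)
    rows = [
        (record_id, ch, t, matrix[i, t])
        for i, ch in enumerate(channels)
        for t in range(matrix.shape[1])
    ]
    pd.DataFrame(rows, columns=PROBABILITY_COLUMNS).to_csv(path, index=False)
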