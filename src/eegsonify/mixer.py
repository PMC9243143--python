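"""Binaural stereo mixing via interaural time delay (ITD) alone.

Each EEG channel's audio track is placed on a virtual 2D head seen from
above (nasion toward +y, right ear toward +x). The only spatial cue used
is the interaural time delay — the precedence effect — computed from the
Woodworth spherical-head model:

    ITD(theta) = (r / c) * (theta + sin(theta)),   |theta| <= pi/2

with front-back mirroring beyond ±pi/2. Positive ITD means the right ear
leads. Each track is written into both output channels with the lagging
ear delayed by the ITD rounded to whole samples; gains are equal for both
ears (no interaural level difference). The summed mix is peak-normalized
to 0.9 full scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import StereoAudio
from .vocoder import AudioTrack

__all__ = [
    "HeadModel",
    "ELECTRODE_POSITIONS",
    "electrode_position",
    "azimuth",
    "itd",
    "mix",
]


@dataclass
class HeadModel:
    radius: float = 0.0875       # m, adult head used for listening geometry
    sound_speed: float = 343.0   # m/s

    def __post_init__(self):
        if self.radius <= 0 or self.sound_speed <= 0:
            raise ValueError("radius and sound speed must be positive")


def _ring(theta_deg: float, r: float) -> tuple[float, float]:
    th = math.radians(theta_deg)
    return (r * math.sin(th), r * math.cos(th))


#: Planar 10-20 projection on the unit head circle, nasion at +y, right at
#: +x. The outer ring is at radius 1 with 36 deg spacing (Fp1/Fp2 at
#: ±18 deg); the parasagittal rows use the standard intermediate radii.
ELECTRODE_POSITIONS: dict[str, tuple[float, float]] = {
    "FPZ": _ring(0, 1.0), "FP2": _ring(18, 1.0), "F8": _ring(54, 1.0),
    "T4": _ring(90, 1.0), "T6": _ring(126, 1.0), "O2": _ring(162, 1.0),
    "OZ": _ring(180, 1.0), "O1": _ring(-162, 1.0), "T5": _ring(-126, 1.0),
    "T3": _ring(-90, 1.0), "F7": _ring(-54, 1.0), "FP1": _ring(-18, 1.0),
    "FZ": _ring(0, 0.5), "PZ": _ring(180, 0.5), "CZ": (0.0, 0.0),
    "C4": _ring(90, 0.5), "C3": _ring(-90, 0.5),
    "F4": _ring(40, 0.55), "F3": _ring(-40, 0.55),
    "P4": _ring(140, 0.55), "P3": _ring(-140, 0.55),
}


def electrode_position(label: str,
                       table: dict[str, tuple[float, float]] | None = None
                       ) -> tuple[float, float]:
    """2D position for an electrode or a bipolar derivation "A-B".

    Bipolar channels sit at the midpoint of their two electrodes. Unknown
    labels fall back to the vertex (midline) with a KeyError only when a
    component electrode of a derivation is unknown.
    """
    table = table or ELECTRODE_POSITIONS
    key = label.strip().upper()
    if key in table:
        return table[key]
    if "-" in key:
        parts = key.split("-")
        coords = [table[p] for p in parts if p in table]
        if len(coords) != len(parts):
            missing = [p for p in parts if p not in table]
            raise KeyError(f"unknown electrode(s) {missing} in {label!r}")
        x = sum(c[0] for c in coords) / len(coords)
        y = sum(c[1] for c in coords) / len(coords)
        return (x, y)
    raise KeyError(f"unknown electrode {label!r}")


def azimuth(position: tuple[float, float]) -> float:
    """Azimuth in radians from the midline (nasion direction), positive
    to the listener's right; the vertex maps to the midline."""
    x, y = position
    if x == 0 and y == 0:
        return 0.0
    return math.atan2(x, y)


def itd(theta: float, head: HeadModel | None = None) -> float:
    """Woodworth interaural time delay in seconds; antisymmetric in theta,
    mirrored front-to-back beyond ±pi/2."""
    head = head or HeadModel()
    if abs(theta) > math.pi + 1e-12:
        raise ValueError("|theta| must be <= pi")
    eff = abs(theta)
    if eff > math.pi / 2:
        eff = math.pi - eff
    mag = head.radius / head.sound_speed * (eff + math.sin(eff))
    return math.copysign(mag, theta) if theta != 0 else 0.0


def mix(tracks: list[AudioTrack],
        positions: list[tuple[float, float]] | None = None,
        head: HeadModel | None = None,
        normalize: bool = True,
        peak: float = 0.9) -> StereoAudio:
    """Sum tracks into stereo with per-track ear delays.

    ``positions`` defaults to looking the positions up from each track's
    label. Tracks of unequal length are zero-padded to the longest. With
    ``normalize=False`` the raw linear sum is returned (used by tests of
    mixing linearity).
    """
    if not tracks:
        raise ValueError("no tracks to mix")
    rates = {t.rate for t in tracks}
    if len(rates) != 1:
        raise ValueError(f"tracks must share one rate, got {sorted(rates)}")
    rate = rates.pop()
    head = head or HeadModel()
    if positions is None:
        positions = [electrode_position(t.label) for t in tracks]
    if len(positions) != len(tracks):
        raise ValueError("one position per track required")

    delays = []
    for pos in positions:
        d = int(round(itd(azimuth(pos), head) * rate))
        # positive ITD: right ear leads -> left channel delayed by d
        delays.append((max(d, 0), max(-d, 0)))
    max_delay = max(max(dl, dr) for dl, dr in delays)
    n = max(t.samples.size for t in tracks) + max_delay
    left = np.zeros(n)
    right = np.zeros(n)
    for track, (dl, dr) in zip(tracks, delays):
        s = track.samples
        left[dl:dl + s.size] += s
        right[dr:dr + s.size] += s
    if normalize:
        m = max(np.max(np.abs(left)), np.max(np.abs(right)))
        if m > 0:
            scale = peak / m
            left *= scale
            right *= scale
    return StereoAudio(left=left, right=right, rate=rate)
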