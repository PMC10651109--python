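"""Preference index for the two-shelter arena valence assay.

An animal explores a circular arena with an odourised shelter and an
opposite control shelter; occupancy times inside the two shelter zones give

    PI = (time_odour - time_control) / time_total

so +1 is full attraction to the odour shelter and -1 full avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Zone:
    """A disc-shaped shelter zone in arena coordinates (mm)."""

    cx: float
    cy: float
    radius: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius ** 2

    def overlaps(self, other: "Zone") -> bool:
        d = np.hypot(self.cx - other.cx, self.cy - other.cy)
        return d < self.radius + other.radius


@dataclass
class ArenaTrack:
    """Per-frame animal centroid positions with the two shelter zones."""

    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    odour_zone: Zone
    control_zone: Zone

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


@dataclass
class PreferenceResult:
    time_odour_s: float
    time_control_s: float
    time_total_s: float
    pi: float = field(init=False)

    def __post_init__(self) -> None:
        self.pi = preference_index(self.time_odour_s, self.time_control_s,
                                   self.time_total_s)


def occupancy_times(track: ArenaTrack) -> tuple[float, float, float]:
    """Seconds spent in the odour zone, control zone, and the session total."""
    if track.odour_zone.overlaps(track.control_zone):
        raise ValueError("shelter zones overlap")
    if track.x.size == 0:
        raise ValueError("empty track")
    dt = 1.0 / track.frame_rate
    in_odour = track.odour_zone.contains(track.x, track.y)
    in_control = track.control_zone.contains(track.x, track.y)
    return (float(in_odour.sum() * dt), float(in_control.sum() * dt),
            float(track.x.size * dt))


def preference_index(time_odour: float, time_control: float,
                     time_total: float) -> float:
    """PI = (time_odour - time_control) / time_total."""
    if time_total <= 0:
        raise ValueError("time_total must be positive")
    if time_odour < 0 or time_control < 0:
        raise ValueError("zone times must be nonnegative")
    if time_odour + time_control > time_total * (1 + 1e-12):
        raise ValueError("zone times exceed the session total")
    return (time_odour - time_control) / time_total


def session_result(track: ArenaTrack) -> PreferenceResult:
    to, tc, tt = occupancy_times(track)
    return PreferenceResult(to, tc, tt)


def group_pi_certainty(pis: np.ndarray, n_boot: int = 2000,
                       seed: int = 0) -> tuple[float, float]:
    """Group mean PI and the bootstrap certainty that it differs from zero.

    Certainty is the proportion of seeded bootstrap resamples (over animals)
    whose mean lies on the observed side of zero — the deterministic analogue
    of a posterior tail probability.
    """
    vals = np.asarray(pis, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no PI values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    mean = float(vals.mean())
    certainty = float(np.mean(means > 0) if mean > 0 else np.mean(means < 0))
    return mean, certainty


def read_arena_track(path, odour_zone: Zone, control_zone: Zone,
                     frame_rate: float | None = None) -> ArenaTrack:
    """Read an arena track CSV (time_s, x_mm, y_mm)."""
    df = pd.read_csv(path)
    if not {"time_s", "x_mm", "y_mm"}.issubset(df.columns):
        raise ValueError("arena track needs columns time_s, x_mm, y_mm")
    if frame_rate is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        frame_rate = 1.0 / dt
    return ArenaTrack(df["x_mm"].to_numpy(), df["y_mm"].to_numpy(),
                      frame_rate, odour_zone, control_zone)


def write_arena_track(track: ArenaTrack, path) -> None:
    t = np.arange(track.x.size) / track.frame_rate
    pd.DataFrame({"time_s": t, "x_mm": track.x, "y_mm": track.y}).to_csv(
        path, index=False, float_format="%.10g")
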