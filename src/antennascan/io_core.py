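"""Domain types, file formats and configuration for the antennal-sweep pipeline.

All analyses operate on :class:`Trial` objects: one wind-tunnel recording
session of 3D-tracked points (head, two antennal tips, up to six tarsi) at a
fixed frame rate, together with the stimulus protocol describing when and
where the odour stream was presented.

Coordinate frame (fixed to the tunnel): +x to the animal's right of its
initial midline, +y upwind/forward, +z up; units are millimetres and seconds.
Tracking dropouts are carried as explicit per-frame validity flags, never as
silent zeros: short gaps (<= ``interp_max_gap_s``) are linearly interpolated,
longer runs stay invalid and are excluded from window statistics downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

ODOURS = ("colony", "butanol", "linalool", "air_sham")
REQUIRED_POINTS = ("head", "ant_L", "ant_R")
LEG_LABELS = ("R1", "R2", "R3", "L1", "L2", "L3")

TRACKING_COLUMNS = ["frame", "time_s", "label", "x_mm", "y_mm", "z_mm", "valid"]


class MissingPointError(KeyError):
    """A required tracked point label is absent from a tracking table."""


@dataclass
class PointSeries:
    """One tracked point: (n, 3) coordinates in mm plus per-frame validity."""

    xyz: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_frames, 3)")
        if self.valid.shape != (self.xyz.shape[0],):
            raise ValueError("valid must have shape (n_frames,)")
        if not np.all(np.isfinite(self.xyz[self.valid])):
            raise ValueError("coordinates must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    def copy(self) -> "PointSeries":
        return PointSeries(self.xyz.copy(), self.valid.copy())


@dataclass
class StimulusProtocol:
    """Odour stimulus timing and stream-centre geometry for one trial.

    ``stream_x`` is the lateral (x) position of the stream centre line in mm,
    given as piecewise-linear breakpoints ``[(t_s, x_mm), ...]``; a single
    breakpoint means a static stream.  ``stream_z_mm`` is the height of the
    stream axis relative to head level (the stimulus is strongest at about
    head height, hence the default 0).
    """

    onset_s: float
    offset_s: float
    stream_x: Sequence[tuple[float, float]] = ((0.0, 0.0),)
    stream_y_mm: float = 30.0
    stream_z_mm: float = 0.0
    is_sham: bool = False
    static_positions: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_s < self.offset_s:
            raise ValueError("require 0 <= onset_s < offset_s")
        self.stream_x = [(float(t), float(x)) for t, x in self.stream_x]
        if not self.stream_x:
            raise ValueError("stream_x needs at least one breakpoint")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def stream_x_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Lateral stream-centre position (mm) at time(s) t, defined for all t."""
        ts, xs = zip(*self.stream_x)
        return np.interp(t, ts, xs)


@dataclass
class Trial:
    """One recording session: tracked point series plus stimulus protocol."""

    trial_id: str
    animal_id: str
    odour: str
    frame_rate: float
    points: dict[str, PointSeries]
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        if self.odour not in ODOURS:
            raise ValueError(f"unknown odour {self.odour!r}; expected one of {ODOURS}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for label in REQUIRED_POINTS:
            if label not in self.points:
                raise MissingPointError(f"required point {label} absent")
        counts = {p.n_frames for p in self.points.values()}
        if len(counts) != 1:
            raise ValueError(f"point series disagree on frame count: {counts}")
        if self.protocol.offset_s > self.n_frames / self.frame_rate + 1e-9:
            raise ValueError("protocol offset lies beyond trial duration")

    @property
    def n_frames(self) -> int:
        return next(iter(self.points.values())).n_frames

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def leg_labels(self) -> list[str]:
        return [lab for lab in LEG_LABELS if lab in self.points]

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Frame slice [start_s, end_s) on this trial's clock."""
        i0 = int(np.ceil(start_s * self.frame_rate - 1e-9))
        i1 = int(np.ceil(end_s * self.frame_rate - 1e-9))
        return slice(max(i0, 0), min(i1, self.n_frames))


DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 1.0),
    (1.0, 2.0),
    (2.0, 3.0),
    (3.0, 5.0),
    (5.0, 10.0),
)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the pipeline defaults.

    ``pre_window_s = None`` means "same length as the stimulus window", the
    baseline convention used throughout.  Wavelet bands are half-open
    ``[low, high)`` intervals in Hz, non-overlapping and ascending.
    """

    pre_window_s: float | None = None
    heatmap_bins: int = 24
    wavelet_bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    power_bin_s: float = 1.0
    smoothing_window_s: float = 1.0
    step_min_prominence_mm: float = 0.5
    step_min_separation_s: float = 0.15
    pid_prominence_frac: float = 0.02
    kde_bandwidth: float | None = None
    interp_max_gap_s: float = 0.1
    normalize_per_antenna: bool = False
    distance_lateral_only: bool = False
    combined_speed: str = "euclidean"  # or "abs_sum"
    row_count_floor_frac: float = 0.05
    bootstrap_n: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        bands = [(float(lo), float(hi)) for lo, hi in self.wavelet_bands]
        if any(hi <= lo for lo, hi in bands):
            raise ValueError("each band needs low < high")
        for (_, hi_prev), (lo, _) in zip(bands, bands[1:]):
            if lo < hi_prev:
                raise ValueError("bands must be ascending and non-overlapping")
        self.wavelet_bands = tuple(bands)
        for name in ("power_bin_s", "smoothing_window_s", "step_min_separation_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pre_window_s is not None and self.pre_window_s <= 0:
            raise ValueError("pre_window_s must be > 0")
        if self.heatmap_bins < 1:
            raise ValueError("heatmap_bins must be >= 1")
        if self.combined_speed not in ("euclidean", "abs_sum"):
            raise ValueError("combined_speed must be 'euclidean' or 'abs_sum'")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "wavelet_bands" in raw:
            raw["wavelet_bands"] = tuple(tuple(b) for b in raw["wavelet_bands"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["wavelet_bands"] = [list(b) for b in self.wavelet_bands]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# tracking tables


def interpolate_dropouts(point: PointSeries, frame_rate: float,
                         max_gap_s: float = 0.1) -> PointSeries:
    """Fill invalid runs no longer than ``max_gap_s`` by linear interpolation.

    Longer runs, and invalid frames at the series edges, keep their invalid
    flag; downstream window statistics exclude them.
    """
    out = point.copy()
    n = out.n_frames
    max_gap = int(round(max_gap_s * frame_rate))
    invalid = ~out.valid
    if not invalid.any():
        return out
    idx = np.arange(n)
    # contiguous invalid runs
    starts = np.flatnonzero(invalid & ~np.r_[False, invalid[:-1]])
    ends = np.flatnonzero(invalid & ~np.r_[invalid[1:], False])
    for s, e in zip(starts, ends):
        run = e - s + 1
        if s == 0 or e == n - 1 or run > max_gap:
            continue
        for ax in range(3):
            out.xyz[s:e + 1, ax] = np.interp(
                idx[s:e + 1], [s - 1, e + 1], [out.xyz[s - 1, ax], out.xyz[e + 1, ax]]
            )
        out.valid[s:e + 1] = True
    return out


def read_protocol(path: str | Path) -> tuple[StimulusProtocol, dict]:
    """Read a key-value protocol file; returns the protocol and trial metadata."""
    raw = yaml.safe_load(Path(path).read_text())
    stream_x = raw.get("stream_x", 0.0)
    if np.isscalar(stream_x):
        stream_x = [(0.0, float(stream_x))]
    proto = StimulusProtocol(
        onset_s=float(raw["onset_s"]),
        offset_s=float(raw["offset_s"]),
        stream_x=stream_x,
        stream_y_mm=float(raw.get("stream_y_mm", 30.0)),
        stream_z_mm=float(raw.get("stream_z_mm", 0.0)),
        is_sham=bool(raw.get("is_sham", False)),
        static_positions=[tuple(p) for p in raw.get("static_positions", [])],
    )
    meta = {
        "trial_id": str(raw.get("trial_id", Path(path).stem)),
        "animal_id": str(raw.get("animal_id", "unknown")),
        "odour": str(raw.get("odour", "air_sham" if proto.is_sham else "colony")),
        "frame_rate": float(raw.get("frame_rate", 100.0)),
    }
    return proto, meta


def write_protocol(trial: Trial, path: str | Path) -> None:
    p = trial.protocol
    d = {
        "trial_id": trial.trial_id,
        "animal_id": trial.animal_id,
        "odour": trial.odour,
        "frame_rate": trial.frame_rate,
        "onset_s": p.onset_s,
        "offset_s": p.offset_s,
        "stream_x": [list(b) for b in p.stream_x],
        "stream_y_mm": p.stream_y_mm,
        "stream_z_mm": p.stream_z_mm,
        "is_sham": p.is_sham,
        "static_positions": [list(sp) for sp in p.static_positions],
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_trial(path: str | Path, protocol_path: str | Path,
               interp_max_gap_s: float = 0.1) -> Trial:
    """Read a CSV tracking table plus protocol file into a :class:`Trial`.

    The table is long format, one row per frame per point:
    ``frame, time_s, label, x_mm, y_mm, z_mm, valid``.  Missing coordinates
    (empty cells or NaN) mark a frame invalid even if flagged valid.
    """
    df = pd.read_csv(path)
    missing_cols = set(TRACKING_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"tracking table missing columns: {sorted(missing_cols)}")
    proto, meta = read_protocol(protocol_path)

    points: dict[str, PointSeries] = {}
    n_frames = None
    for label, grp in df.groupby("label", sort=False):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"non-monotonic frame index for point {label}")
        xyz = grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        valid = grp["valid"].to_numpy(dtype=bool) & np.all(np.isfinite(xyz), axis=1)
        xyz[~valid] = np.nan
        ps = PointSeries(xyz, valid)
        points[str(label)] = interpolate_dropouts(ps, meta["frame_rate"],
                                                  interp_max_gap_s)
        if n_frames is None:
            n_frames = ps.n_frames
        elif ps.n_frames != n_frames:
            raise ValueError(f"point {label} has {ps.n_frames} frames, expected {n_frames}")

    for label in REQUIRED_POINTS:
        if label not in points:
            raise MissingPointError(f"required point {label} absent")

    return Trial(points=points, protocol=proto, **meta)


def write_trial(trial: Trial, path: str | Path, protocol_path: str | Path | None = None) -> None:
    """Write a trial back to the CSV tracking format (and optionally its protocol)."""
    rows = []
    t = trial.time_s
    for label, ps in trial.points.items():
        rows.append(pd.DataFrame({
            "frame": np.arange(ps.n_frames),
            "time_s": t,
            "label": label,
            "x_mm": ps.xyz[:, 0],
            "y_mm": ps.xyz[:, 1],
            "z_mm": ps.xyz[:, 2],
            "valid": ps.valid.astype(int),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
    if protocol_path is not None:
        write_protocol(trial, protocol_path)


# ---------------------------------------------------------------------------
# result tables and PID traces


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format metric table; requires trial_id, metric, value columns."""
    if results is None or len(results) == 0:
        raise ValueError("empty result set")
    required = {"trial_id", "metric", "value"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    results.to_csv(path, index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_pid_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PID voltage trace CSV (time_s, volts)."""
    df = pd.read_csv(path)
    if not {"time_s", "volts"}.issubset(df.columns):
        raise ValueError("PID trace needs columns time_s, volts")
    return df["time_s"].to_numpy(float), df["volts"].to_numpy(float)


def write_pid_trace(time_s: np.ndarray, volts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": time_s, "volts": volts}).to_csv(
        path, index=False, float_format="%.10g")
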