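"""Angular kinematics of the antennae and head.

Each antenna is approximated as a straight line from the tracked head point
to the tracked antennal tip (the flagellum cannot be bent voluntarily and
passive aerodynamic bending is negligible at these air speeds).  The angular
variables follow the sign conventions used throughout the pipeline:

* azimuth — signed angle of the horizontal projection of the head-to-tip
  vector against the forward head-line (+y): 0 deg parallel to the head-line,
  negative to the animal's left, positive to the right;
* elevation — signed angle of the head-to-tip vector against the horizontal
  plane at head height: negative below head level, positive above;
* heading — signed angle of the tether-to-head vector against the tunnel
  midline (+y), same left/right sign convention; its absolute value measures
  deviation from straight-ahead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import Trial


@dataclass
class AngleSeries:
    """Per-antenna azimuth/elevation in degrees, one value per frame."""

    azimuth_L: np.ndarray
    azimuth_R: np.ndarray
    elevation_L: np.ndarray
    elevation_R: np.ndarray
    valid_L: np.ndarray
    valid_R: np.ndarray
    frame_rate: float

    def azimuth(self, antenna: str) -> np.ndarray:
        return self.azimuth_L if antenna == "L" else self.azimuth_R

    def elevation(self, antenna: str) -> np.ndarray:
        return self.elevation_L if antenna == "L" else self.elevation_R

    def valid(self, antenna: str) -> np.ndarray:
        return self.valid_L if antenna == "L" else self.valid_R


@dataclass
class HeadingSeries:
    heading: np.ndarray          # deg, negative left / positive right
    absolute_heading: np.ndarray  # |heading|
    valid: np.ndarray
    frame_rate: float


@dataclass
class NormalizedCoords:
    """Head-centred antennal tip coordinates scaled to the within-trial maxima.

    After scaling, |x|, |y|, |z| <= 1 on every valid frame and the head sits
    at the origin; the scale factor approximates the antennal length in mm.
    """

    xyz_L: np.ndarray
    xyz_R: np.ndarray
    valid_L: np.ndarray
    valid_R: np.ndarray
    axis_scale_mm: np.ndarray   # per-axis scaling used, shape (3,) or (2, 3)
    scale_factor_mm: float      # max head-to-tip distance, ~ antennal length
    frame_rate: float

    def xyz(self, antenna: str) -> np.ndarray:
        return self.xyz_L if antenna == "L" else self.xyz_R

    def valid(self, antenna: str) -> np.ndarray:
        return self.valid_L if antenna == "L" else self.valid_R


@dataclass
class SpeedSeries:
    """Angular speeds in deg/s per frame, per antenna."""

    azimuth_speed_L: np.ndarray
    azimuth_speed_R: np.ndarray
    elevation_speed_L: np.ndarray
    elevation_speed_R: np.ndarray
    combined_L: np.ndarray
    combined_R: np.ndarray
    valid_L: np.ndarray
    valid_R: np.ndarray
    frame_rate: float

    def combined(self, antenna: str) -> np.ndarray:
        return self.combined_L if antenna == "L" else self.combined_R


def _angles_one(head: np.ndarray, tip: np.ndarray,
                valid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vec = tip - head
    horiz = np.hypot(vec[:, 0], vec[:, 1])
    length = np.linalg.norm(vec, axis=1)
    ok = valid & (length > 1e-12)
    az = np.degrees(np.arctan2(vec[:, 0], vec[:, 1]))
    el = np.degrees(np.arctan2(vec[:, 2], horiz))
    az[~ok] = np.nan
    el[~ok] = np.nan
    return az, el, ok


def antennal_angles(trial: Trial) -> AngleSeries:
    """Azimuth and elevation of both antennae from head and tip tracks.

    Frames where head or tip is invalid, or where the head-to-tip vector is
    degenerate (zero length), are flagged invalid and carry NaN angles.
    """
    head = trial.points["head"]
    out = {}
    for side in ("L", "R"):
        tip = trial.points[f"ant_{side}"]
        valid = head.valid & tip.valid
        az, el, ok = _angles_one(head.xyz, tip.xyz, valid)
        out[side] = (az, el, ok)
    return AngleSeries(
        azimuth_L=out["L"][0], azimuth_R=out["R"][0],
        elevation_L=out["L"][1], elevation_R=out["R"][1],
        valid_L=out["L"][2], valid_R=out["R"][2],
        frame_rate=trial.frame_rate,
    )


def heading(trial: Trial, tether_xy: tuple[float, float]) -> HeadingSeries:
    """Heading of the tether-to-head line against the tunnel midline (+y)."""
    head = trial.points["head"]
    dx = head.xyz[:, 0] - tether_xy[0]
    dy = head.xyz[:, 1] - tether_xy[1]
    ok = head.valid & (np.hypot(dx, dy) > 1e-12)
    h = np.degrees(np.arctan2(dx, dy))
    h[~ok] = np.nan
    return HeadingSeries(heading=h, absolute_heading=np.abs(h), valid=ok,
                         frame_rate=trial.frame_rate)


def normalize_coords(trial: Trial, per_antenna: bool = False) -> NormalizedCoords:
    """Head-centre the antennal tips and scale each axis to its within-trial max.

    By default the per-axis maxima are taken jointly over both antennae so
    left/right positions stay comparable; ``per_antenna=True`` scales each
    antenna by its own maxima.  An axis with zero maximum (no motion and no
    offset) passes through unscaled.
    """
    head = trial.points["head"]
    centred = {}
    for side in ("L", "R"):
        tip = trial.points[f"ant_{side}"]
        valid = head.valid & tip.valid
        c = tip.xyz - head.xyz
        c[~valid] = np.nan
        centred[side] = (c, valid)

    both = np.vstack([centred["L"][0], centred["R"][0]])
    lengths = np.linalg.norm(both, axis=1)
    scale_factor = float(np.nanmax(lengths)) if np.any(np.isfinite(lengths)) else 0.0

    def axis_max(arr: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            m = np.nanmax(np.abs(arr), axis=0)
        m = np.where(np.isfinite(m) & (m > 0), m, 1.0)  # zero-range axis: unscaled
        return m

    if per_antenna:
        scales = np.stack([axis_max(centred["L"][0]), axis_max(centred["R"][0])])
        xyz_L = centred["L"][0] / scales[0]
        xyz_R = centred["R"][0] / scales[1]
    else:
        scales = axis_max(both)
        xyz_L = centred["L"][0] / scales
        xyz_R = centred["R"][0] / scales

    return NormalizedCoords(
        xyz_L=xyz_L, xyz_R=xyz_R,
        valid_L=centred["L"][1], valid_R=centred["R"][1],
        axis_scale_mm=scales, scale_factor_mm=scale_factor,
        frame_rate=trial.frame_rate,
    )


def _rate(series: np.ndarray, frame_rate: float, wrap: bool = False) -> np.ndarray:
    """Forward-difference rate per frame; last frame repeats the previous rate."""
    d = np.diff(series)
    if wrap:
        d = (d + 180.0) % 360.0 - 180.0
    r = np.empty_like(series)
    r[:-1] = d * frame_rate
    r[-1] = r[-2] if len(r) > 1 else np.nan
    return r


def angular_speed(angles: AngleSeries, combined: str = "euclidean") -> SpeedSeries:
    """Frame-to-frame angular speeds at the native frame rate.

    Combined speed is the Euclidean norm of the azimuth and elevation rates
    (``combined="abs_sum"`` uses |az| + |el| instead).  No smoothing is
    applied; smoothing is explicit via :func:`smooth`.
    """
    if angles.azimuth_L.shape[0] < 2:
        raise ValueError("need at least 2 frames for speeds")
    out = {}
    for side in ("L", "R"):
        az = np.abs(_rate(angles.azimuth(side), angles.frame_rate, wrap=True))
        el = np.abs(_rate(angles.elevation(side), angles.frame_rate))
        if combined == "euclidean":
            comb = np.hypot(az, el)
        elif combined == "abs_sum":
            comb = az + el
        else:
            raise ValueError("combined must be 'euclidean' or 'abs_sum'")
        ok = angles.valid(side) & np.isfinite(comb)
        out[side] = (az, el, comb, ok)
    return SpeedSeries(
        azimuth_speed_L=out["L"][0], azimuth_speed_R=out["R"][0],
        elevation_speed_L=out["L"][1], elevation_speed_R=out["R"][1],
        combined_L=out["L"][2], combined_R=out["R"][2],
        valid_L=out["L"][3], valid_R=out["R"][3],
        frame_rate=angles.frame_rate,
    )


def smooth(series: np.ndarray, window_s: float, frame_rate: float) -> np.ndarray:
    """Centred moving average; windows shrink symmetrically at the edges.

    NaNs are ignored within each window (a window of all-NaN yields NaN).
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    win = max(int(round(window_s * frame_rate)), 1)
    if win > n:
        raise ValueError(f"window of {win} frames longer than series of {n}")
    half = win // 2
    finite = np.isfinite(series)
    vals = np.where(finite, series, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out
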