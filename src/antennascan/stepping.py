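"""Step detection and walking statistics from tracked tarsi.

Single steps are identified as peaks in a tarsus's y coordinate (forward
motion during the swing phase).  The trial-level stepping rate is the mean
of the four front/middle legs' instantaneous rates (L1, L2, R1, R2 — the
reliably tracked legs), each normalised by its own within-trial mean.  The
6x6 leg-speed correlation matrix summarises inter-leg coordination; a double
tripod gait shows up as high correlations within each tripod (L1-R2-L3 and
R1-L2-R3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io_core import LEG_LABELS, Trial

FRONT_LEGS = ("L1", "L2", "R1", "R2")
PAUSE_GAP_S = 2.0  # no step for this long reads as not walking


@dataclass
class StepSeries:
    """Per-leg step times plus the normalised mean stepping rate per frame."""

    step_times: dict[str, np.ndarray]
    rate: dict[str, np.ndarray]           # raw instantaneous rate, Hz
    normalized_rate: dict[str, np.ndarray]
    mean_normalized_rate: np.ndarray
    time_s: np.ndarray


@dataclass
class LegCorrelationMatrix:
    values: np.ndarray   # 6x6, ordered as labels
    labels: tuple[str, ...]


def detect_steps(tarsus_y: np.ndarray, frame_rate: float,
                 min_prominence: float = 0.5,
                 min_separation_s: float = 0.15) -> np.ndarray:
    """Step times (s) as prominence/separation-filtered peaks in forward motion.

    Defaults suit slow walking around 2 Hz at 100 fps tracking; both
    thresholds are configurable.  An empty result is allowed (standing leg).
    """
    y = np.asarray(tarsus_y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 frames for step detection")
    finite = np.isfinite(y)
    yf = y.copy()
    if not finite.all():
        yf[~finite] = np.interp(np.flatnonzero(~finite), np.flatnonzero(finite),
                                y[finite]) if finite.any() else 0.0
    distance = max(int(round(min_separation_s * frame_rate)), 1)
    peaks, _ = find_peaks(yf, prominence=min_prominence, distance=distance)
    return peaks / frame_rate


def _instantaneous_rate(steps: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    """Zero-order-hold reciprocal inter-step interval, 0 during pauses.

    Frames inside an inter-step interval carry 1/interval; intervals longer
    than ``PAUSE_GAP_S`` count as pauses (rate 0).  Frames before the first
    or after the last step extend the nearest interval's rate while within
    ``PAUSE_GAP_S`` of that step, and are 0 beyond.
    """
    rate = np.zeros_like(time_s)
    if steps.size < 2:
        return np.full_like(time_s, np.nan)
    intervals = np.diff(steps)
    rates = np.where(intervals <= PAUSE_GAP_S, 1.0 / intervals, 0.0)
    k = np.searchsorted(steps, time_s, side="right") - 1
    inside = (k >= 0) & (k < intervals.size)
    rate[inside] = rates[k[inside]]
    before = time_s < steps[0]
    rate[before] = np.where(steps[0] - time_s[before] <= PAUSE_GAP_S, rates[0], 0.0)
    after = time_s >= steps[-1]
    rate[after] = np.where(time_s[after] - steps[-1] <= PAUSE_GAP_S, rates[-1], 0.0)
    return rate


def stepping_rate(trial: Trial, min_prominence: float = 0.5,
                  min_separation_s: float = 0.15) -> StepSeries:
    """Mean normalised instantaneous stepping rate of the four front legs.

    Each leg's rate series is normalised by its within-trial mean; legs with
    fewer than 2 steps contribute missing values and drop out of the mean.
    """
    t = trial.time_s
    step_times: dict[str, np.ndarray] = {}
    rate: dict[str, np.ndarray] = {}
    norm: dict[str, np.ndarray] = {}
    for leg in FRONT_LEGS:
        if leg not in trial.points:
            continue
        ps = trial.points[leg]
        y = np.where(ps.valid, ps.xyz[:, 1], np.nan)
        steps = detect_steps(y, trial.frame_rate, min_prominence, min_separation_s)
        step_times[leg] = steps
        r = _instantaneous_rate(steps, t)
        rate[leg] = r
        mean_r = np.nanmean(r) if np.isfinite(r).any() else np.nan
        norm[leg] = r / mean_r if np.isfinite(mean_r) and mean_r > 0 else np.full_like(r, np.nan)
    if not norm:
        raise ValueError("no front legs (L1, L2, R1, R2) tracked")
    stacked = np.vstack(list(norm.values()))
    with np.errstate(invalid="ignore"):
        mean_norm = np.nanmean(stacked, axis=0)
    return StepSeries(step_times=step_times, rate=rate, normalized_rate=norm,
                      mean_normalized_rate=mean_norm, time_s=t)


def leg_speed_correlations(trial: Trial) -> LegCorrelationMatrix:
    """Pairwise Pearson correlations of frame-to-frame 3-D leg speeds.

    Rows/columns follow R1–R3 then L1–L3.  A leg with constant speed (or
    missing) yields NaN in its row and column; the diagonal is 1 for any
    tracked leg.
    """
    labels = LEG_LABELS
    speeds = []
    for leg in labels:
        if leg not in trial.points:
            speeds.append(None)
            continue
        ps = trial.points[leg]
        xyz = np.where(ps.valid[:, None], ps.xyz, np.nan)
        d = np.diff(xyz, axis=0)
        speeds.append(np.linalg.norm(d, axis=1) * trial.frame_rate)
    n = len(labels)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            si, sj = speeds[i], speeds[j]
            if si is None or sj is None:
                continue
            ok = np.isfinite(si) & np.isfinite(sj)
            if ok.sum() < 3:
                continue
            a, b = si[ok], sj[ok]
            if i == j:
                mat[i, j] = 1.0
                continue
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            c = np.corrcoef(a, b)[0, 1]
            mat[i, j] = mat[j, i] = c
    return LegCorrelationMatrix(values=mat, labels=labels)
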