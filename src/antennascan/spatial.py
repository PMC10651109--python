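"""Spatial sampling statistics of antennal tip positions.

Covers occupancy heat maps and kernel density curves of the normalized tip
coordinates, distance to the odour-stream centre line, per-antenna and
overall sweeping ranges, odour-induced change metrics against a pre-stimulus
baseline, sham correction, the responsive-antenna labelling that captures
the local-sampling / large-scale-scanning trade-off, and the correlation of
tip motion with a moving stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import StimulusProtocol
from .kinematics import NormalizedCoords

PLANES = {"xy": (0, 1), "xz": (0, 2)}


@dataclass
class OccupancyMap:
    """2-D histogram of normalized tip positions; values sum to 1."""

    values: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    plane: str


@dataclass
class ChangeSeries:
    """A metric expressed as difference from its pre-stimulus mean.

    ``window_means`` holds means of the change over named windows
    (pre / odour / post); the pre-window mean is 0 by construction in the
    uncorrected form.  A window with more than half its frames invalid is
    reported as NaN.
    """

    metric: str
    time_s: np.ndarray
    change: np.ndarray
    onset_s: float
    window_s: float = 0.0
    window_means: dict[str, float] = field(default_factory=dict)
    sham_corrected: bool = False


@dataclass
class ResponsiveLabel:
    """Per-trial responsive-antenna call with its stimulus-free control call."""

    trial_id: str
    responsive: str               # "L" or "R"
    control: str                  # same labelling on the pre-stimulus split
    distance_change: dict[str, float]
    control_distance_change: dict[str, float]
    tied: bool = False


def occupancy_map(coords: NormalizedCoords, window: slice, plane: str = "xy",
                  bins: int = 24, extent: float = 1.0) -> OccupancyMap:
    """Joint occupancy histogram of both antennal tips over a frame window.

    Bin edges span [-extent, extent] on each axis (extent=1 for within-trial
    normalized coordinates; pass the cross-trial maximum for pooled maps).
    Values are proportions of the valid observations, summing to 1.
    """
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {sorted(PLANES)}")
    ax0, ax1 = PLANES[plane]
    pts = []
    for side in ("L", "R"):
        xyz = coords.xyz(side)[window]
        ok = coords.valid(side)[window]
        pts.append(xyz[ok][:, [ax0, ax1]])
    pts = np.vstack(pts)
    if pts.shape[0] == 0:
        raise ValueError("no valid frames in window")
    edges = np.linspace(-extent, extent, bins + 1)
    h, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
    return OccupancyMap(values=h / h.sum(), x_edges=xe, y_edges=ye, plane=plane)


def density_curve(values: np.ndarray, bandwidth: float | None = None,
                  grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel probability density of a 1-D coordinate sample.

    ``bandwidth`` is the kernel standard deviation in coordinate units;
    ``None`` uses Scott's rule.  The curve integrates to 1 (the grid is
    padded by three bandwidths so no mass is cut off).  Zero-variance input
    with automatic bandwidth is an error prompting an explicit bandwidth.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 points for a density curve")
    sd = values.std(ddof=1)
    if bandwidth is None:
        if sd == 0:
            raise ValueError("zero-variance input: supply an explicit bandwidth")
        kde = stats.gaussian_kde(values)
        bw = kde.factor * sd
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        bw = float(bandwidth)
        if sd == 0:  # gaussian_kde cannot handle degenerate samples
            grid_ = grid if grid is not None else np.linspace(
                values[0] - 4 * bw, values[0] + 4 * bw, 512)
            dens = np.exp(-0.5 * ((np.asarray(grid_) - values[0]) / bw) ** 2)
            dens /= bw * np.sqrt(2 * np.pi)
            return np.asarray(grid_), dens
        kde = stats.gaussian_kde(values, bw_method=bw / sd)
    if grid is None:
        grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, 512)
    return np.asarray(grid), kde(np.asarray(grid))


def distance_to_stream(coords: NormalizedCoords, protocol: StimulusProtocol,
                       lateral_only: bool = False) -> dict[str, np.ndarray]:
    """Per-frame distance of each tip to the stream centre line, per antenna.

    The stream centre is a line parallel to y at lateral position
    ``stream_x(t)`` and height ``stream_z_mm`` (head level by default), so
    the perpendicular distance lives in the x-z plane.  The stream position
    is mapped into the normalized frame with the same per-axis scales used
    for the coordinates.  ``lateral_only`` reduces to |x_tip - x_stream|.
    """
    if protocol is None:
        raise ValueError("protocol required for distance to stream")
    n = coords.xyz_L.shape[0]
    t = np.arange(n) / coords.frame_rate
    sx_mm = np.asarray(protocol.stream_x_at(t), dtype=float)
    out = {}
    for i, side in enumerate(("L", "R")):
        scales = (coords.axis_scale_mm[i] if coords.axis_scale_mm.ndim == 2
                  else coords.axis_scale_mm)
        sx = sx_mm / scales[0]
        sz = protocol.stream_z_mm / scales[2]
        xyz = coords.xyz(side)
        dx = xyz[:, 0] - sx
        if lateral_only:
            d = np.abs(dx)
        else:
            d = np.hypot(dx, xyz[:, 2] - sz)
        d[~coords.valid(side)] = np.nan
        out[side] = d
    return out


def antennal_range(x: np.ndarray, window: slice | None = None) -> float:
    """Max-minus-min of one antenna's lateral tip position within a window."""
    vals = np.asarray(x, dtype=float)
    if window is not None:
        vals = vals[window]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 valid frames for a range")
    return float(vals.max() - vals.min())


def overall_range(x_left: np.ndarray, x_right: np.ndarray,
                  window: slice | None = None) -> float:
    """Spread from the left-most to the right-most position of both antennae."""
    xl, xr = np.asarray(x_left, float), np.asarray(x_right, float)
    if window is not None:
        xl, xr = xl[window], xr[window]
    both = np.concatenate([xl, xr])
    both = both[np.isfinite(both)]
    if both.size < 2:
        raise ValueError("need at least 2 valid frames for a range")
    return float(both.max() - both.min())


def _window_mean(change: np.ndarray, sl: slice) -> float:
    seg = change[sl]
    if seg.size == 0:
        return float("nan")
    finite = np.isfinite(seg)
    if finite.sum() <= 0.5 * seg.size:  # >50% invalid: window unusable
        return float("nan")
    return float(seg[finite].mean())


def baseline_change(metric: np.ndarray, time_s: np.ndarray,
                    protocol: StimulusProtocol, metric_name: str = "metric",
                    pre_window_s: float | None = None) -> ChangeSeries:
    """Express a per-frame metric as change from its pre-stimulus mean.

    The baseline window is [onset - w, onset) with w defaulting to the
    stimulus duration; it must lie fully inside the trial.  Window means of
    the change are reported for pre, odour and (if recorded) post windows of
    the same length.
    """
    metric = np.asarray(metric, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    w = protocol.duration_s if pre_window_s is None else float(pre_window_s)
    t0 = protocol.onset_s - w
    if t0 < time_s[0] - 1e-9:
        raise ValueError("pre-stimulus window truncated by trial start")
    pre = (time_s >= t0 - 1e-9) & (time_s < protocol.onset_s - 1e-9)
    if not pre.any():
        raise ValueError("pre-stimulus window contains no frames")
    base_vals = metric[pre]
    base = np.nanmean(base_vals) if np.isfinite(base_vals).any() else np.nan
    change = metric - base

    def sl(a: float, b: float) -> slice:
        idx = np.flatnonzero((time_s >= a - 1e-9) & (time_s < b - 1e-9))
        return slice(idx[0], idx[-1] + 1) if idx.size else slice(0, 0)

    means = {
        "pre": _window_mean(change, sl(t0, protocol.onset_s)),
        "odour": _window_mean(change, sl(protocol.onset_s, protocol.offset_s)),
        "post": _window_mean(change, sl(protocol.offset_s, protocol.offset_s + w)),
    }
    return ChangeSeries(metric=metric_name, time_s=time_s, change=change,
                        onset_s=protocol.onset_s, window_s=w, window_means=means)


def sham_correct(change: ChangeSeries, sham_change: ChangeSeries,
                 tol_frames: int = 2) -> ChangeSeries:
    """Subtract the same animal's sham-trial change, aligned on time from onset.

    Both series must share sampling; small length mismatches (up to
    ``tol_frames`` after alignment) are trimmed, larger ones are an error.
    """
    dt_o = np.median(np.diff(change.time_s))
    dt_s = np.median(np.diff(sham_change.time_s))
    if not np.isclose(dt_o, dt_s, rtol=1e-6):
        raise ValueError("odour and sham trials have different frame intervals")
    # align on time relative to odour onset
    rel_o = change.time_s - change.onset_s
    rel_s = sham_change.time_s - sham_change.onset_s
    shift = int(round((rel_s[0] - rel_o[0]) / dt_o))
    o_start, s_start = max(0, -shift), max(0, shift)
    n = min(len(rel_o) - o_start, len(rel_s) - s_start)
    if abs(len(rel_o) - len(rel_s)) - abs(shift) > tol_frames:
        raise ValueError("odour and sham series lengths differ beyond tolerance")
    if n < 1:
        raise ValueError("no overlap between odour and sham series")
    corrected = np.full_like(change.change, np.nan)
    corrected[o_start:o_start + n] = (change.change[o_start:o_start + n]
                                      - sham_change.change[s_start:s_start + n])
    out = ChangeSeries(metric=change.metric, time_s=change.time_s,
                       change=corrected, onset_s=change.onset_s,
                       window_s=change.window_s, sham_corrected=True)
    out.window_means = {
        k: change.window_means.get(k, np.nan) - sham_change.window_means.get(k, np.nan)
        for k in change.window_means
    }
    return out


def label_responsive(distance_change_L: ChangeSeries,
                     distance_change_R: ChangeSeries,
                     trial_id: str = "") -> ResponsiveLabel:
    """Label the responsive antenna of a trial and its stimulus-free control.

    The responsive antenna is the one whose distance-to-stream shows the
    strongest decrease (most negative odour-window mean change), regardless
    of left/right identity.  The control applies the same rule to two
    consecutive pre-stimulus windows — the later one expressed as change from
    the earlier — quantifying spontaneous asymmetry without any stimulus.
    Ties break to the left antenna with a warning.
    """
    dl = distance_change_L.window_means.get("odour", np.nan)
    dr = distance_change_R.window_means.get("odour", np.nan)
    if not (np.isfinite(dl) and np.isfinite(dr)):
        raise ValueError("both antennae need valid odour-window means")
    tied = bool(np.isclose(dl, dr, rtol=0, atol=1e-12))
    if tied:
        warnings.warn("responsive-antenna tie; breaking to L", stacklevel=2)
    responsive = "L" if dl <= dr else "R"

    ctrl = {}
    for side, cs in (("L", distance_change_L), ("R", distance_change_R)):
        t = cs.time_s
        pre_avail = cs.onset_s - (t[0] if t.size else 0.0)
        # two consecutive stimulus-length windows before onset, shrunk to fit
        half = cs.window_s if (cs.window_s > 0 and 2 * cs.window_s <= pre_avail
                               ) else pre_avail / 2.0
        first = (t >= cs.onset_s - 2 * half) & (t < cs.onset_s - half)
        second = (t >= cs.onset_s - half) & (t < cs.onset_s)
        raw = cs.change  # offsets cancel in the difference of window means
        m1 = np.nanmean(raw[first]) if np.isfinite(raw[first]).any() else np.nan
        m2 = np.nanmean(raw[second]) if np.isfinite(raw[second]).any() else np.nan
        ctrl[side] = m2 - m1
    control = "L" if ctrl["L"] <= ctrl["R"] else "R"

    return ResponsiveLabel(
        trial_id=trial_id, responsive=responsive, control=control,
        distance_change={"L": dl, "R": dr},
        control_distance_change=ctrl, tied=tied,
    )


def stream_following_correlation(tip_x: np.ndarray, stream_x: np.ndarray,
                                 window: slice | None = None) -> float:
    """Pearson correlation between tip and stream lateral positions.

    Returns NaN when either series is constant over the window (the
    correlation is undefined there).
    """
    tx, sx = np.asarray(tip_x, float), np.asarray(stream_x, float)
    if window is not None:
        tx, sx = tx[window], sx[window]
    ok = np.isfinite(tx) & np.isfinite(sx)
    tx, sx = tx[ok], sx[ok]
    if tx.size < 3:
        raise ValueError("need at least 3 paired frames")
    if np.ptp(tx) == 0 or np.ptp(sx) == 0:
        return float("nan")
    return float(stats.pearsonr(tx, sx).statistic)


def bootstrap_mean_interval(values: np.ndarray, n_boot: int = 2000,
                            seed: int = 0, level: float = 0.95
                            ) -> tuple[float, float, float]:
    """Mean with a seeded nonparametric bootstrap percentile interval."""
    vals = np.asarray(values, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(means, [alpha, 1 - alpha])
    return float(vals.mean()), float(lo), float(hi)
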