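"""Plume structure from smoke visualisation and PID fluctuation statistics.

The smoke stage quantifies how an antennal sweep reshapes a laminar stream:
frames are thresholded (one threshold per sequence), cropped to a region of
interest in front of the head, and the hand-drawn body mask removes pixels
belonging to the animal, leaving white pixels that represent smoke only.
Row-wise white-pixel counts give the left-to-right smoke distribution; the
profile width (longest contiguous run of rows above a small floor) is
normalised by a reference frame.

The PID stage treats the photo-ionisation detector voltage as a proxy for
local odorant concentration: alternating minima/maxima are detected, and
per-window fluctuation rate (mean instantaneous frequency of the pooled
extrema) and magnitude (mean positive contrast from each minimum to the next
maximum) are regressed on the concurrent antennal speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import find_peaks

from .kinematics import smooth


@dataclass
class SmokeSequence:
    """Grayscale frames plus the shared threshold, ROI and body masks.

    ``roi`` is (row0, row1, col0, col1), half-open, in frame coordinates.
    ``mask`` is True on body pixels (to be removed); either one mask for the
    sequence or one per frame.
    """

    frames: np.ndarray          # (n, H, W)
    threshold: float
    roi: tuple[int, int, int, int]
    mask: np.ndarray            # (H, W) or (n, H, W), True = body

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, H, W)")
        r0, r1, c0, c1 = self.roi
        _, h, w = self.frames.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError("ROI outside frame bounds")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape not in (self.frames.shape, self.frames.shape[1:]):
            raise ValueError("mask shape must match frames")


@dataclass
class RowProfile:
    counts: np.ndarray       # white pixels per ROI row, left-to-right
    width_rows: int
    normalized_width: float  # width / reference width


def threshold_and_mask(seq: SmokeSequence) -> np.ndarray:
    """Binary ROI frames: white iff >= threshold, inside ROI, outside body mask."""
    r0, r1, c0, c1 = seq.roi
    binary = seq.frames >= seq.threshold
    mask = seq.mask if seq.mask.ndim == 3 else seq.mask[None]
    binary = binary & ~mask
    return binary[:, r0:r1, c0:c1]


def row_counts(binary_roi_frame: np.ndarray) -> np.ndarray:
    """White-pixel count per ROI row (the left-to-right smoke distribution)."""
    if binary_roi_frame.size == 0:
        raise ValueError("empty ROI")
    return binary_roi_frame.sum(axis=1).astype(int)


def _profile_width(counts: np.ndarray, floor_frac: float) -> int:
    """Longest contiguous run of rows with count above floor_frac * max."""
    if counts.max() == 0:
        return 0
    above = counts > floor_frac * counts.max()
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    return best


def row_profile(binary_roi_frame: np.ndarray,
                reference: np.ndarray | None = None,
                floor_frac: float = 0.05) -> RowProfile:
    """Row-wise smoke distribution with width normalised to a reference frame.

    ``reference`` is the binary ROI frame used for normalisation (frame I of
    the sequence by convention); omit it to normalise against the frame
    itself (width 1).  A zero-width reference is an error.
    """
    counts = row_counts(binary_roi_frame)
    width = _profile_width(counts, floor_frac)
    if reference is None:
        ref_width = width
    else:
        ref_width = _profile_width(row_counts(reference), floor_frac)
    if ref_width == 0:
        raise ValueError("reference frame has zero profile width")
    return RowProfile(counts=counts, width_rows=width,
                      normalized_width=width / ref_width)


# ---------------------------------------------------------------------------
# PID fluctuation statistics


@dataclass
class PIDExtrema:
    minima: np.ndarray   # sample indices
    maxima: np.ndarray


def detect_pid_extrema(volts: np.ndarray,
                       min_prominence: float | None = None,
                       prominence_frac: float = 0.02) -> PIDExtrema:
    """Alternating prominence-filtered minima and maxima of a PID trace.

    Default prominence is ``prominence_frac`` of the trace's voltage range.
    Alternation is enforced by keeping the more extreme of any same-type
    neighbours, so after pairing every minimum is followed by a maximum.
    """
    v = np.asarray(volts, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 samples")
    if min_prominence is None:
        rng = np.ptp(v)
        min_prominence = prominence_frac * rng if rng > 0 else np.inf
    maxima, _ = find_peaks(v, prominence=min_prominence)
    minima, _ = find_peaks(-v, prominence=min_prominence)

    events = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = idx if (v[idx] - v[prev]) * kind > 0 else prev
            kept[-1] = (better, kind)
        else:
            kept.append((idx, kind))
    return PIDExtrema(
        minima=np.array([i for i, k in kept if k == -1], dtype=int),
        maxima=np.array([i for i, k in kept if k == +1], dtype=int),
    )


def fluctuation_stats(time_s: np.ndarray, volts: np.ndarray,
                      window: tuple[float, float] | None = None,
                      min_prominence: float | None = None,
                      prominence_frac: float = 0.02,
                      rate_method: str = "instantaneous"
                      ) -> tuple[float, float]:
    """Fluctuation rate (Hz) and magnitude (V) of a PID trace window.

    rate: mean instantaneous frequency of the pooled minima+maxima event
    sequence (reciprocal successive inter-event intervals); the alternative
    ``rate_method="count"`` uses event count / window duration.  magnitude:
    mean positive contrast, i.e. voltage rise from each minimum to its
    subsequent maximum.  Either statistic is NaN when the window holds too
    few events (fewer than 2 extrema for rate, no min-to-max pair for
    magnitude).
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(volts, dtype=float)
    if window is not None:
        sel = (t >= window[0]) & (t < window[1])
        t, v = t[sel], v[sel]
    if t.size < 3:
        return float("nan"), float("nan")
    ex = detect_pid_extrema(v, min_prominence, prominence_frac)
    events = np.sort(np.concatenate([ex.minima, ex.maxima]))
    if events.size < 2:
        rate = float("nan")
    elif rate_method == "count":
        rate = events.size / (t[-1] - t[0])
    else:
        intervals = np.diff(t[events])
        rate = float(np.mean(1.0 / intervals))

    contrasts = []
    for m in ex.minima:
        nxt = ex.maxima[ex.maxima > m]
        if nxt.size:
            contrasts.append(v[nxt[0]] - v[m])
    magnitude = float(np.mean(contrasts)) if contrasts else float("nan")
    return rate, magnitude


def select_speed_windows(speed: np.ndarray, frame_rate: float,
                         n_windows: int = 20, window_s: float = 2.0,
                         smooth_s: float = 0.5,
                         control: bool = False, seed: int = 0
                         ) -> list[tuple[float, float]]:
    """Non-overlapping analysis windows centred on local peaks of antennal speed.

    Peak detection runs on the moving-average-smoothed speed, but callers
    use the windows on the unaltered trace.  All non-overlapping
    peak-centred candidates are gathered (in descending prominence); when
    more than ``n_windows`` fit, the kept set is spread evenly across the
    candidates ranked by window-mean speed, so the selection covers the full
    range of movement regimes rather than only the fastest ones.
    ``control=True`` draws seeded random non-overlapping windows instead
    (for fixed-antenna recordings).  If no peaks exist, evenly spaced
    windows are returned with a warning.
    """
    sp = np.asarray(speed, dtype=float)
    n = sp.size
    duration = n / frame_rate
    if duration <= window_s:
        raise ValueError("speed trace shorter than one window")
    half = window_s / 2.0

    def overlaps(c: float, centres: list[float]) -> bool:
        return any(abs(c - o) < window_s for o in centres)

    def window_mean(c: float) -> float:
        i0 = max(int((c - half) * frame_rate), 0)
        i1 = min(int((c + half) * frame_rate), n)
        return float(np.nanmean(sp[i0:i1]))

    centres: list[float] = []
    if control:
        rng = np.random.default_rng(seed)
        for c in rng.uniform(half, duration - half, size=50 * n_windows):
            if not overlaps(c, centres):
                centres.append(float(c))
            if len(centres) == n_windows:
                break
    else:
        sm = smooth(sp, smooth_s, frame_rate)
        peaks, props = find_peaks(sm, prominence=0.0)
        order = peaks[np.argsort(props["prominences"])[::-1]]
        for p in order:
            c = float(np.clip(p / frame_rate, half, duration - half))
            if not overlaps(c, centres):
                centres.append(c)
        if not centres:
            warnings.warn("no speed peaks; falling back to evenly spaced windows",
                          stacklevel=2)
            k = min(n_windows, int(duration // window_s))
            centres = [half + i * window_s for i in range(k)]
        if len(centres) > n_windows:
            ranked = sorted(centres, key=window_mean)
            pick = np.unique(np.round(
                np.linspace(0, len(ranked) - 1, n_windows)).astype(int))
            centres = [ranked[i] for i in pick]
    return [(c - half, c + half) for c in sorted(centres)]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    slope_ci: tuple[float, float]


def regress_fluctuations_on_speed(mean_speed: np.ndarray, outcome: np.ndarray,
                                  n_boot: int = 2000, seed: int = 0
                                  ) -> RegressionResult:
    """OLS line of a per-window PID statistic on mean antennal speed.

    Returns slope, intercept and Pearson r plus a seeded bootstrap 95%
    percentile interval on the slope (resampling windows).
    """
    x = np.asarray(mean_speed, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 windows")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    slopes = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        if np.ptp(x[idx]) == 0:
            continue
        slopes[b] = stats.linregress(x[idx], y[idx]).slope
    lo, hi = np.nanquantile(slopes, [0.025, 0.975])
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), slope_ci=(float(lo), float(hi)))
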