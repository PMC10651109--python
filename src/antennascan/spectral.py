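"""Spectral analysis of antennal angle time series.

Two complementary views: a one-sided FFT amplitude spectrum for summary
plots, and a continuous-wavelet band-power statistic for time-resolved
changes.  The wavelet power is averaged in 1 s time bins and a fixed set of
frequency bands ([0.5-1), [1-2), [2-3), [3-5), [5-10) Hz by default), then
each band is scaled by its own pre-stimulus average power P0:

    dP/P = (P_t - P0) / P0

so 0 means "as before the stimulus", +1 means a doubling of band power, and
-1 is the hard lower bound (power is nonnegative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .io_core import DEFAULT_BANDS

# Morlet mother with omega0 = 6 in pywt's (bandwidth, centre-frequency)
# parametrisation: envelope exp(-t^2/2) -> B = 2, fc = 6 / (2 pi).
MORLET_OMEGA0 = 6.0
_WAVELET = f"cmor2.0-{MORLET_OMEGA0 / (2 * np.pi):.10f}"
VOICES_PER_OCTAVE = 12


@dataclass
class BandPowerMatrix:
    """Time-binned, frequency-banded, baseline-scaled wavelet power."""

    scaled: np.ndarray        # (n_bins, n_bands) dP/P
    raw: np.ndarray           # (n_bins, n_bands) mean power before scaling
    p0: np.ndarray            # (n_bands,) pre-stimulus average power
    bin_time_s: np.ndarray    # (n_bins,) bin centres
    bands: tuple[tuple[float, float], ...]
    band_n_scales: np.ndarray  # scales per band (band occupancy)
    edge_flag: np.ndarray      # (n_bins, n_bands) True inside the cone of influence
    onset_s: float
    offset_s: float


def fft_spectrum(series: np.ndarray, frame_rate: float,
                 time_s: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT amplitude spectrum of a detrended angle series.

    Amplitudes are scaled so a pure sinusoid of amplitude A shows A at its
    frequency, and (Parseval) the sum of squared amplitudes / 2 recovers the
    signal variance.  Requires >= 64 uniformly sampled frames.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise ValueError("need at least 64 frames for an FFT spectrum")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains invalid frames; interpolate first")
    if time_s is not None:
        dt = np.diff(np.asarray(time_s, float))
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling")
    n = x.size
    X = np.fft.rfft(x - x.mean())
    amp = 2.0 * np.abs(X) / n
    amp[0] = np.abs(X[0]) / n
    if n % 2 == 0:
        amp[-1] = np.abs(X[-1]) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    return freqs, amp


def average_spectra(spectra: Sequence[tuple[np.ndarray, np.ndarray]]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean amplitude spectrum across trials sharing one frequency grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0][0]
    for f, _ in spectra[1:]:
        if f.shape != f0.shape or not np.allclose(f, f0):
            raise ValueError("spectra have different frequency grids")
    return f0, np.mean([a for _, a in spectra], axis=0)


def _scale_grid(frame_rate: float, f_lo: float, f_hi: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced frequencies (12 voices/octave) and matching cwt scales."""
    n_oct = np.log2(f_hi / f_lo)
    k = np.arange(int(np.floor(n_oct * VOICES_PER_OCTAVE)) + 1)
    freqs = f_lo * 2.0 ** (k / VOICES_PER_OCTAVE)
    freqs = freqs[freqs < f_hi * (1 + 1e-9)]
    fc = pywt.central_frequency(_WAVELET)
    scales = fc * frame_rate / freqs
    return freqs, scales


def wavelet_band_power(series: np.ndarray, frame_rate: float,
                       onset_s: float, offset_s: float,
                       bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
                       power_bin_s: float = 1.0,
                       pre_window_s: float | None = None) -> BandPowerMatrix:
    """Continuous-wavelet band power scaled by the pre-stimulus average.

    The mean-removed series is transformed with a Morlet wavelet (omega0=6,
    12 voices per octave over the band range), power |W|^2 is averaged in
    ``power_bin_s`` time bins and the configured frequency bands, and each
    band is expressed as (P_t - P0)/P0 with P0 the band's average power over
    the pre-stimulus window [onset - w, onset).  Bins inside the cone of
    influence are flagged (not masked).  A band with P0 = 0 is reported as
    NaN with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2 * frame_rate:
        raise ValueError("need at least 2 s of frames")
    w = (offset_s - onset_s) if pre_window_s is None else float(pre_window_s)
    if onset_s - w < -1e-9:
        raise ValueError("pre-stimulus window truncated by trial start")
    bands = tuple((float(lo), float(hi)) for lo, hi in bands)
    f_lo = min(lo for lo, _ in bands)
    f_hi = max(hi for _, hi in bands)
    freqs, scales = _scale_grid(frame_rate, f_lo, f_hi)

    # reflection-pad past the largest wavelet's support so the convolution
    # edge transient falls outside the analysed span (edge bins stay flagged)
    pad = int(min(n - 1, np.ceil(3 * scales.max())))
    xp = np.pad(x - x.mean(), pad, mode="reflect", reflect_type="odd")
    coefs, _ = pywt.cwt(xp, scales, _WAVELET, sampling_period=1.0 / frame_rate)
    power = np.abs(coefs[:, pad:pad + n]) ** 2  # (n_scales, n_frames)

    t = np.arange(n) / frame_rate
    bin_idx = np.floor(t / power_bin_s).astype(int)
    n_bins = bin_idx.max() + 1
    bin_centres = (np.arange(n_bins) + 0.5) * power_bin_s

    band_members = [np.flatnonzero((freqs >= lo) & (freqs < hi)) for lo, hi in bands]
    raw = np.full((n_bins, len(bands)), np.nan)
    for b, members in enumerate(band_members):
        if members.size == 0:
            continue
        band_power = power[members].mean(axis=0)
        sums = np.bincount(bin_idx, weights=band_power, minlength=n_bins)
        counts = np.bincount(bin_idx, minlength=n_bins)
        raw[:, b] = sums / np.maximum(counts, 1)

    # approximate Morlet cone of influence: e-folding time sqrt(2)*fc/f
    duration = n / frame_rate
    edge = np.zeros_like(raw, dtype=bool)
    for b, (lo, hi) in enumerate(bands):
        coi_s = np.sqrt(2.0) * pywt.central_frequency(_WAVELET) / lo
        edge[:, b] = (bin_centres < coi_s) | (bin_centres > duration - coi_s)

    pre_bins = (bin_centres >= onset_s - w) & (bin_centres < onset_s)
    if not pre_bins.any():
        raise ValueError("no complete time bins inside the pre-stimulus window")
    p0 = raw[pre_bins].mean(axis=0)
    if edge[pre_bins].any():
        warnings.warn("pre-stimulus window overlaps the cone of influence; "
                      "P0 may carry edge effects (add lead-in time)", stacklevel=2)
    scaled = np.full_like(raw, np.nan)
    for b in range(len(bands)):
        if not np.isfinite(p0[b]) or p0[b] <= 0:
            warnings.warn(f"band {bands[b]} has zero pre-stimulus power; "
                          "reported missing", stacklevel=2)
            continue
        scaled[:, b] = (raw[:, b] - p0[b]) / p0[b]

    return BandPowerMatrix(
        scaled=scaled, raw=raw, p0=p0, bin_time_s=bin_centres, bands=bands,
        band_n_scales=np.array([m.size for m in band_members]),
        edge_flag=edge, onset_s=onset_s, offset_s=offset_s,
    )


def merge_bands(matrix: BandPowerMatrix,
                groups: Sequence[Sequence[int]]) -> BandPowerMatrix:
    """Pool bands by recomputing on raw power, not by averaging ratios.

    Each group of band indices is merged with weights proportional to band
    occupancy (number of wavelet scales), which reproduces the power average
    over the union of scales; P0 is merged the same way before rescaling.
    """
    n_bins = matrix.raw.shape[0]
    new_bands, raw, p0, occ, edge = [], [], [], [], []
    for grp in groups:
        grp = list(grp)
        wts = matrix.band_n_scales[grp].astype(float)
        if wts.sum() == 0:
            raise ValueError("cannot merge empty bands")
        lo = min(matrix.bands[g][0] for g in grp)
        hi = max(matrix.bands[g][1] for g in grp)
        new_bands.append((lo, hi))
        raw.append(matrix.raw[:, grp] @ wts / wts.sum())
        p0.append(float(matrix.p0[grp] @ wts / wts.sum()))
        occ.append(int(wts.sum()))
        edge.append(matrix.edge_flag[:, grp].any(axis=1))
    raw = np.column_stack(raw)
    p0 = np.asarray(p0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (raw - p0) / p0
    scaled[:, p0 <= 0] = np.nan
    return BandPowerMatrix(
        scaled=scaled, raw=raw, p0=p0, bin_time_s=matrix.bin_time_s,
        bands=tuple(new_bands), band_n_scales=np.asarray(occ),
        edge_flag=np.column_stack(edge), onset_s=matrix.onset_s,
        offset_s=matrix.offset_s,
    )


def pool_band_power(matrices: Sequence[BandPowerMatrix], window: str = "during",
                    n_boot: int = 2000, seed: int = 0
                    ) -> dict[tuple[float, float], tuple[float, float, float]]:
    """Band-wise mean dP/P over a named window with bootstrap intervals.

    ``window``: "during" averages bins within [onset, offset); "after"
    averages the post-stimulus window of the same length.  Returns, per
    band, (mean over trials, CI low, CI high) from a seeded nonparametric
    bootstrap over trials.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 trials to pool")
    bands = matrices[0].bands
    for m in matrices[1:]:
        if m.bands != bands:
            raise ValueError("trials have different band definitions")
    per_trial = []
    for m in matrices:
        dur = m.offset_s - m.onset_s
        if window == "during":
            sel = (m.bin_time_s >= m.onset_s) & (m.bin_time_s < m.offset_s)
        elif window == "after":
            sel = (m.bin_time_s >= m.offset_s) & (m.bin_time_s < m.offset_s + dur)
        else:
            raise ValueError("window must be 'during' or 'after'")
        if not sel.any():
            raise ValueError(f"window {window!r} lies outside a trial")
        per_trial.append(np.nanmean(m.scaled[sel], axis=0))
    per_trial = np.vstack(per_trial)  # (n_trials, n_bands)

    rng = np.random.default_rng(seed)
    n_tr = per_trial.shape[0]
    idx = rng.integers(0, n_tr, size=(n_boot, n_tr))
    boot = np.nanmean(per_trial[idx], axis=1)
    lo, hi = np.nanquantile(boot, [0.025, 0.975], axis=0)
    means = np.nanmean(per_trial, axis=0)
    return {band: (float(means[b]), float(lo[b]), float(hi[b]))
            for b, band in enumerate(bands)}
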