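# Methods

`antennascan` analyses how a walking insect's antennae sample an odour
landscape: where the antennal tips spend their time, how far and how fast
they sweep, how their oscillation spectrum changes when an odour arrives,
and how the sweeps themselves reshape the plume they are sampling. This
note records the models and conventions the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinate conventions and kinematic variables

All raw tracking is in a tunnel-fixed frame: +x to the animal's right, +y
upwind (forward), +z up, in millimetres at a fixed frame rate (100 fps by
default). Each antenna is treated as a straight line from the tracked head
point to the tracked tip — flagellum curvature is neglected, since the
animal cannot bend its antenna voluntarily and passive aerodynamic bending
is negligible at the air speeds in question (< 0.2 m s⁻¹).

* **Azimuth** is the signed angle of the horizontal projection of the
  head-to-tip vector against the forward head-line (0° forward, negative
  left, positive right; range (−180°, 180°]).
* **Elevation** is the signed angle against the horizontal plane at head
  height (negative below head level; range [−90°, 90°]).
* **Heading** is the signed angle of the tether-to-head vector against the
  tunnel midline; its absolute value measures deviation from straight ahead.
* **Angular speeds** are forward frame-to-frame differences at the native
  frame rate, with no implicit smoothing; azimuth differences are taken on
  the circle. The **combined speed** is the Euclidean norm of the azimuth
  and elevation rates (a sum-of-absolute-values alternative is available via
  `AnalysisConfig.combined_speed`). Smoothing is explicit
  (`kinematics.smooth`, centred moving average with shrinking edge windows)
  and applied only where an analysis states it.

The head-line is fixed to the tunnel midline direction (+y). A body-locked
alternative would require an oriented body axis, which single-point head
tracking does not supply; heading quantifies how far the head deviates from
that same midline, so one reference serves both.

**Normalized coordinates.** Tip positions are head-centred per frame and
each axis is divided by its within-trial maximum absolute value, taken
jointly over both antennae so that left and right remain comparable
(per-antenna scaling is a config option). This effectively normalises by
the antennal length (about 45–55 mm in adult males), so positions are
expressed as proportions of reach, and |x|, |y|, |z| ≤ 1 within a trial.
An axis with zero maximum passes through unscaled. The reported
`scale_factor_mm` is the maximal head-to-tip distance and approximates the
antennal length.

**Tracking dropouts** are explicit validity flags. Invalid runs of at most
0.1 s are linearly interpolated; longer runs stay invalid and are excluded
from window statistics. A window with more than half its frames invalid
yields a missing value. The 0.1 s threshold is a package choice (exposed as
`interp_max_gap_s`), appropriate for 100 fps tracking where single-frame
losses are common and long occlusions are not recoverable.

## Spatial metrics

* **Occupancy maps**: 24×24-bin 2-D histograms of the normalized tip
  positions (both antennae pooled), normalised to sum to 1. Cross-trial
  maps are built by passing the cross-trial maximum coordinate as the bin
  extent.
* **Density curves**: Gaussian-kernel densities (scipy `gaussian_kde`), with
  the bandwidth given as a kernel standard deviation in coordinate units;
  curves integrate to 1 on a grid padded by three bandwidths. One bandwidth
  should be shared across curves that are compared.
* **Distance to stream**: the stream centre is modelled as a line parallel
  to y at lateral position `stream_x(t)` and at the stream's nominal height
  (head level — the stimulus is strongest there), mapped into the normalized
  frame with the same axis scales; the distance is the perpendicular
  distance in the x–z plane (lateral-only by config).
* **Ranges**: per-antenna range is max − min of the lateral (x) tip position
  within a window; the overall range spans the left-most to right-most
  position of the two antennae combined.
* **Change metrics**: a metric's odour-induced change is its value minus the
  mean over a pre-stimulus window of the same length as the stimulus,
  immediately before onset; pre-window means are therefore zero by
  construction. For moving-stream experiments each odour trial is further
  corrected by subtracting the same animal's sham (air) trial, aligned on
  time from onset.
* **Responsive antenna**: per trial, the antenna with the most negative
  odour-window mean change in distance to the stream, irrespective of
  left/right identity; that identity is then carried into the range
  analysis. A control label applies the same rule to two consecutive
  stimulus-length windows before onset (the later expressed as change from
  the earlier), quantifying spontaneous asymmetry; on stimulus-free data it
  splits ~50/50. Ties break to the left antenna with a warning.
* **Stream following**: Pearson correlation between tip lateral position and
  stream centre position over the stimulus window; undefined (missing) for
  constant series.

Uncertainty on window summaries uses a seeded nonparametric bootstrap over
trials (2000 resamples by default) with percentile intervals; the decision
semantics (proportion of resamples beyond a reference) mirror a posterior
tail probability while staying deterministic and dependency-light.

## Stepping

Steps are peaks in a tarsus's forward (y) coordinate, filtered by
prominence (default 0.5 mm) and minimum separation (default 0.15 s,
consistent with slow walking around 2 Hz). The per-leg instantaneous rate
is the reciprocal of the enclosing inter-step interval, held per frame and
set to zero once 2 s pass without a step so pauses read as non-walking.
Only the reliably tracked front and middle legs (L1, L2, R1, R2) enter the
trial-level rate: each leg's series is normalised by its own within-trial
mean and the four normalised series are averaged; a leg with fewer than two
steps contributes missing values. Inter-leg coordination is summarised by
the 6×6 Pearson matrix of frame-to-frame 3-D leg speeds, where a double
tripod gait appears as high within-tripod (L1-R2-L3, R1-L2-R3)
correlations.

## Spectral analysis

FFT summary spectra are one-sided amplitude spectra of mean-removed series,
scaled so a sinusoid of amplitude A reads A at its frequency and the sum of
squared amplitudes halved recovers the variance.

The time-resolved statistic is a continuous wavelet transform with a Morlet
mother (ω₀ = 6, the de-facto default of R wavelet packages; in pywt's
parametrisation `cmor2.0-0.9549`), 12 voices per octave spanning 0.5–10 Hz.
Power |W|² is averaged in 1 s time bins and the bands [0.5–1), [1–2),
[2–3), [3–5), [5–10) Hz, and each band is scaled by its pre-stimulus
average P₀:

    ΔP/P = (P_t − P₀) / P₀

so 0 means baseline, +1 a doubling, and −1 the hard floor. Numerical
choices:

* the series is mean-removed and **odd-reflect padded** past the largest
  wavelet's support before the transform; plain zero padding leaves edge
  transients orders of magnitude above the noise floor in quiet bands, and
  even-symmetric reflection still kinks the derivative of a large slow
  sweep. Bins inside an approximate cone of influence (e-folding time
  √2·f_c/f for the band's lowest frequency) are flagged `edge_flag` but
  retained.
* P₀ is the plain average over all pre-window bins, so the pre-window mean
  of ΔP/P is exactly zero by construction. Analyses should allow lead-in
  time before the pre-window so it sits outside the cone of influence; the
  synthetic trials reserve 3 s for this, and a warning is raised otherwise.
* band pooling for summaries merges **raw power** with weights proportional
  to band occupancy (number of wavelet scales) and rescales afterwards —
  averaging the per-band ratios instead would bias toward low-power bands.
* a band whose P₀ is zero is reported missing with a warning.

## Plume interaction

**Smoke profiles.** Grayscale frames are binarised with one threshold per
sequence, cropped to an ROI in front of the head, and a hand-drawn body
mask removes pixels on the animal (thresholding and masking are pointwise,
so their order is irrelevant). White-pixel counts per ROI row give the
left-to-right smoke distribution. The profile **width** is the longest
contiguous run of rows whose count exceeds 5% of the profile's maximum (the
floor is configurable); widths are normalised by a reference frame (frame I
of each sequence).

**PID fluctuations.** Alternating minima/maxima are detected with a
prominence floor of 2% of the window's voltage range (configurable);
same-type neighbours keep the more extreme event so min/max strictly
alternate. Per 2 s window, the **fluctuation rate** is the mean
instantaneous frequency of the pooled extrema sequence (mean reciprocal
inter-event interval; a count/duration alternative is available) and the
**magnitude** is the mean positive contrast — voltage rise from each minimum
to its next maximum. For a pure sinusoid of frequency f and amplitude A
these are exactly 2f and 2A. Windows are centred on local peaks of the
smoothed antennal speed; all non-overlapping candidates are collected and,
when more exist than requested, the kept set is spread evenly across the
candidates ranked by window-mean speed so the selection covers slow as well
as fast regimes. Control recordings (fixed antenna) use seeded random
windows. Per-window (mean speed, rate) and (mean speed, magnitude) pairs
are fit by ordinary least squares with a seeded bootstrap interval on the
slope.

## Valence assay

The preference index of an arena session is
PI = (time_odour − time_control)/time_total, with occupancy counted by
point-in-zone membership of the tracked centroid in two disjoint disc
zones. PI is +1 for full attraction and −1 for full avoidance, antisymmetric
under zone swap, and invariant to uniform time rescaling. Group-level
certainty against zero uses the seeded bootstrap over animals.

## The synthetic-data generator

The generator produces every input the pipeline reads, with a
machine-readable `GroundTruth` next to each dataset, and is itself under
test. It emulates the statistical structure the analyses rely on — not the
physics:

* **Trials** (24 s at 100 fps, odour window 9–15 s; the 3 s lead-in keeps
  the 6 s pre-window clear of the wavelet cone of influence): antennal tips
  sweep as independent per-antenna sinusoids around ±50° resting azimuth
  (30° amplitude, 0.5 Hz with 5% between-trial frequency jitter, 2° frame
  noise) plus small elevation oscillations; the head jitters by a fraction
  of a millimetre. During the odour window the designated responsive
  antenna's azimuth mean shifts toward the stream (default 15°), elevation
  movement doubles, 4 Hz bursts are added, the contralateral sweep amplitude
  grows by 30%, and — for moving streams — both antennae track the stream's
  azimuthal displacement with gain 0.5. Six tarsi step as two antiphase
  sawtooth tripods at 2 Hz, halved during odour. Sham trials keep only the
  declared mechanical artifact. The 5% frequency jitter is deliberate: at
  10% the sweep-phase variability, not the injected noise, dominates the
  odour-window distance statistic, and effect sizes in units of the noise
  s.d. lose their meaning.
* **PID experiments** (120 s at 100 Hz): the speed trace visits eight
  shuffled plateaus spanning 0–400 deg s⁻¹, ramped over ~1 s, with slow
  modulation and low-passed wander; the PID voltage oscillates with
  instantaneous event rate 2 Hz + 0.01 Hz/(deg s⁻¹)·speed and positive
  contrast 0.1 V + 0.5 mV/(deg s⁻¹)·speed, with 20% smooth rate jitter,
  per-half-cycle amplitude jitter (switched at zero crossings and blended
  over 50 ms) and 0.2 mV white noise. Every stochastic ingredient is
  smooth by construction: step-like artefacts (hard regime jumps, white
  speed noise feeding the amplitude, hard gain switches) produce
  single-sample voltage steps that a prominence-based detector counts as
  extrema, which is a property of discontinuous synthesis, not of plumes.
* **Smoke sequences**: a flat-top bright band (the stream) across the ROI
  over a noisy background with sparse supra-threshold speckle, a synthetic
  elliptical body silhouette in the mask, and an optional wake of known row
  count carved inward from the band's edge — the antenna enters the plume
  from outside, so the deficit starts at the boundary, and the measured
  width drops by exactly the wake size.
* **Arena tracks**: a sticky three-state Markov chain (odour shelter,
  control shelter, elsewhere) whose transition matrix
  P(i→j) = (1−s)π_j + s·δ_ij has the prescribed occupancy fractions π as its
  exact stationary distribution; s = 0.98 at 5 fps gives ~10 s dwells and a
  session-level PI sampling error small against the injected preference.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so every component is independently reproducible and `simulate`
output is byte-identical under a fixed seed.

**What passing tests do and do not show.** The generator's sweeps are
narrowband sinusoids, its noise is Gaussian, its plume statistics are
stationary within regimes, and its odour effects are step-like and
uncorrelated across antennae beyond what is injected. Recovery of injected
effects therefore demonstrates that the estimators measure what they claim
under the model's assumptions — not that real antennal behaviour satisfies
those assumptions. In particular, real sweep spectra are broadband, real
PID traces carry turbulent intermittency far from a jittered oscillator,
and real responsive-antenna asymmetries may drift within a trial.

## Known limitations

* The Bayesian multilevel models of the original analysis workflow are out
  of scope; bootstrap summaries replace credible intervals and make no
  shrinkage across animals.
* The wavelet cone-of-influence handling flags rather than masks edge bins;
  analyses of trials without lead-in time must treat flagged bins with care.
* Zone occupancy in the valence assay is centroid-based; partial-body
  occupancy is not modelled.
* The smoke analysis quantifies row profiles only — no optical flow, no
  particle velocimetry, and the synthetic wake is a geometric carve-out,
  not fluid dynamics.
* The mean-reciprocal fluctuation-rate estimator is sensitive to spurious
  extrema on near-flat traces; the 2%-of-range prominence floor controls
  this for clean PID signals but noisy recordings may need a higher floor.

## Problem sizes used in the shipped checks

The packaged recovery tests and the acceptance script run on deliberately
small cohorts — e.g. 100–200 trials for label recovery, 10 trials for band
power and stepping, one 120 s PID experiment or 50 seeded replicates for
bootstrap coverage, 12 arena sessions — chosen so the full suite documents
every claim while remaining quick to run end to end.
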