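"""Synthetic wind-tunnel recordings with known injected effects.

Every input the pipeline consumes can be generated here with a machine-
readable ground truth, so each analysis stage has a recovery test against
the injected effect sizes.  The generator emulates the statistical structure
the analyses assume, not the physics:

* antennal tips sweep as independent per-antenna sinusoids (plus frequency
  jitter and Gaussian noise) around a natural resting azimuth of about
  +/-50 deg from the midline;
* during the odour window the designated responsive antenna's azimuth mean
  shifts toward the stream position, elevation movement is amplified, and
  band-limited oscillation bursts are added; the contralateral antenna's
  sweep amplitude can grow (range gain);
* six tarsi step as two antiphase tripods (L1-R2-L3 vs R1-L2-R3) with
  sawtooth forward motion at about 2 Hz, slowed during the odour window;
* the PID experiment couples fluctuation rate and positive-contrast
  magnitude affinely to the concurrent antennal speed;
* smoke sequences are a flat-top bright stream band plus speckle noise, with
  an optional wake carved inward from the band edge (an antenna sweeping in
  from outside captures particles at the plume boundary first);
* arena tracks are sticky three-state Markov chains (odour shelter, control
  shelter, elsewhere) with a prescribed stationary occupancy.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so each generated component is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import PointSeries, StimulusProtocol, Trial
from .valence import ArenaTrack, Zone

# lateral stream-centre positions (mm): centred, side, edge of antennal reach
STREAM_POSITIONS_MM = {"P1": 0.0, "P2": 30.0, "P3": 60.0}


@dataclass
class TrialGeneratorParams:
    """Study conditions for one synthetic wind-tunnel trial."""

    duration_s: float = 24.0
    frame_rate: float = 100.0
    onset_s: float = 9.0
    offset_s: float = 15.0
    scenario: str = "static1"        # static1 | static2 | moving
    odour: str = "colony"
    is_sham: bool = False
    antennal_length_mm: float = 50.0
    # baseline sweeping
    baseline_azimuth_deg: float = 50.0   # resting distance from midline, per side
    sweep_amplitude_deg: float = 30.0
    sweep_frequency_hz: float = 0.5
    elevation_amplitude_deg: float = 8.0
    elevation_frequency_hz: float = 0.8
    noise_sd_deg: float = 2.0
    frequency_jitter: float = 0.05       # fractional sd on sweep frequencies
    # odour-window effects (all zero for null / sham trials)
    responsive_side: str | None = None   # None: drawn from the seed
    azimuth_shift_deg: float = 15.0
    elevation_gain: float = 2.0
    burst_bands: tuple[tuple[float, float], ...] = ((4.0, 6.0),)  # (Hz, deg)
    contralateral_range_gain: float = 1.3
    stream_follow_gain: float = 0.5      # both antennae track a moving stream
    mech_artifact_deg: float = 0.0       # present in sham trials too
    # walking
    stepping_rate_hz: float = 2.0
    odour_slowdown: float = 0.5          # odour-window rate multiplier
    step_amplitude_mm: float = 4.0

    def null(self) -> "TrialGeneratorParams":
        """Copy with every odour-induced effect removed."""
        return dataclasses.replace(
            self, azimuth_shift_deg=0.0, elevation_gain=1.0, burst_bands=(),
            contralateral_range_gain=1.0, odour_slowdown=1.0,
            stream_follow_gain=0.0)


@dataclass
class GroundTruth:
    """Injected effect sizes serialized alongside every generated dataset."""

    kind: str
    seed: int
    values: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"kind": self.kind, "seed": self.seed, "values": self.values},
            indent=2, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], seed=d["seed"], values=d["values"])


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _angles_to_xyz(head: np.ndarray, az_deg: np.ndarray, el_deg: np.ndarray,
                   length_mm: float) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    return head + length_mm * np.column_stack([
        np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])


def _stream_breakpoints(params: TrialGeneratorParams
                        ) -> list[tuple[float, float]]:
    if params.scenario == "static1":
        return [(0.0, STREAM_POSITIONS_MM["P1"])]
    if params.scenario == "static2":
        return [(0.0, STREAM_POSITIONS_MM["P2"])]
    if params.scenario == "moving":
        t0, t1 = params.onset_s, params.offset_s
        third = (t1 - t0) / 3.0
        return [
            (t0, STREAM_POSITIONS_MM["P1"]),
            (t0 + third, STREAM_POSITIONS_MM["P1"]),
            (t0 + 1.5 * third, STREAM_POSITIONS_MM["P2"]),
            (t0 + 2 * third, STREAM_POSITIONS_MM["P2"]),
            (t0 + 2.5 * third, STREAM_POSITIONS_MM["P3"]),
            (t1, STREAM_POSITIONS_MM["P3"]),
        ]
    raise ValueError(f"unknown scenario {params.scenario!r}")


def generate_trial(params: TrialGeneratorParams, seed: int,
                   trial_id: str = "sim", animal_id: str = "animal"
                   ) -> tuple[Trial, GroundTruth]:
    """One synthetic tracked trial plus its injected-effect ground truth.

    Sham trials (``is_sham=True``) omit all odour effects but keep the
    declared mechanical artifact, mirroring a non-odorised air stream.
    """
    if params.offset_s > params.duration_s or params.onset_s >= params.offset_s:
        raise ValueError("stimulus window inconsistent with trial duration")
    rng_side, rng_head, rng_L, rng_R, rng_legs = _rngs(seed, 5)

    n = int(round(params.duration_s * params.frame_rate))
    t = np.arange(n) / params.frame_rate
    proto = StimulusProtocol(
        onset_s=params.onset_s, offset_s=params.offset_s,
        stream_x=_stream_breakpoints(params), is_sham=params.is_sham)
    odour_win = (t >= params.onset_s) & (t < params.offset_s)

    responsive = params.responsive_side or ("L", "R")[rng_side.integers(2)]
    apply_effects = not params.is_sham

    head = np.zeros((n, 3))
    head += 0.3 * rng_head.standard_normal((n, 3)).cumsum(axis=0) / np.sqrt(n)

    points: dict[str, PointSeries] = {
        "head": PointSeries(head, np.ones(n, dtype=bool))}

    stream_x_t = np.asarray(proto.stream_x_at(t), dtype=float)
    az_target = np.degrees(np.arctan2(stream_x_t, proto.stream_y_mm))

    for side, rng in (("L", rng_L), ("R", rng_R)):
        sgn = -1.0 if side == "L" else 1.0
        f_az = params.sweep_frequency_hz * (
            1 + params.frequency_jitter * rng.standard_normal())
        f_el = params.elevation_frequency_hz * (
            1 + params.frequency_jitter * rng.standard_normal())
        phi_az, phi_el = rng.uniform(0, 2 * np.pi, 2)

        amp = np.full(n, params.sweep_amplitude_deg)
        mean_az = np.full(n, sgn * params.baseline_azimuth_deg)
        el_scale = np.ones(n)
        burst = np.zeros(n)

        if params.mech_artifact_deg:
            mean_az[odour_win] += params.mech_artifact_deg
        if apply_effects:
            if side == responsive and params.azimuth_shift_deg:
                shift_dir = np.sign(az_target[odour_win] - mean_az[odour_win])
                mean_az[odour_win] += shift_dir * params.azimuth_shift_deg
            if params.stream_follow_gain:
                az_at_onset = float(np.degrees(np.arctan2(
                    proto.stream_x_at(params.onset_s), proto.stream_y_mm)))
                mean_az[odour_win] += params.stream_follow_gain * (
                    az_target[odour_win] - az_at_onset)
            if side != responsive and params.contralateral_range_gain != 1.0:
                amp[odour_win] *= params.contralateral_range_gain
            if params.elevation_gain != 1.0:
                el_scale[odour_win] = params.elevation_gain
            for f_b, a_b in params.burst_bands:
                burst[odour_win] += a_b * np.sin(
                    2 * np.pi * f_b * t[odour_win] + rng.uniform(0, 2 * np.pi))

        az = (mean_az + amp * np.sin(2 * np.pi * f_az * t + phi_az) + burst
              + params.noise_sd_deg * rng.standard_normal(n))
        el = el_scale * (params.elevation_amplitude_deg
                         * np.sin(2 * np.pi * f_el * t + phi_el)
                         + params.noise_sd_deg * rng.standard_normal(n)) - 5.0
        el = np.clip(el, -89.0, 89.0)
        tip = _angles_to_xyz(head, az, el, params.antennal_length_mm)
        points[f"ant_{side}"] = PointSeries(tip, np.ones(n, dtype=bool))

    # legs: two antiphase tripods with sawtooth forward motion
    rate = np.full(n, params.stepping_rate_hz)
    if apply_effects:
        rate[odour_win] *= params.odour_slowdown
    phase = 2 * np.pi * np.cumsum(rate) / params.frame_rate
    tripod_a = ("L1", "R2", "L3")
    base_xy = {"R1": (12, 8), "R2": (14, 0), "R3": (12, -8),
               "L1": (-12, 8), "L2": (-14, 0), "L3": (-12, -8)}
    for leg, (bx, by) in base_xy.items():
        ph = phase + (0.0 if leg in tripod_a else np.pi)
        saw = (ph % (2 * np.pi)) / (2 * np.pi)  # rising ramp, sharp drop = a step
        y = by + params.step_amplitude_mm * saw + 0.05 * rng_legs.standard_normal(n)
        x = bx + 0.1 * rng_legs.standard_normal(n)
        z = 0.2 * np.abs(np.sin(ph / 2)) + 0.02 * rng_legs.standard_normal(n)
        points[leg] = PointSeries(np.column_stack([x, y, z]),
                                  np.ones(n, dtype=bool))

    trial = Trial(trial_id=trial_id, animal_id=animal_id,
                  odour="air_sham" if params.is_sham else params.odour,
                  frame_rate=params.frame_rate, points=points, protocol=proto)
    truth = GroundTruth(kind="trial", seed=seed, values={
        "responsive_side": responsive if apply_effects else None,
        "azimuth_shift_deg": params.azimuth_shift_deg if apply_effects else 0.0,
        "elevation_gain": params.elevation_gain if apply_effects else 1.0,
        "burst_bands": [list(b) for b in params.burst_bands] if apply_effects else [],
        "contralateral_range_gain": (params.contralateral_range_gain
                                     if apply_effects else 1.0),
        "stream_follow_gain": params.stream_follow_gain if apply_effects else 0.0,
        "odour_slowdown": params.odour_slowdown if apply_effects else 1.0,
        "stepping_rate_hz": params.stepping_rate_hz,
        "mech_artifact_deg": params.mech_artifact_deg,
        "scenario": params.scenario,
        "is_sham": params.is_sham,
    })
    return trial, truth


# ---------------------------------------------------------------------------
# PID experiment


@dataclass
class PIDExperimentParams:
    """Speed-coupled PID fluctuation experiment conditions."""

    duration_s: float = 120.0
    sample_rate_hz: float = 100.0
    baseline_volts: float = 1.0
    rate0_hz: float = 2.0              # fluctuation rate at zero speed
    rate_slope: float = 0.01           # Hz per deg/s (1 Hz per 100 deg/s)
    mag0_volts: float = 0.1            # positive contrast at zero speed
    mag_slope: float = 0.0005          # V per deg/s
    noise_sd_volts: float = 0.0002
    rate_jitter: float = 0.2           # fractional low-frequency jitter on rate
    mag_jitter: float = 0.2            # and on contrast magnitude
    speed_max_deg_s: float = 400.0
    n_regimes: int = 8
    control: bool = False              # fixed antenna: speed identically 0


def generate_pid_experiment(params: PIDExperimentParams, seed: int
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """(time, antennal speed, PID volts, truth) with affine speed coupling.

    The speed trace visits ``n_regimes`` plateaus spanning 0 to
    ``speed_max_deg_s`` with slow within-regime modulation, so selected
    windows cover a wide range of mean speeds.  The PID oscillates at
    instantaneous frequency rate(t)/2 (each cycle contributes one minimum
    and one maximum) with half-amplitude magnitude(t)/2, so a window's
    fluctuation rate and positive-contrast magnitude equal the coupled
    targets up to noise.
    """
    rng_speed, rng_pid = _rngs(seed, 2)
    n = int(round(params.duration_s * params.sample_rate_hz))
    t = np.arange(n) / params.sample_rate_hz

    if params.control:
        speed = np.zeros(n)
    else:
        levels = rng_speed.permutation(
            np.linspace(0.05, 1.0, params.n_regimes)) * params.speed_max_deg_s
        regime = np.minimum((t / (params.duration_s / params.n_regimes)).astype(int),
                            params.n_regimes - 1)
        level_t = levels[regime].astype(float)
        # ramp between regimes over ~1 s: movement transitions are continuous
        k_lvl = int(params.sample_rate_hz)
        level_t = np.convolve(np.pad(level_t, (k_lvl // 2, k_lvl - k_lvl // 2 - 1),
                                     mode="edge"),
                              np.ones(k_lvl) / k_lvl, mode="valid")
        speed = level_t * (0.75 + 0.25 * np.sin(
            2 * np.pi * 0.125 * t + rng_speed.uniform(0, 2 * np.pi)))
        # slow wander, not white noise: tracked angular speed is smooth
        w_sp = int(params.sample_rate_hz / 2)
        wander = np.convolve(rng_speed.standard_normal(n + w_sp),
                             np.ones(w_sp) / w_sp, mode="valid")[:n]
        speed = np.clip(speed + 5.0 * np.sqrt(w_sp) * wander, 0.0, None)

    # plume fluctuations are irregular, not a clean oscillator: the event
    # frequency carries smooth (~1 s correlated) multiplicative jitter and
    # each half-cycle draws its own amplitude (switching at zero crossings,
    # so the jitter adds no sample-scale wiggles of its own)
    w = int(params.sample_rate_hz)
    raw = rng_pid.standard_normal(n + w)
    sm = np.convolve(raw, np.ones(w) / w, mode="valid")[:n] * np.sqrt(w)
    rate = ((params.rate0_hz + params.rate_slope * speed)
            * np.clip(1.0 + params.rate_jitter * sm, 0.2, None))
    mag = params.mag0_volts + params.mag_slope * speed
    phase = 2 * np.pi * np.cumsum(rate / 2.0) / params.sample_rate_hz
    half_cycle = np.floor(phase / np.pi).astype(int)
    gains = np.clip(1.0 + params.mag_jitter
                    * rng_pid.standard_normal(half_cycle.max() + 1), 0.2, None)
    env = gains[half_cycle]
    # spread the per-half-cycle switch over ~50 ms: the crossing sample is
    # not exactly at sin = 0, and a hard switch would leave a voltage step
    k = max(int(0.05 * params.sample_rate_hz), 1)
    env = np.convolve(np.pad(env, (k // 2, k - k // 2 - 1), mode="edge"),
                      np.ones(k) / k, mode="valid")
    volts = (params.baseline_volts + 0.5 * mag * env * np.sin(phase)
             + params.noise_sd_volts * rng_pid.standard_normal(n))

    truth = GroundTruth(kind="pid", seed=seed, values={
        "rate0_hz": params.rate0_hz,
        "rate_slope_hz_per_deg_s": params.rate_slope,
        "mag0_volts": params.mag0_volts,
        "mag_slope_v_per_deg_s": params.mag_slope,
        "control": params.control,
    })
    return t, speed, volts, truth


# ---------------------------------------------------------------------------
# smoke sequences


@dataclass
class SmokeParams:
    """Geometry of a synthetic smoke-visualisation sequence."""

    n_frames: int = 10
    height: int = 120
    width: int = 160
    roi: tuple[int, int, int, int] = (10, 110, 40, 140)
    band_centre_row: int = 60
    band_half_width: int = 20          # stream spans 2*half_width + 1 rows
    band_intensity: float = 180.0
    background_intensity: float = 20.0
    speckle_p: float = 0.01            # supra-threshold speckle probability
    threshold: float = 100.0
    wake_rows: int = 0                 # rows carved inward from the band edge
    wake_from_frame: int = 5


def generate_smoke_sequence(params: SmokeParams, seed: int
                            ) -> tuple[np.ndarray, np.ndarray,
                                       tuple[int, int, int, int], GroundTruth]:
    """(frames, body mask, ROI, truth) for the smoke-profile analysis.

    The stream is a flat-top bright band across the ROI; the optional wake
    carves ``wake_rows`` dark rows inward from the band's upper edge on
    frames >= ``wake_from_frame`` (the sweeping antenna enters the plume from
    outside, so the deficit starts at the boundary).  Frame 0 is the
    reference frame for width normalisation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    h, w = params.height, params.width
    frames = np.full((params.n_frames, h, w), params.background_intensity)
    frames += 5.0 * rng.standard_normal(frames.shape)

    r0 = params.band_centre_row - params.band_half_width
    r1 = params.band_centre_row + params.band_half_width + 1
    frames[:, r0:r1, :] = params.band_intensity + 5.0 * rng.standard_normal(
        (params.n_frames, r1 - r0, w))

    speckle = rng.random(frames.shape) < params.speckle_p
    frames[speckle] = params.band_intensity

    if params.wake_rows > 0:
        for k in range(params.wake_from_frame, params.n_frames):
            frames[k, r0:r0 + params.wake_rows, :] = params.background_intensity

    frames = np.clip(frames, 0, 255)

    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[:h, :w]
    # synthetic body silhouette: an ellipse left of the ROI
    mask[((yy - h / 2) / (h / 3)) ** 2 + ((xx - 15) / 18) ** 2 <= 1.0] = True

    truth = GroundTruth(kind="smoke", seed=seed, values={
        "band_rows": 2 * params.band_half_width + 1,
        "wake_rows": params.wake_rows,
        "wake_from_frame": params.wake_from_frame,
        "threshold": params.threshold,
    })
    return frames, mask, params.roi, truth


# ---------------------------------------------------------------------------
# arena tracks


@dataclass
class ArenaParams:
    """Two-shelter arena assay conditions."""

    duration_s: float = 1800.0
    frame_rate: float = 5.0
    arena_radius_mm: float = 450.0
    shelter_radius_mm: float = 80.0
    odour_fraction: float = 0.3        # expected occupancy of the odour shelter
    control_fraction: float = 0.1
    stickiness: float = 0.98           # per-frame probability of staying put


def generate_arena_track(params: ArenaParams, seed: int
                         ) -> tuple[ArenaTrack, GroundTruth]:
    """Random-walk arena track with prescribed expected zone occupancy.

    States (odour shelter, control shelter, elsewhere) follow a sticky
    Markov chain whose stationary distribution equals the requested
    fractions, so expected PI = odour_fraction - control_fraction.
    """
    po, pc = params.odour_fraction, params.control_fraction
    if not (0 <= po <= 1 and 0 <= pc <= 1 and po + pc <= 1):
        raise ValueError("zone fractions must be in [0,1] and sum to <= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = int(round(params.duration_s * params.frame_rate))
    pi = np.array([po, pc, 1.0 - po - pc])
    s = params.stickiness

    R = params.arena_radius_mm
    odour_zone = Zone(-R + params.shelter_radius_mm, 0.0, params.shelter_radius_mm)
    control_zone = Zone(R - params.shelter_radius_mm, 0.0, params.shelter_radius_mm)
    centres = {0: odour_zone, 1: control_zone}

    # P(i->j) = (1-s) pi_j + s delta_ij has stationary distribution pi
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(3, p=pi)
    stay = rng.random(n)
    jumps = rng.choice(3, size=n, p=pi)
    for k in range(1, n):
        states[k] = states[k - 1] if stay[k] < s else jumps[k]

    x = np.empty(n)
    y = np.empty(n)
    u = rng.random(n)
    theta = rng.uniform(0, 2 * np.pi, n)
    for st in (0, 1):
        sel = states == st
        z = centres[st]
        r = z.radius * np.sqrt(u[sel]) * 0.95
        x[sel] = z.cx + r * np.cos(theta[sel])
        y[sel] = z.cy + r * np.sin(theta[sel])
    sel = states == 2
    m = sel.sum()
    xs = np.empty(m)
    ys = np.empty(m)
    filled = 0
    while filled < m:
        cand_r = R * np.sqrt(rng.random(2 * (m - filled)))
        cand_t = rng.uniform(0, 2 * np.pi, 2 * (m - filled))
        cx, cy = cand_r * np.cos(cand_t), cand_r * np.sin(cand_t)
        ok = ~odour_zone.contains(cx, cy) & ~control_zone.contains(cx, cy)
        take = min(ok.sum(), m - filled)
        xs[filled:filled + take] = cx[ok][:take]
        ys[filled:filled + take] = cy[ok][:take]
        filled += take
    x[sel], y[sel] = xs, ys

    track = ArenaTrack(x=x, y=y, frame_rate=params.frame_rate,
                       odour_zone=odour_zone, control_zone=control_zone)
    truth = GroundTruth(kind="arena", seed=seed, values={
        "odour_fraction": po, "control_fraction": pc,
        "expected_pi": po - pc,
    })
    return track, truth
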