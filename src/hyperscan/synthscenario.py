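"""Synthetic two-person OPM-MEG sessions.

Generates complete hyperscanning recordings with the statistical
structure the downstream analyses assume:

* a remnant shielded-room field (~2 nT uniform plus ~2 nT/m gradient)
  with a slow, seeded random-walk drift (~200 pT over 10 min);
* rigid-body head motion, band-limited, with stated excursion bounds;
* task-locked beta-band (13-30 Hz) neural sources: amplitude-modulated
  band-limited noise carriers whose envelopes implement event-related
  desynchronisation (touch task) or rally-locked rebound/suppression
  trains with a controllable inter-brain lag (ball game);
* movement artefacts from each sensor's trajectory through the
  post-nulling residual field, sensor white noise, and range clipping.

All generators are deterministic under a stated seed, and the latent
ground truth (envelopes, source timecourses, poses, lag) is returned
alongside the Recording for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from .forward import (
    Dipole,
    OPMMode,
    OPMSensor,
    Pose,
    Recording,
    SensorArray,
    SphereModel,
    lead_field,
)

MOTION_RATE = 120.0  # optical-tracking sample rate, Hz
DATA_RATE = 1200.0  # OPM sample rate, Hz


# ---------------------------------------------------------------------------
# Remnant field
# ---------------------------------------------------------------------------

@dataclass
class RemnantFieldModel:
    """Static remnant MSR field plus a slow seeded random-walk drift.

    ``field(points, t) = uniform + gradient @ r + drift(t)`` where the
    drift is a spatially uniform random walk scaled so its RMS excursion
    over ``drift_window`` seconds equals ``drift_magnitude``.
    """

    uniform: np.ndarray  # (3,) T
    gradient: np.ndarray  # (3, 3) T/m
    drift_magnitude: float = 200e-12  # T
    drift_window: float = 600.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        self.uniform = np.asarray(self.uniform, dtype=float)
        self.gradient = np.asarray(self.gradient, dtype=float)
        self._trace = None  # lazily built drift trace at 1 Hz

    @classmethod
    def msr_default(cls, seed: int = 0) -> "RemnantFieldModel":
        """Typical optimised-MSR conditions: 2 nT uniform, ~2 nT/m gradient."""
        u = 2e-9 * np.array([0.45, -0.60, 0.66]) / np.linalg.norm([0.45, -0.60, 0.66])
        # symmetric, traceless gradient tensor (consistent with a
        # source-free static field), Frobenius norm ~2 nT/m
        g = 2e-9 * np.array(
            [
                [0.30, 0.50, 0.20],
                [0.50, -0.10, 0.40],
                [0.20, 0.40, -0.20],
            ]
        )
        return cls(uniform=u, gradient=g, seed=seed)

    def _drift(self, t: np.ndarray) -> np.ndarray:
        """Spatially uniform drift vector at time(s) t, (len(t), 3)."""
        t = np.atleast_1d(t)
        t_max = float(max(t.max(), 1.0))
        n_need = int(np.ceil(t_max)) + 2
        if self._trace is None or self._trace.shape[0] < n_need:
            rng = np.random.default_rng(self.seed)
            n = max(n_need, int(self.drift_window) + 2)
            step = self.drift_magnitude / np.sqrt(self.drift_window * 3.0)
            walk = np.vstack(
                [np.zeros(3), np.cumsum(rng.normal(0.0, step, (n - 1, 3)), axis=0)]
            )
            self._trace = walk
        out = np.empty((t.size, 3))
        grid = np.arange(self._trace.shape[0], dtype=float)
        for k in range(3):
            out[:, k] = np.interp(t, grid, self._trace[:, k])
        return out

    def static_field(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return self.uniform + pts @ self.gradient.T

    def field(self, points, t) -> np.ndarray:
        """Field (T) at room-frame ``points`` and scalar time ``t``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self._drift(np.atleast_1d(float(t)))[0]
        return self.static_field(pts) + d

    def __call__(self, points, t) -> np.ndarray:
        return self.field(points, t)


# ---------------------------------------------------------------------------
# Task designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskDesign:
    """Trial structure of one experiment."""

    n_trials: int
    trial_structure: tuple  # ((label, duration s), ...)
    alternating: bool  # odd/even trials swap the active participant
    iti: float  # cue-to-cue interval metadata, s
    dropped_trials: tuple = ()
    kind: str = "custom"

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.trial_structure):
            raise ValueError("epoch durations must be positive")
        if any(k < 0 or k >= self.n_trials for k in self.dropped_trials):
            raise ValueError("dropped trials outside trial range")

    @property
    def period(self) -> float:
        return float(sum(d for _, d in self.trial_structure))

    @property
    def duration(self) -> float:
        return self.n_trials * self.period

    @property
    def kept_trials(self) -> np.ndarray:
        return np.array(
            [k for k in range(self.n_trials) if k not in self.dropped_trials], int
        )

    def event_times(self) -> np.ndarray:
        return np.arange(self.n_trials) * self.period

    def event_codes(self) -> list:
        if self.alternating:
            return ["P1_active" if k % 2 == 0 else "P2_active" for k in range(self.n_trials)]
        return [self.kind for _ in range(self.n_trials)]


def gen_touch_task(n_trials: int = 60) -> TaskDesign:
    """Alternating touch task: cues every 5 s, odd/even active participant."""
    return TaskDesign(
        n_trials=n_trials,
        trial_structure=(("trial", 5.0),),
        alternating=True,
        iti=5.0,
        kind="touch",
    )


def gen_ball_game(n_trials: int = 25, dropped_trials: tuple = (7, 16)) -> TaskDesign:
    """Ball game: 5 s rally + 7 s rest per trial, two dropped-ball trials."""
    return TaskDesign(
        n_trials=n_trials,
        trial_structure=(("rally", 5.0), ("rest", 7.0)),
        alternating=False,
        iti=0.0,
        dropped_trials=tuple(dropped_trials),
        kind="ball",
    )


# ---------------------------------------------------------------------------
# Neural sources
# ---------------------------------------------------------------------------

def _default_dipole() -> Dipole:
    """Left-sensorimotor current dipole in the helmet frame (+y is up)."""
    direction = np.array([-0.35, 0.85, 0.40])
    position = 0.055 * direction / np.linalg.norm(direction)
    # tangential orientation (orthogonal to the radial direction)
    tang = np.cross(position, [1.0, 0.0, 0.0])
    return Dipole(position, tang / np.linalg.norm(tang))


@dataclass
class NeuralSourceSpec:
    """Latent beta-band source dynamics for both participants.

    The envelopes are dimensionless multipliers on
    ``baseline_beta_amplitude``.  Touch task: the active participant's
    suppression spans ``[erd_onset, erd_offset]`` after the cue; the
    passive participant starts ``passive_onset_delay`` later and ends
    ``passive_offset_advance`` earlier.  Ball game: a common suppression
    during the rally with per-participant rebound bumps after each of
    their own hits, the two bump trains offset by ``interbrain_lag``.
    """

    dipoles: tuple = field(default_factory=lambda: (_default_dipole(), _default_dipole()))
    baseline_beta_amplitude: float = 30e-9  # A*m
    erd_depth: float = 0.55
    erd_onset: float = 0.3  # s after cue, active participant
    erd_offset: float = 2.7
    passive_onset_delay: float = 0.3
    passive_offset_advance: float = 0.5
    interbrain_lag: float = 0.6  # s, participant 2 lags participant 1
    oscillation_band: tuple = (13.0, 30.0)
    rebound_amplitude: float = 0.6
    hit_period: float = 1.5  # s, mean spacing of one participant's own hits
    rally_jitter: tuple = (-0.12, 0.18, -0.06, 0.12)  # fractional pace variation
    first_hit: float = 0.35  # s after rally cue, participant 1
    last_hit_time: float = 5.9  # s; rebounds after the final strike allowed
    rally_build_centre: float = 4.2  # s, peak of the rally-intensity profile
    rally_build_width: float = 5.0  # s, full width of that profile
    suppression_window: tuple = (0.1, 6.8)
    edge: float = 0.3  # raised-cosine ramp width, s

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must be in [0, 1]")

    def hit_times(self, participant: int) -> np.ndarray:
        """One participant's strike times within a trial (rally + rebound tail).

        The rally pace varies from stroke to stroke (``rally_jitter``
        cycles over the hit intervals) while participant 2's strikes
        stay a fixed ``interbrain_lag`` behind participant 1's, so only
        the true lag aligns the two rebound trains.
        """
        n_max = int(np.ceil(self.last_hit_time / self.hit_period)) + 1
        jit = np.array([self.rally_jitter[k % len(self.rally_jitter)] for k in range(n_max)])
        intervals = self.hit_period * (1.0 + jit)
        base = self.first_hit + np.concatenate([[0.0], np.cumsum(intervals)])
        hits = base + participant * self.interbrain_lag
        return hits[hits < self.last_hit_time]


def _smooth_window(t: np.ndarray, t0: float, t1: float, edge: float) -> np.ndarray:
    """Raised-cosine-edged window: 0 outside [t0, t1], 1 in the flat top."""
    up = np.clip((t - t0) / edge, 0.0, 1.0)
    down = np.clip((t1 - t) / edge, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def _bump(t: np.ndarray, centre: float, width: float) -> np.ndarray:
    """Raised-cosine bump of full width ``width`` centred on ``centre``."""
    x = (t - centre) / (width / 2.0)
    out = np.zeros_like(t)
    m = np.abs(x) < 1.0
    out[m] = 0.5 * (1 + np.cos(np.pi * x[m]))
    return out


def latent_envelopes(design: TaskDesign, spec: NeuralSourceSpec, times: np.ndarray) -> np.ndarray:
    """Dimensionless beta-amplitude envelopes, shape (2, len(times))."""
    env = np.ones((2, times.size))
    for k in range(design.n_trials):
        t_rel = times - k * design.period
        in_trial = (t_rel >= 0) & (t_rel < design.period)
        if not np.any(in_trial):
            continue
        tr = t_rel[in_trial]
        if design.kind == "touch" or design.alternating:
            active = k % 2  # trial 0: participant 1 active
            for p in range(2):
                if p == active:
                    t0, t1 = spec.erd_onset, spec.erd_offset
                else:
                    t0 = spec.erd_onset + spec.passive_onset_delay
                    t1 = spec.erd_offset - spec.passive_offset_advance
                env[p, in_trial] -= spec.erd_depth * _smooth_window(tr, t0, t1, spec.edge)
        else:  # rally/rest structure
            s0, s1 = spec.suppression_window
            supp = spec.erd_depth * _smooth_window(tr, s0, s1, spec.edge)
            for p in range(2):
                e = -supp.copy()
                # rebound bumps after each of this participant's strikes,
                # scaled by a rally-intensity profile that builds and fades
                for hit in spec.hit_times(p):
                    amp = spec.rebound_amplitude * float(
                        _bump(
                            np.atleast_1d(hit),
                            spec.rally_build_centre,
                            spec.rally_build_width,
                        )[0]
                    )
                    e += amp * _bump(tr, hit + 0.25, 0.7)
                env[p, in_trial] += e
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionSpec:
    """Band-limited rigid-body motion with stated maximum excursions."""

    max_translation: float = 0.02  # m, from the starting position
    max_rotation: float = 5.0  # degrees
    smoothness: float = 1.0  # bandwidth, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ValueError("motion bounds must be non-negative")

    @classmethod
    def touch_task(cls, seed: int = 0) -> "MotionSpec":
        """Smooth reaching movements: ~2 cm translations, ~5 deg rotations."""
        return cls(0.020, 5.0, 0.8, seed)

    @classmethod
    def ball_game(cls, seed: int = 0) -> "MotionSpec":
        """Quicker, larger movements: ~6 cm translations, ~17 deg rotations."""
        return cls(0.060, 17.0, 2.0, seed)


def gen_motion(
    spec: MotionSpec,
    duration: float,
    rate: float = MOTION_RATE,
    seed: Optional[int] = None,
) -> Pose:
    """Seeded band-limited rigid-body trajectory starting at the identity.

    The maximum translation norm (from the start) equals
    ``max_translation`` exactly (by rescaling); likewise the rotation
    magnitude, realised through rotation vectors.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = max(int(round(duration * rate)), 2)
    times = np.arange(n) / rate

    def trajectory(bound: float) -> np.ndarray:
        raw = rng.normal(size=(n, 3))
        if bound == 0.0:
            return np.zeros((n, 3))
        wn = min(spec.smoothness / (rate / 2.0), 0.99)
        sos = butter(4, wn, output="sos")
        smooth = sosfiltfilt(sos, raw, axis=0)
        smooth = smooth - smooth[0]
        peak = np.linalg.norm(smooth, axis=1).max()
        return smooth * (bound / peak) if peak > 0 else smooth

    trans = trajectory(spec.max_translation)
    rotvec = trajectory(np.deg2rad(spec.max_rotation))
    return Pose(times, Rotation.from_rotvec(rotvec), trans)


# ---------------------------------------------------------------------------
# Helmets and two-person setups
# ---------------------------------------------------------------------------

def build_helmet(
    centre,
    helmet_id: str,
    n_sensors: int = 16,
    n_nulling: int = 10,
    scalp_radius: float = 0.105,
    cap_angle_deg: float = 75.0,
) -> SensorArray:
    """Quasi-uniform radial OPM array on the upper head cap (+y is up).

    Sensor positions follow a spherical Fibonacci spiral over the cap;
    ``n_nulling`` of them, spread evenly through the ordering, are
    flagged as inputs to the field-nulling controller.  The returned
    array's static pose places the helmet-frame origin (the head centre)
    at room-frame ``centre``.
    """
    golden = np.pi * (3.0 - np.sqrt(5.0))
    cos_min = np.cos(np.deg2rad(cap_angle_deg))
    flag = set(np.round(np.linspace(0, n_sensors - 1, n_nulling)).astype(int))
    sensors = []
    for i in range(n_sensors):
        cy = 1.0 - (1.0 - cos_min) * (i + 0.5) / n_sensors
        sy = np.sqrt(max(1.0 - cy**2, 0.0))
        phi = i * golden
        direction = np.array([sy * np.cos(phi), cy, sy * np.sin(phi)])
        sensors.append(
            OPMSensor(
                position=scalp_radius * direction,
                orientation=direction,
                used_for_nulling=i in flag,
            )
        )
    pose = Pose(
        np.array([0.0]), Rotation.identity(1), np.asarray(centre, float)[None, :]
    )
    return SensorArray(tuple(sensors), pose, helmet_id)


def two_person_setup(
    separation: float = 0.65,
    n_sensors: int = 16,
    n_nulling: int = 10,
) -> tuple:
    """Two helmets facing each other across the x axis, between the coil planes.

    Returns ``(arrays, models)``: the sensor arrays and per-helmet
    conducting-sphere models (helmet frame, shared single sphere).
    """
    arrays = (
        build_helmet([-separation / 2.0, 0.0, 0.0], "P1", n_sensors, n_nulling),
        build_helmet([separation / 2.0, 0.0, 0.0], "P2", n_sensors, n_nulling),
    )
    models = (SphereModel(np.zeros(3), 0.09), SphereModel(np.zeros(3), 0.09))
    return arrays, models


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Latent quantities behind a synthetic Recording."""

    envelopes: np.ndarray  # (2, S) dimensionless
    moments: np.ndarray  # (2, S) A*m source timecourses
    dipoles: tuple  # per-participant Dipole (helmet frame)
    interbrain_lag: float
    poses: dict  # helmet_id -> Pose (motion composed with base position)
    event_times: np.ndarray
    saturation_fraction: float = 0.0


def _band_noise(rng, band, fs, n) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise carrier."""
    lo, hi = band
    sos = butter(4, [lo / (fs / 2.0), hi / (fs / 2.0)], btype="band", output="sos")
    x = sosfiltfilt(sos, rng.normal(size=n))
    return x / np.std(x)


def gen_session(
    design: TaskDesign,
    sources: NeuralSourceSpec,
    motion: MotionSpec,
    remnant: RemnantFieldModel,
    arrays: Sequence[SensorArray],
    models: Sequence[SphereModel],
    residual_field: Optional[Callable] = None,
    seed: int = 0,
    sample_rate: float = DATA_RATE,
    mode: Optional[OPMMode] = None,
    include_noise: bool = True,
) -> tuple[Recording, GroundTruth]:
    """Simulate one synchronized two-helmet recording.

    Per channel the signal is the projected dipole field (task-modulated
    beta carrier; the dipole co-moves rigidly with its helmet, so the
    neuromagnetic geometry is motion-invariant), plus the movement
    artefact from the sensor trajectory through ``residual_field``
    (room-frame; defaults to the un-nulled remnant), plus drift and
    white sensor noise, clipped at the measurement range.
    """
    if mode is None:
        mode = OPMMode.measurement()
    rng = np.random.default_rng(seed)
    fs = sample_rate
    S = int(round(design.duration * fs))
    times = np.arange(S) / fs
    env = latent_envelopes(design, sources, times)
    if residual_field is None:
        residual_field = remnant.field

    data_blocks = []
    tables = []
    poses = {}
    moments = np.empty((2, S))
    n_sat = 0
    for p, (arr, model) in enumerate(zip(arrays, models)):
        carrier = _band_noise(rng, sources.oscillation_band, fs, S)
        Q = sources.baseline_beta_amplitude * env[p] * carrier
        moments[p] = Q
        dip = sources.dipoles[p]
        L = lead_field(dip.position, dip.orientation, arr, model)
        neural = np.outer(L, Q)

        # rigid-body motion composed with the helmet's base placement
        base = arr.pose.translations[0]
        mpose = gen_motion(motion, design.duration, MOTION_RATE, seed=motion.seed + 131 * p)
        pose = Pose(mpose.times, mpose.rotations, base + mpose.translations)
        poses[arr.helmet_id] = pose

        # movement artefact: sensors sweeping through the residual DC field,
        # evaluated at the motion rate and interpolated up to the data rate
        K = mpose.times.size
        R = pose.rotations
        pos_h = arr.positions
        ax_h = arr.orientations
        Rm = R.as_matrix()  # (K, 3, 3)
        p_room = np.einsum("kij,nj->kni", Rm, pos_h) + pose.translations[:, None, :]
        a_room = np.einsum("kij,nj->kni", Rm, ax_h)
        B_static = residual_field(p_room.reshape(-1, 3), 0.0).reshape(K, arr.n_sensors, 3)
        drift = remnant._drift(mpose.times)  # (K, 3)
        art_lo = np.einsum("kni,kni->nk", B_static + drift[:, None, :], a_room)
        artefact = np.empty((arr.n_sensors, S))
        for i in range(arr.n_sensors):
            artefact[i] = np.interp(times, mpose.times, art_lo[i])

        block = neural + artefact
        if include_noise and mode.noise_density > 0:
            block = block + rng.normal(
                0.0, mode.noise_density * np.sqrt(fs / 2.0), block.shape
            )
        n_sat += int(np.count_nonzero(np.abs(block) > mode.range))
        block = np.clip(block, -mode.range, mode.range)
        data_blocks.append(block)
        tables.append(
            pd.DataFrame(
                {
                    "name": ["%s_s%02d" % (arr.helmet_id, i) for i in range(arr.n_sensors)],
                    "helmet": arr.helmet_id,
                    "sensor_index": np.arange(arr.n_sensors),
                }
            )
        )

    events = pd.DataFrame({"time": design.event_times(), "code": design.event_codes()})
    rec = Recording(
        np.vstack(data_blocks),
        fs,
        pd.concat(tables, ignore_index=True),
        events,
        poses,
    )
    truth = GroundTruth(
        envelopes=env,
        moments=moments,
        dipoles=sources.dipoles,
        interbrain_lag=sources.interbrain_lag,
        poses=poses,
        event_times=design.event_times(),
        saturation_fraction=n_sat / rec.data.size,
    )
    return rec, truth
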