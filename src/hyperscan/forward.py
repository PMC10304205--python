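"""OPM sensing model and neuromagnetic forward model.

The neuromagnetic forward problem is solved in the homogeneous conducting
sphere: the field of a current dipole has the Sarvas closed form, in which
volume currents contribute no radial field and radially oriented dipoles
are externally silent.  Sensors are radial single-axis magnetometers
(optionally dual-axis in field-zeroing mode) rigidly mounted in a helmet
whose pose in the room evolves as a tracked rigid body.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

MU0 = 4e-7 * np.pi


class GeometryError(ValueError):
    """Raised for degenerate source/sensor geometry."""


# ---------------------------------------------------------------------------
# Sarvas field of a current dipole in a conducting sphere
# ---------------------------------------------------------------------------

def dipole_field_sphere(dipole_position, dipole_moment, sphere_centre, r) -> np.ndarray:
    """Magnetic field of a current dipole inside a homogeneous conducting sphere.

    Parameters
    ----------
    dipole_position : (..., 3) array
        Dipole location(s) in metres.
    dipole_moment : (..., 3) array
        Dipole moment(s) in A*m (orientation times strength).
    sphere_centre : (3,) array
        Centre of the conducting sphere.
    r : (..., 3) array
        Field evaluation point(s), outside the conductor.

    All leading dimensions broadcast.  Returns the field in tesla.

    Notes
    -----
    Implements the closed-form solution for the external field of a
    current dipole in a spherically symmetric conductor.  With
    ``a = r - r0`` (all positions relative to the sphere centre),

    ``F = a (r a + r^2 - r0 . r)``

    ``grad F = (a^2/r + a.r/a + 2a + 2r) r - (a + 2r + a.r/a) r0``

    ``B = mu0 / (4 pi F^2) (F (q x r0) - ((q x r0) . r) grad F)``

    The result is independent of the (unspecified) conductivity, decays
    at least as 1/d^2, and vanishes identically for radial dipoles.
    """
    c = np.asarray(sphere_centre, dtype=float)
    r0 = np.asarray(dipole_position, dtype=float) - c
    q = np.asarray(dipole_moment, dtype=float)
    rv = np.asarray(r, dtype=float) - c

    r0, q, rv = np.broadcast_arrays(r0, q, rv)
    a_vec = rv - r0
    a = np.linalg.norm(a_vec, axis=-1)
    rn = np.linalg.norm(rv, axis=-1)
    if np.any(rn < 1e-12):
        raise GeometryError("field evaluation point at the sphere centre")
    if np.any(a < 1e-12):
        raise GeometryError("field evaluation point coincides with the dipole")

    dot_ar = np.einsum("...i,...i->...", a_vec, rv)
    dot_r0r = np.einsum("...i,...i->...", r0, rv)
    F = a * (rn * a + rn**2 - dot_r0r)
    gF = (
        (a**2 / rn + dot_ar / a + 2.0 * a + 2.0 * rn)[..., None] * rv
        - (a + 2.0 * rn + dot_ar / a)[..., None] * r0
    )
    qxr0 = np.cross(q, r0)
    dot_qxr0_r = np.einsum("...i,...i->...", qxr0, rv)
    with np.errstate(divide="raise", invalid="raise"):
        B = (MU0 / (4.0 * np.pi * F**2))[..., None] * (
            F[..., None] * qxr0 - dot_qxr0_r[..., None] * gF
        )
    return B


# ---------------------------------------------------------------------------
# Rigid-body pose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pose:
    """Time series of rigid-body transforms (helmet frame -> room frame).

    Interpolation between tracked samples is piecewise linear for the
    translation and spherical-linear (slerp) for the rotation; motion
    bandwidth is far below the data sample rate so this is exact for all
    practical purposes.
    """

    times: np.ndarray  # (K,), strictly increasing, seconds
    rotations: Rotation  # length K
    translations: np.ndarray  # (K, 3), metres

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        tr = np.asarray(self.translations, dtype=float)
        if t.ndim != 1 or len(self.rotations) != t.size or tr.shape != (t.size, 3):
            raise ValueError("inconsistent pose arrays")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("pose timestamps must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "translations", tr)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.array([0.0]), Rotation.identity(1), np.zeros((1, 3)))

    def at(self, t) -> tuple[Rotation, np.ndarray]:
        """Interpolated (rotation, translation) at time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 1:
            R = Rotation.from_quat(
                np.repeat(self.rotations.as_quat()[:1], t.size, axis=0)
            )
            T = np.repeat(self.translations[:1], t.size, axis=0)
            return R, T
        tc = np.clip(t, self.times[0], self.times[-1])
        R = Slerp(self.times, self.rotations)(tc)
        T = np.empty((t.size, 3))
        for k in range(3):
            T[:, k] = np.interp(tc, self.times, self.translations[:, k])
        return R, T


# ---------------------------------------------------------------------------
# Sensors
# ---------------------------------------------------------------------------

def default_second_axis(orientation: np.ndarray) -> np.ndarray:
    """Deterministic second measurement axis for field-zeroing mode.

    The projection of the helmet x-axis orthogonal to the radial axis,
    normalised; falls back to the y-axis when the radial axis is within
    ~1e-6 of x.
    """
    u = np.asarray(orientation, dtype=float)
    for ref in (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])):
        v = ref - np.dot(ref, u) * u
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n
    raise GeometryError("cannot construct a second axis")


@dataclass(frozen=True)
class OPMSensor:
    """A single OPM: position and radial measurement axis in the helmet frame."""

    position: np.ndarray
    orientation: np.ndarray  # unit vector, radial axis
    second_axis: Optional[np.ndarray] = None  # unit vector, field-zeroing axis
    used_for_nulling: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        u = np.asarray(self.orientation, dtype=float)
        nu = np.linalg.norm(u)
        if not np.isclose(nu, 1.0, atol=1e-6):
            raise ValueError("orientation must be a unit vector")
        u = u / nu
        if self.second_axis is None:
            v = default_second_axis(u)
        else:
            v = np.asarray(self.second_axis, dtype=float)
            v = v / np.linalg.norm(v)
            if abs(np.dot(u, v)) > 1e-6:
                raise ValueError("second_axis must be orthogonal to orientation")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "orientation", u)
        object.__setattr__(self, "second_axis", v)


@dataclass(frozen=True)
class SensorArray:
    """All OPMs of one helmet plus the helmet's rigid-body pose."""

    sensors: tuple
    pose: Pose = field(default_factory=Pose.identity)
    helmet_id: str = "helmet"

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sensors])

    @property
    def orientations(self) -> np.ndarray:
        return np.array([s.orientation for s in self.sensors])

    @property
    def second_axes(self) -> np.ndarray:
        return np.array([s.second_axis for s in self.sensors])

    @property
    def nulling_indices(self) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sensors) if s.used_for_nulling], dtype=int
        )

    def with_pose(self, pose: Pose) -> "SensorArray":
        return replace(self, pose=pose)


@dataclass(frozen=True)
class OPMMode:
    """Operating mode of the OPMs: measurement range, gain, noise floor."""

    mode: str  # "field_zeroing" or "measurement"
    range: float  # tesla (full scale +/-range)
    gain_factor: float = 1.0
    noise_density: float = 15e-15  # T/sqrt(Hz)

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ValueError("range must be positive")
        if self.mode not in ("field_zeroing", "measurement"):
            raise ValueError("mode must be 'field_zeroing' or 'measurement'")

    @classmethod
    def field_zeroing(cls, noise_density: float = 15e-15) -> "OPMMode":
        """Dual-axis DC mode, +/-50 nT range."""
        return cls("field_zeroing", 50e-9, 1.0, noise_density)

    @classmethod
    def measurement(cls, noise_density: float = 15e-15) -> "OPMMode":
        """Radial-axis recording mode at 0.33x gain, +/-5 nT range."""
        return cls("measurement", 5e-9, 0.33, noise_density)


def sense(
    sensors: SensorArray,
    mode: OPMMode,
    ambient_field: Callable[[np.ndarray, float], np.ndarray],
    t,
    rng: Optional[np.random.Generator] = None,
    sample_rate: Optional[float] = None,
):
    """Project an ambient field onto each sensor's measurement axis/axes.

    ``ambient_field(points, t)`` must return an (N, 3) field (tesla) at
    room-frame ``points`` and time ``t``.  Readings are clipped silently
    at ``+/-mode.range``; clipping is flagged per sample in the returned
    saturation mask.  When ``rng`` and ``sample_rate`` are given, white
    sensor noise of density ``mode.noise_density`` is added before
    clipping.

    Returns ``(readings, saturated)`` with shape (n_channels, n_times);
    in field-zeroing mode each sensor contributes two consecutive
    channels (radial axis first, then the second axis).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    R, T = sensors.pose.at(t)
    pos = sensors.positions
    ax1 = sensors.orientations
    dual = mode.mode == "field_zeroing"
    n_ch = sensors.n_sensors * (2 if dual else 1)
    readings = np.empty((n_ch, t.size))
    for j, tj in enumerate(t):
        Rj = R[j]
        p_room = Rj.apply(pos) + T[j]
        B = np.asarray(ambient_field(p_room, tj), dtype=float)
        b1 = np.einsum("ij,ij->i", B, Rj.apply(ax1))
        if dual:
            b2 = np.einsum("ij,ij->i", B, Rj.apply(sensors.second_axes))
            readings[0::2, j] = b1
            readings[1::2, j] = b2
        else:
            readings[:, j] = b1
    if rng is not None and sample_rate is not None and mode.noise_density > 0:
        sigma = mode.noise_density * np.sqrt(sample_rate / 2.0)
        readings = readings + rng.normal(0.0, sigma, readings.shape)
    saturated = np.abs(readings) > mode.range
    readings = np.clip(readings, -mode.range, mode.range)
    return readings, saturated


# ---------------------------------------------------------------------------
# Sources, head model, lead fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dipole:
    """A current dipole source: position, unit orientation, moment timecourse."""

    position: np.ndarray  # metres, head frame
    orientation: np.ndarray  # unit vector
    moment: Optional[np.ndarray] = None  # A*m timecourse

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float)
        u = np.asarray(self.orientation, dtype=float)
        u = u / np.linalg.norm(u)
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "orientation", u)


@dataclass(frozen=True)
class SphereModel:
    """Conducting-sphere head model: one shared centre or one per channel."""

    centre: np.ndarray  # (3,) shared, or (N, 3) per channel
    radius: float = 0.09

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "centre", np.asarray(self.centre, dtype=float))

    def centre_for_channel(self, i: int) -> np.ndarray:
        c = self.centre
        return c if c.ndim == 1 else c[i]


def lead_field(position, orientation, sensors: SensorArray, model: SphereModel) -> np.ndarray:
    """Forward field of a unit dipole projected on each radial sensor axis.

    Sensors are taken in their fixed reference (helmet-frame) pose.
    Returns an (N,) vector in T/(A*m).
    """
    pos = np.asarray(position, dtype=float)
    ori = np.asarray(orientation, dtype=float)
    ori = ori / np.linalg.norm(ori)
    L = np.empty(sensors.n_sensors)
    c = model.centre
    if c.ndim == 1:
        B = dipole_field_sphere(pos, ori, c, sensors.positions)
        L = np.einsum("ij,ij->i", B, sensors.orientations)
    else:
        for i, s in enumerate(sensors.sensors):
            B = dipole_field_sphere(pos, ori, c[i], s.position)
            L[i] = float(np.dot(B, s.orientation))
    return L


def lead_field_grid(points, sensors: SensorArray, model: SphereModel) -> np.ndarray:
    """Lead fields for unit dipoles along x, y, z at many source points.

    Returns (P, 3, N): for each of P points, the N-channel lead field of
    a unit dipole along each Cartesian axis.  Vectorised over points for
    whole-volume beamformer scans.
    """
    pts = np.asarray(points, dtype=float)
    P = pts.shape[0]
    N = sensors.n_sensors
    out = np.empty((P, 3, N))
    eye = np.eye(3)
    c_shared = model.centre if model.centre.ndim == 1 else None
    for i in range(N):
        s = sensors.sensors[i]
        centre = c_shared if c_shared is not None else model.centre[i]
        for k in range(3):
            B = dipole_field_sphere(pts, eye[k], centre, s.position)
            out[:, k, i] = B @ s.orientation
    return out


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel field time series with trial annotations.

    ``data`` is channels x samples in tesla; ``channel_table`` is a
    DataFrame with columns ``name``, ``helmet``, ``sensor_index``;
    ``events`` is a DataFrame with columns ``time`` (s) and ``code``.
    """

    data: np.ndarray
    sample_rate: float
    channel_table: pd.DataFrame
    events: pd.DataFrame
    poses: dict = field(default_factory=dict)  # helmet_id -> Pose

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.data.shape[0] != len(self.channel_table):
            raise ValueError("channel table does not match data")
        dur = self.duration
        if len(self.events) and (
            self.events["time"].min() < 0 or self.events["time"].max() > dur
        ):
            raise ValueError("event times outside record duration")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channels_for_helmet(self, helmet_id: str) -> np.ndarray:
        return np.flatnonzero((self.channel_table["helmet"] == helmet_id).to_numpy())

    def pick(self, idx) -> "Recording":
        """Sub-recording restricted to the given channel indices."""
        idx = np.asarray(idx, dtype=int)
        return Recording(
            self.data[idx],
            self.sample_rate,
            self.channel_table.iloc[idx].reset_index(drop=True),
            self.events.copy(),
            self.poses,
        )

    def save(self, path) -> None:
        from .io import save_recording

        save_recording(self, path)

    @classmethod
    def load(cls, path) -> "Recording":
        from .io import load_recording

        return load_recording(path)
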