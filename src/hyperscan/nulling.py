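"""Data-driven field nulling with the matrix coil.

The remnant field over two sensor helmets is cancelled in three stages:

1. *Calibration*: a current pulse is applied to each unit coil in turn
   while the dual-axis DC readings of the nulling sensors are recorded;
   the field change per unit current populates the N x M calibration
   matrix ``A``.
2. *Current solution*: the Tikhonov-regularised minimum-power currents
   ``x = -A^T (A A^T + alpha I)^(-1) b`` drive the measured field vector
   ``b`` towards zero while keeping the dissipated power (and the coil
   currents) small.  For ``alpha = 0`` and full-row-rank ``A`` this is
   the Moore-Penrose solution of ``A x = -b``.
3. *Feed-forward control*: currents are updated incrementally,
   ``x_i = x_{i-1} - G A^T (A A^T + alpha I)^(-1) b_i``, quantised to the
   DAC grid and clipped to the driver limits, until the residual field
   stops decreasing.  The final currents are then held constant for the
   recording; no dynamic field tracking is applied.

``alpha`` is set per calibration to a fraction (default 1%) of the
largest singular value of ``A A^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .coilfield import CoilArray, DriverElectronics, max_current, quantize_current
from .forward import OPMMode, SensorArray, sense


class CalibrationError(RuntimeError):
    """A sensor saturated (or otherwise failed) during coil calibration."""


class InstabilityError(RuntimeError):
    """The feed-forward loop diverged (gain too large for the geometry)."""


@dataclass(frozen=True)
class CalibrationMatrix:
    """Field change per unit coil current at every nulling measurement.

    ``A[n, m]`` is the field (T) measured by nulling measurement ``n``
    (a sensor/axis pair) per ampere in coil ``m``.
    """

    A: np.ndarray  # (N, M), T/A
    row_labels: tuple  # (sensor label, axis index) per measurement
    col_labels: tuple  # coil ids

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if not np.all(np.isfinite(A)):
            raise ValueError("calibration matrix must be finite")
        object.__setattr__(self, "A", A)

    @property
    def n_measurements(self) -> int:
        return self.A.shape[0]

    @property
    def n_coils(self) -> int:
        return self.A.shape[1]

    def default_alpha(self, alpha_fraction: float = 0.01) -> float:
        """``alpha_fraction`` times the largest singular value of A A^T."""
        smax = np.linalg.svd(self.A, compute_uv=False)[0]
        return float(alpha_fraction * smax**2)


@dataclass(frozen=True)
class NullingState:
    """Snapshot of the feed-forward controller."""

    x: np.ndarray  # (M,) coil currents, A
    b: np.ndarray  # (N,) last measured DC fields, T
    gain: float
    alpha: float
    dt: float
    iteration: int = 0
    saturated: bool = False


# ---------------------------------------------------------------------------
# DC measurement helper
# ---------------------------------------------------------------------------

def nulling_view(sensors: SensorArray) -> SensorArray:
    """Sub-array containing only the sensors flagged for nulling."""
    idx = sensors.nulling_indices
    if idx.size == 0:
        raise ValueError("no sensors flagged used_for_nulling on %s" % sensors.helmet_id)
    return replace(sensors, sensors=tuple(sensors.sensors[i] for i in idx))


def measurement_labels(arrays: Sequence[SensorArray]) -> tuple:
    labels = []
    for arr in arrays:
        for i in arr.nulling_indices:
            for axis in (0, 1):
                labels.append(("%s/s%02d" % (arr.helmet_id, i), axis))
    return tuple(labels)


def measure_dc(
    arrays: Sequence[SensorArray],
    ambient: Callable[[np.ndarray, float], np.ndarray],
    t: float,
    mode: Optional[OPMMode] = None,
    rng: Optional[np.random.Generator] = None,
    sample_rate: Optional[float] = None,
    n_samples: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Dual-axis DC field readings of all nulling sensors, both helmets.

    Returns ``(b, saturated)``; ``b`` stacks, per helmet, two channels
    per nulling sensor (radial axis then second axis), averaged over
    ``n_samples`` consecutive samples.
    """
    if mode is None:
        mode = OPMMode.field_zeroing()
    ts = t + np.arange(n_samples) * (1.0 / sample_rate if sample_rate else 0.0)
    chunks = []
    sats = []
    for arr in arrays:
        view = nulling_view(arr)
        readings, sat = sense(view, mode, ambient, ts, rng=rng, sample_rate=sample_rate)
        chunks.append(readings.mean(axis=1))
        sats.append(sat.any(axis=1))
    return np.concatenate(chunks), np.concatenate(sats)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    array: CoilArray,
    sensor_arrays: Sequence[SensorArray],
    electronics: DriverElectronics,
    ambient: Callable[[np.ndarray, float], np.ndarray],
    pulse_current: float = 5.0 / 1200.0,
    pulse_duration: float = 0.1,
    rng: Optional[np.random.Generator] = None,
    sample_rate: Optional[float] = None,
    n_samples: int = 8,
    t_start: float = 0.0,
) -> CalibrationMatrix:
    """Pulse each coil in turn and measure the per-coil field responses.

    For every coil the DC readings of all nulling sensors are taken over
    an equal-length pre-pulse baseline and over the pulse plateau; the
    difference divided by the (quantised) pulse current gives one column
    of ``A``.  Sensors must remain stationary.  A saturated reading
    during a pulse raises :class:`CalibrationError` naming the
    sensor/coil pair.
    """
    if abs(pulse_current) > max_current(electronics):
        raise ValueError("pulse current exceeds driver limit")
    i_pulse = quantize_current(electronics, pulse_current)
    if i_pulse == 0.0:
        raise ValueError("pulse current quantises to zero")
    labels = measurement_labels(sensor_arrays)
    M = array.n_coils
    N = len(labels)
    A = np.empty((N, M))
    t = t_start
    for m in range(M):
        def base_field(points, tt):
            return ambient(points, tt)

        b0, sat0 = measure_dc(
            sensor_arrays, base_field, t, rng=rng, sample_rate=sample_rate,
            n_samples=n_samples,
        )
        t += pulse_duration

        def pulsed_field(points, tt, _m=m):
            x = np.zeros(M)
            x[_m] = i_pulse
            return ambient(points, tt) + array.field(points, x)

        b1, sat1 = measure_dc(
            sensor_arrays, pulsed_field, t, rng=rng, sample_rate=sample_rate,
            n_samples=n_samples,
        )
        t += pulse_duration
        sat = sat0 | sat1
        if np.any(sat):
            n_bad = int(np.flatnonzero(sat)[0])
            raise CalibrationError(
                "saturated reading at measurement %s during pulse of coil %d"
                % (labels[n_bad], m)
            )
        A[:, m] = (b1 - b0) / i_pulse
    return CalibrationMatrix(A, labels, tuple(range(M)))


# ---------------------------------------------------------------------------
# Regularised current solution and controller
# ---------------------------------------------------------------------------

def solve_currents(calib: CalibrationMatrix, b: np.ndarray, alpha: float) -> np.ndarray:
    """Minimum-power Tikhonov currents ``x = -A^T (A A^T + alpha I)^(-1) b``.

    Equivalently the minimiser of ``||A x + b||^2 + alpha ||x||^2``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    A = calib.A
    b = np.asarray(b, dtype=float)
    if b.shape != (A.shape[0],):
        raise ValueError("field vector length does not match calibration")
    K = A @ A.T + alpha * np.eye(A.shape[0])
    if alpha == 0.0 and (
        np.linalg.matrix_rank(A) < A.shape[0]
        or np.linalg.cond(K) > 1e12
    ):
        raise np.linalg.LinAlgError(
            "A A^T is singular (rank-deficient calibration); use alpha > 0"
        )
    return -A.T @ np.linalg.solve(K, b)


def feedforward_step(
    state: NullingState,
    calib: CalibrationMatrix,
    b_now: np.ndarray,
    electronics: DriverElectronics,
) -> NullingState:
    """One controller update: scaled regularised step, quantised and clipped."""
    dx = solve_currents(calib, b_now, state.alpha)
    x_raw = state.x + state.gain * dx
    i_max = max_current(electronics)
    saturated = bool(np.any(np.abs(x_raw) > i_max))
    x_new = quantize_current(electronics, np.clip(x_raw, -i_max, i_max))
    return replace(
        state,
        x=x_new,
        b=np.asarray(b_now, dtype=float),
        iteration=state.iteration + 1,
        saturated=saturated,
    )


@dataclass
class NullingResult:
    """Outcome of a nulling run, mirroring the stored hardware log."""

    state: NullingState
    calibration: CalibrationMatrix
    pre_fields: np.ndarray  # (N,) T, before nulling
    post_fields: np.ndarray  # (N,) T, with final currents applied
    residual_norms: list  # mean |b| per iteration
    converged: bool
    electronics: DriverElectronics

    @property
    def final_voltages(self) -> np.ndarray:
        return self.state.x * self.electronics.series_resistance

    @property
    def reduction_factor(self) -> float:
        """Mean |field| before nulling over mean |field| after."""
        post = np.mean(np.abs(self.post_fields))
        return float(np.mean(np.abs(self.pre_fields)) / post) if post > 0 else np.inf

    def residual_field(self, array: CoilArray, remnant):
        """Room-frame residual field function with the final currents held."""
        x = self.state.x

        def f(points, t):
            return remnant(points, t) + array.field(points, x)

        return f

    def save(self, path) -> None:
        from .io import save_nulling_log

        save_nulling_log(self, path)


def run_nulling(
    array: CoilArray,
    sensor_arrays: Sequence[SensorArray],
    remnant: Callable[[np.ndarray, float], np.ndarray],
    electronics: Optional[DriverElectronics] = None,
    gain: float = 0.1,
    alpha_fraction: float = 0.01,
    dt: float = 0.1,
    max_steps: int = 600,
    rel_tol: float = 1e-3,
    tol_steps: int = 5,
    divergence_steps: int = 10,
    calibration: Optional[CalibrationMatrix] = None,
    rng: Optional[np.random.Generator] = None,
    sample_rate: Optional[float] = None,
) -> NullingResult:
    """Calibrate (unless given) and run the feed-forward nulling loop.

    Iterates :func:`feedforward_step` against DC measurements of
    ``remnant`` plus the currently applied coil field, at intervals of
    ``dt`` seconds, until the mean |field| changes by less than
    ``rel_tol`` (relatively) for ``tol_steps`` consecutive steps, or
    ``max_steps`` is reached.  A mean |field| growing for
    ``divergence_steps`` consecutive steps raises
    :class:`InstabilityError` (the gain-too-large failure mode).  The
    final currents are held constant; re-measured fields with those
    currents applied are stored as ``post_fields``.
    """
    if electronics is None:
        electronics = DriverElectronics()
    if calibration is None:
        calibration = calibrate(
            array, sensor_arrays, electronics, remnant,
            rng=rng, sample_rate=sample_rate,
        )
    alpha = calibration.default_alpha(alpha_fraction)
    M = array.n_coils
    t = 0.0

    def ambient_with_currents(x):
        def f(points, tt):
            B = remnant(points, tt)
            if np.any(x):
                B = B + array.field(points, x)
            return B

        return f

    pre_fields, _ = measure_dc(
        sensor_arrays, remnant, t, rng=rng, sample_rate=sample_rate
    )
    state = NullingState(
        x=np.zeros(M), b=pre_fields.copy(), gain=gain, alpha=alpha, dt=dt
    )
    residual_norms = [float(np.mean(np.abs(pre_fields)))]
    converged = residual_norms[0] == 0.0
    flat = 0
    growing = 0
    while not converged and state.iteration < max_steps:
        t += dt
        b_now, _ = measure_dc(
            sensor_arrays, ambient_with_currents(state.x), t,
            rng=rng, sample_rate=sample_rate,
        )
        state = feedforward_step(state, calibration, b_now, electronics)
        norm = float(np.mean(np.abs(b_now)))
        prev = residual_norms[-1]
        residual_norms.append(norm)
        growing = growing + 1 if norm > prev else 0
        if growing >= divergence_steps:
            raise InstabilityError(
                "residual field grew for %d consecutive steps; "
                "reduce the controller gain" % divergence_steps
            )
        # a residual far above its starting level means the loop has gone
        # unstable even if quantization/clipping bounds the oscillation
        if norm > 3.0 * max(residual_norms[0], 1e-15):
            raise InstabilityError(
                "residual field grew far beyond its initial level; "
                "reduce the controller gain"
            )
        flat = flat + 1 if abs(norm - prev) <= rel_tol * max(prev, 1e-30) else 0
        if flat >= tol_steps:
            converged = True
    post_fields, _ = measure_dc(
        sensor_arrays, ambient_with_currents(state.x), t + dt,
        rng=rng, sample_rate=sample_rate,
    )
    state = replace(state, b=post_fields)
    return NullingResult(
        state=state,
        calibration=calibration,
        pre_fields=pre_fields,
        post_fields=post_fields,
        residual_norms=residual_norms,
        converged=converged,
        electronics=electronics,
    )
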