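"""Magnetostatics of the bi-planar matrix coil and its driver electronics.

The active-shielding hardware modelled here is a pair of parallel planes,
each tiled with 24 square unit coils: a 4x4 grid plus an overlapping 3x3
grid (offset by half a pitch) whose central coil is omitted, giving 48
independently driven coils in total.  Every coil is a ten-turn square
filament; its field anywhere in space follows from the exact Biot-Savart
law for finite straight segments.  The driver electronics (16-bit DACs
behind a large series resistance) set the current resolution, the maximum
current and the current-noise floor that propagates into magnetic field
noise at the sensors.

All quantities are SI internally: metres, amperes, tesla.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

#: minimum distance (m) from an evaluation point to a wire filament
WIRE_TOLERANCE = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a field is requested on (or numerically at) a wire."""


@dataclass(frozen=True)
class WireLoop:
    """A closed polygonal filament carrying ``turns`` co-located turns.

    Parameters
    ----------
    vertices : (K, 3) array
        Ordered corner points in metres.  The polygon is closed
        implicitly (the last vertex connects back to the first).
    turns : int
        Number of turns; the loop field scales linearly with it.
    """

    vertices: np.ndarray
    turns: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise ValueError("vertices must be (K>=3, 3)")
        if self.turns < 1:
            raise ValueError("turns must be >= 1")
        object.__setattr__(self, "vertices", v)

    @property
    def n_segments(self) -> int:
        return self.vertices.shape[0]

    @property
    def centre(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def wire_length(self) -> float:
        """Total length of wire across all turns (m)."""
        seg = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(self.turns * np.linalg.norm(seg, axis=1).sum())

    def reversed(self) -> "WireLoop":
        return WireLoop(self.vertices[::-1].copy(), self.turns)


def segment_field(p1, p2, r, current: float) -> np.ndarray:
    """Exact Biot-Savart field of a finite straight segment.

    Uses the closed form
    ``B = mu0 I / 4pi * (a x b)(|a|+|b|) / (|a||b|(|a||b| + a.b))``
    with ``a = r - p1`` and ``b = r - p2``, which is regular everywhere
    off the segment and antisymmetric in the current.

    ``r`` may be a single point or an (P, 3) array of points.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    rr = np.atleast_2d(r)

    a = rr - p1
    b = rr - p2
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb * (na * nb + np.einsum("ij,ij->i", a, b))
    if np.any(na < WIRE_TOLERANCE) or np.any(nb < WIRE_TOLERANCE) or np.any(
        denom < WIRE_TOLERANCE**2
    ):
        raise DegenerateGeometryError("evaluation point lies on the wire segment")
    cross = np.cross(a, b)
    B = (MU0 * current / (4 * np.pi)) * cross * ((na + nb) / denom)[:, None]
    return B[0] if single else B


def coil_field(coil: WireLoop, r, current: float) -> np.ndarray:
    """Field of a closed polygonal loop: turns x sum of segment fields."""
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    rr = np.atleast_2d(r)
    B = np.zeros_like(rr)
    verts = coil.vertices
    nxt = np.roll(verts, -1, axis=0)
    for p1, p2 in zip(verts, nxt):
        B += segment_field(p1, p2, rr, current)
    B *= coil.turns
    return B[0] if single else B


@dataclass(frozen=True)
class CoilArray:
    """The set of M unit coils making up the matrix coil."""

    coils: tuple
    plane_separation: float
    side_length: float
    layout_ids: tuple  # per-coil (plane, grid, row, col)

    @property
    def n_coils(self) -> int:
        return len(self.coils)

    def unit_fields(self, r) -> np.ndarray:
        """Field vector per unit current of every coil at point(s) ``r``.

        Returns (M, 3) for a single point or (M, P, 3) for P points.
        """
        r = np.asarray(r, dtype=float)
        return np.stack([coil_field(c, r, 1.0) for c in self.coils])

    def field(self, r, currents) -> np.ndarray:
        """Superposed field at ``r`` for a length-M current vector."""
        currents = np.asarray(currents, dtype=float)
        if currents.shape != (self.n_coils,):
            raise ValueError("currents must have one entry per coil")
        U = self.unit_fields(r)
        return np.einsum("m,m...->...", currents, U)


def _square_loop(centre: np.ndarray, side: float, turns: int) -> WireLoop:
    """Axis-aligned square loop in a z = const plane, normal along +z."""
    h = side / 2.0
    cx, cy, cz = centre
    verts = np.array(
        [
            [cx - h, cy - h, cz],
            [cx + h, cy - h, cz],
            [cx + h, cy + h, cz],
            [cx - h, cy + h, cz],
        ]
    )
    return WireLoop(verts, turns)


def build_matrix_coil(
    side_length: float = 0.38,
    plane_separation: float = 1.50,
    turns: int = 10,
) -> CoilArray:
    """Construct the default 48-coil bi-planar matrix coil.

    Each plane holds a 4x4 grid of square coils tiled edge-to-edge
    (pitch = side length) plus a 3x3 grid offset by half a pitch with its
    central coil omitted (8 coils), i.e. 24 coils per plane.  The planes
    face each other at ``plane_separation``, centred on the z axis; the
    origin sits at the midpoint between them.
    """
    if side_length <= 0 or plane_separation <= 0:
        raise ValueError("dimensions must be positive")
    pitch = side_length
    coils = []
    ids = []
    for plane, z in enumerate((-plane_separation / 2.0, plane_separation / 2.0)):
        # 4x4 main grid, centres at +/-0.5 and +/-1.5 pitches
        for row in range(4):
            for col in range(4):
                cx = (col - 1.5) * pitch
                cy = (row - 1.5) * pitch
                coils.append(_square_loop(np.array([cx, cy, z]), side_length, turns))
                ids.append((plane, "main", row, col))
        # overlapping 3x3 grid offset by half a pitch, centre omitted
        for row in range(3):
            for col in range(3):
                if row == 1 and col == 1:
                    continue
                cx = (col - 1.0) * pitch
                cy = (row - 1.0) * pitch
                coils.append(_square_loop(np.array([cx, cy, z]), side_length, turns))
                ids.append((plane, "offset", row, col))
    return CoilArray(tuple(coils), plane_separation, side_length, tuple(ids))


@dataclass(frozen=True)
class DriverElectronics:
    """Voltage-driven coil electronics: DAC resolution and current limits.

    Defaults model a +/-10 V amplifier behind a 16-bit DAC and a 1.2 kOhm
    series resistance, giving a maximum coil current of +/-8.33 mA and a
    current resolution (lsb) of ~0.254 uA.  Coil resistance and
    inductance are retained as metadata only; the controller operates at
    DC so no electrical transients are modelled.
    """

    v_max: float = 10.0
    dac_bits: int = 16
    series_resistance: float = 1200.0
    current_noise_density: float = 10e-9  # A/sqrt(Hz)
    coil_resistance: float = 2.0
    coil_inductance: float = 160e-6

    def __post_init__(self) -> None:
        if self.v_max < 0:
            raise ValueError("v_max must be non-negative")
        if self.dac_bits < 1:
            raise ValueError("dac_bits must be >= 1")
        if self.series_resistance <= 0:
            raise ValueError("series_resistance must be positive")

    @property
    def lsb_voltage(self) -> float:
        return 2.0 * self.v_max / 2**self.dac_bits

    @property
    def lsb_current(self) -> float:
        return self.lsb_voltage / self.series_resistance


def max_current(d: DriverElectronics) -> float:
    """Largest current the driver can push through one coil (A)."""
    return d.v_max / d.series_resistance


def quantize_current(d: DriverElectronics, i_requested) -> np.ndarray | float:
    """Snap a requested current to the DAC grid, clipped to the full scale.

    The representable currents are integer multiples of the lsb current;
    the operation is idempotent and never exceeds ``max_current`` in
    magnitude.
    """
    i = np.asarray(i_requested, dtype=float)
    lsb = d.lsb_current
    if lsb == 0.0:
        q = np.zeros_like(i)
    else:
        q = np.round(i / lsb) * lsb
    q = np.clip(q, -max_current(d), max_current(d))
    return float(q) if np.isscalar(i_requested) or q.ndim == 0 else q


def coil_noise_at_point(
    array: CoilArray, d: DriverElectronics, r, axis=None
) -> float:
    """Magnetic field noise density at ``r`` from independent coil currents.

    Each coil carries current noise ``d.current_noise_density``; the
    per-coil field-per-unit-current projections combine in quadrature
    over the M coils (independent sources).  An OPM measures a single
    field component, so the reported number is the noise density in a
    measured component: along ``axis`` when given, otherwise the
    worst case over field components.  Returns T/sqrt(Hz).
    """
    U = array.unit_fields(np.asarray(r, dtype=float))  # (M, 3)
    if axis is not None:
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        return float(np.sqrt(((U @ a) ** 2).sum()) * d.current_noise_density)
    per_component = np.sqrt((U**2).sum(axis=0)) * d.current_noise_density
    return float(per_component.max())
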