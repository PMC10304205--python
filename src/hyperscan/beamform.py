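"""LCMV beamformer source analysis.

A linearly constrained minimum-variance spatial filter reconstructs the
source strength at a location/orientation theta as
``Q(t) = w^T m(t)`` with weights

``w = (C + mu I)^(-1) L / (L^T (C + mu I)^(-1) L)``

which minimise the output variance subject to unit gain ``w^T L = 1``.
Task-versus-control power contrasts are mapped with the pseudo-T
statistic ``(w^T Ca w - w^T Cc w) / (2 w^T Cc w)`` evaluated on a
regular lattice over the head sphere, with the source orientation at
each point chosen (analytically) to extremise the contrast over the
tangential plane; radial orientations are externally silent in the
spherical conductor and are excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .forward import Recording, SensorArray, SphereModel, lead_field, lead_field_grid


def bandpass(data: np.ndarray, band, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward, reflection padding)."""
    lo, hi = band
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    if hi >= nyq:
        raise ValueError("band extends to or beyond the Nyquist frequency")
    sos = butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sosfiltfilt(sos, data, axis=-1)


@dataclass(frozen=True)
class Covariance:
    """Band-limited sensor data covariance with its Tikhonov parameter."""

    C: np.ndarray  # (N, N), T^2
    band: tuple  # Hz
    window: tuple  # ((t0, t1), ...) time intervals used
    mu: float = 0.0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if not np.allclose(C, C.T, atol=1e-20 + 1e-10 * np.abs(C).max()):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "C", 0.5 * (C + C.T))

    @property
    def n_channels(self) -> int:
        return self.C.shape[0]

    def regularized(self, mu_fraction: float = 0.01) -> "Covariance":
        """Set mu to ``mu_fraction`` times the largest singular value of C."""
        smax = np.linalg.svd(self.C, compute_uv=False)[0]
        return Covariance(self.C, self.band, self.window, float(mu_fraction * smax))

    @property
    def C_reg(self) -> np.ndarray:
        return self.C + self.mu * np.eye(self.n_channels)


def compute_covariance(
    rec: Recording,
    band,
    windows: Optional[Sequence] = None,
) -> Covariance:
    """Sample covariance of band-filtered, mean-removed data.

    ``windows`` is a list of (t0, t1) intervals (seconds) whose samples
    are concatenated; None uses the whole recording.  A warning is
    issued when the total window is shorter than three filter
    time-constants of the band's lower edge.
    """
    import warnings

    filtered = bandpass(rec.data, band, rec.sample_rate)
    if windows is None:
        windows = ((0.0, rec.duration),)
    fs = rec.sample_rate
    segments = []
    total = 0.0
    for t0, t1 in windows:
        if t1 <= t0:
            raise ValueError("empty covariance window")
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
        if i1 <= i0:
            raise ValueError("covariance window outside the recording")
        segments.append(filtered[:, i0:i1])
        total += (i1 - i0) / fs
    if total < 3.0 / band[0]:
        warnings.warn(
            "covariance window shorter than 3 filter time-constants", stacklevel=2
        )
    X = np.concatenate(segments, axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    C = X @ X.T / max(X.shape[1] - 1, 1)
    return Covariance(C, tuple(band), tuple(tuple(w) for w in windows))


@dataclass(frozen=True)
class BeamformerWeights:
    """Unit-gain LCMV weights for one source point."""

    w: np.ndarray  # (N,)
    theta: tuple  # (position (3,), orientation (3,))

    def apply(self, data: np.ndarray) -> np.ndarray:
        return self.w @ data


def beamformer_weights(L: np.ndarray, C: Covariance) -> BeamformerWeights:
    """LCMV weights ``w = Creg^-1 L / (L^T Creg^-1 L)`` (unit gain at theta)."""
    L = np.asarray(L, dtype=float)
    if np.linalg.norm(L) == 0.0:
        raise ValueError("zero lead field (magnetically silent source)")
    CiL = np.linalg.solve(C.C_reg, L)
    denom = float(L @ CiL)
    if denom <= 0:
        raise ValueError("covariance is not positive definite for this source")
    return BeamformerWeights(CiL / denom, (None, None))


def pseudo_t(w: BeamformerWeights, Ca: Covariance, Cc: Covariance) -> float:
    """Active/control variance contrast ``(w'Ca w - w'Cc w)/(2 w'Cc w)``."""
    wa = float(w.w @ Ca.C @ w.w)
    wc = float(w.w @ Cc.C @ w.w)
    if wc == 0.0:
        raise ZeroDivisionError("control-window projected power is zero")
    return (wa - wc) / (2.0 * wc)


# ---------------------------------------------------------------------------
# Whole-volume pseudo-T imaging
# ---------------------------------------------------------------------------

@dataclass
class PseudoTImage:
    """Pseudo-T values on a regular source lattice inside the head sphere."""

    points: np.ndarray  # (P, 3), helmet frame
    values: np.ndarray  # (P,)
    orientations: np.ndarray  # (P, 3) optimal source orientation
    grid_pitch: float
    threshold_fraction: float

    @property
    def peak_index(self) -> int:
        return int(np.argmax(np.abs(self.values)))

    @property
    def peak(self) -> np.ndarray:
        return self.points[self.peak_index]

    @property
    def peak_value(self) -> float:
        return float(self.values[self.peak_index])

    @property
    def peak_orientation(self) -> np.ndarray:
        return self.orientations[self.peak_index]

    def thresholded(self) -> np.ndarray:
        """Values with |T| below threshold_fraction * max|T| set to NaN."""
        cut = self.threshold_fraction * np.abs(self.values).max()
        out = self.values.copy()
        out[np.abs(self.values) < cut] = np.nan
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "T_value": self.values,
            }
        ).to_csv(path, index=False)

    def to_nifti(self, path) -> None:
        """Optional NIfTI export of the lattice volume (requires nibabel)."""
        import nibabel as nib

        pitch = self.grid_pitch
        mins = self.points.min(axis=0)
        idx = np.round((self.points - mins) / pitch).astype(int)
        shape = idx.max(axis=0) + 1
        vol = np.full(shape, np.nan)
        vol[tuple(idx.T)] = self.values
        affine = np.diag([pitch, pitch, pitch, 1.0])
        affine[:3, 3] = mins
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)


def source_grid(model: SphereModel, pitch: float = 0.004, inner_exclusion: float = 0.01) -> np.ndarray:
    """Lattice points inside the head sphere at the given pitch.

    Points within ``inner_exclusion`` of the centre are excluded: there
    every dipole orientation is radial, hence externally silent, and the
    beamformer contrast is undefined.
    """
    R = model.radius - pitch / 2.0
    n = int(np.floor(R / pitch))
    ax = np.arange(-n, n + 1) * pitch
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.linalg.norm(pts, axis=1)
    pts = pts[(r <= R) & (r >= inner_exclusion)]
    centre = model.centre if model.centre.ndim == 1 else model.centre.mean(axis=0)
    return pts + centre


def _tangential_basis(points: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """Orthonormal tangential basis (P, 2, 3) at each source point."""
    radial = points - centre
    radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (points.shape[0], 1))
    near_pole = np.abs(radial[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    e1 = np.cross(radial, ref)
    e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(radial, e1)
    return np.stack([e1, e2], axis=1)


def _extreme_rayleigh_2x2(A2: np.ndarray, C2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised extreme generalized Rayleigh quotient of 2x2 pencils.

    For each of P symmetric pairs (A2, C2) with C2 positive definite,
    returns (lambda, u): the eigenvalue of largest magnitude of
    ``C2^-1 A2`` and its unit eigenvector.
    """
    # Cholesky of C2: [[a,0],[b,c]]
    a = np.sqrt(C2[:, 0, 0])
    b = C2[:, 1, 0] / a
    c = np.sqrt(np.maximum(C2[:, 1, 1] - b**2, 1e-300))
    # S = Linv A2 Linv^T, symmetric 2x2
    # Linv = [[1/a, 0], [-b/(a c), 1/c]]
    ia = 1.0 / a
    ic = 1.0 / c
    ib = -b * ia * ic
    s00 = ia * ia * A2[:, 0, 0]
    s01 = ia * (ib * A2[:, 0, 0] + ic * A2[:, 0, 1])
    s11 = (
        ib * ib * A2[:, 0, 0]
        + 2.0 * ib * ic * A2[:, 0, 1]
        + ic * ic * A2[:, 1, 1]
    )
    tr = s00 + s11
    det = s00 * s11 - s01**2
    disc = np.sqrt(np.maximum(tr**2 / 4.0 - det, 0.0))
    lam1 = tr / 2.0 + disc
    lam2 = tr / 2.0 - disc
    lam = np.where(np.abs(lam1) >= np.abs(lam2), lam1, lam2)
    # eigenvector of symmetric [[s00, s01], [s01, s11]] for eigenvalue lam
    v0 = np.where(np.abs(s01) > 1e-300, s01, lam - s11)
    v1 = np.where(np.abs(s01) > 1e-300, lam - s00, np.zeros_like(lam))
    degen = (np.abs(v0) < 1e-300) & (np.abs(v1) < 1e-300)
    v0 = np.where(degen, 1.0, v0)
    # map back: u = Linv^T v
    u0 = ia * v0 + ib * v1
    u1 = ic * v1
    norm = np.sqrt(u0**2 + u1**2)
    return lam, np.stack([u0 / norm, u1 / norm], axis=1)


def scan_image(
    rec: Recording,
    sensors: SensorArray,
    model: SphereModel,
    active_windows: Sequence,
    control_windows: Sequence,
    band=(13.0, 30.0),
    grid_pitch: float = 0.004,
    threshold_fraction: float = 0.8,
    mu_fraction: float = 0.01,
    orientation: str = "optimal",
    fixed_orientation=None,
) -> PseudoTImage:
    """Pseudo-T contrast image over the head volume for one helmet.

    Weights are computed from the whole-recording band-limited
    covariance (Tikhonov-regularised); active/control covariances from
    the stated window lists (seconds, absolute).  At each lattice point
    the tangential source orientation extremising |pseudo-T| is found in
    closed form from the 2x2 generalized eigenproblem of the tangential
    lead-field pair (``orientation='optimal'``); a fixed orientation may
    be supplied instead (``orientation='fixed'``).
    """
    for aw in active_windows:
        for cw in control_windows:
            if max(aw[0], cw[0]) < min(aw[1], cw[1]):
                raise ValueError("active and control windows overlap")
    sub = rec.pick(rec.channels_for_helmet(sensors.helmet_id)) if (
        rec.n_channels != sensors.n_sensors
    ) else rec
    C = compute_covariance(sub, band).regularized(mu_fraction)
    Ca = compute_covariance(sub, band, active_windows)
    Cc = compute_covariance(sub, band, control_windows)

    centre = model.centre if model.centre.ndim == 1 else model.centre.mean(axis=0)
    pts = source_grid(model, grid_pitch)
    basis = _tangential_basis(pts, centre)  # (P, 2, 3)
    L3 = lead_field_grid(pts, sensors, model)  # (P, 3, N)
    Lt = np.einsum("pki,pin->pkn", basis, L3)  # (P, 2, N)

    Ci = np.linalg.inv(C.C_reg)
    Ma = Ci @ Ca.C @ Ci
    Mc = Ci @ Cc.C @ Ci
    if orientation == "optimal":
        A2 = np.einsum("pkn,nm,plm->pkl", Lt, Ma - Mc, Lt)
        C2 = np.einsum("pkn,nm,plm->pkl", Lt, Mc, Lt)
        lam, u = _extreme_rayleigh_2x2(A2, C2)
        values = lam / 2.0
        oris = np.einsum("pk,pki->pi", u, basis)
    elif orientation == "fixed":
        if fixed_orientation is None:
            raise ValueError("fixed orientation requires fixed_orientation")
        f = np.asarray(fixed_orientation, float)
        f = f / np.linalg.norm(f)
        L = np.einsum("pin,i->pn", L3, f)
        num = np.einsum("pn,nm,pm->p", L, Ma - Mc, L)
        den = np.einsum("pn,nm,pm->p", L, Mc, L)
        values = num / (2.0 * den)
        oris = np.tile(f, (pts.shape[0], 1))
    else:
        raise ValueError("orientation must be 'optimal' or 'fixed'")
    return PseudoTImage(pts, values, oris, grid_pitch, threshold_fraction)


@dataclass
class VirtualElectrode:
    """Beamformer-reconstructed source timecourse at one location."""

    timecourse: np.ndarray  # A*m
    theta: tuple  # (position, orientation)
    band: tuple
    sample_rate: float
    events: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.timecourse.size) / self.sample_rate


def virtual_electrode(
    rec: Recording,
    sensors: SensorArray,
    model: SphereModel,
    position,
    orientation,
    band=(1.0, 150.0),
    mu_fraction: float = 0.01,
) -> VirtualElectrode:
    """Reconstruct ``Q(t) = w^T m(t)`` with broadband-covariance weights."""
    sub = rec.pick(rec.channels_for_helmet(sensors.helmet_id)) if (
        rec.n_channels != sensors.n_sensors
    ) else rec
    C = compute_covariance(sub, band).regularized(mu_fraction)
    L = lead_field(position, orientation, sensors, model)
    w = beamformer_weights(L, C)
    filtered = bandpass(sub.data, band, sub.sample_rate)
    return VirtualElectrode(
        w.apply(filtered),
        (np.asarray(position, float), np.asarray(orientation, float)),
        tuple(band),
        sub.sample_rate,
        sub.events,
    )
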