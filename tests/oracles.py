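"""Independent brute-force oracles used to validate the closed-form code.

Each oracle deliberately takes a different computational route from the
implementation it checks: numerical line integration for the analytic
segment field, a boundary-element volume-current integral for the
conducting-sphere dipole field, a numerical optimiser for the Tikhonov
current solver, and explicit O(T^2) loops for the lag correlations.
"""

from __future__ import annotations

import numpy as np

MU0 = 4e-7 * np.pi


def biot_savart_quadrature(p1, p2, r, current, n=100_000):
    """Trapezoid-rule line integral of the Biot-Savart law along a segment."""
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    r = np.asarray(r, float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p1 + t * (p2 - p1)
    dl = (p2 - p1) / (n - 1)
    sep = r - pts
    d3 = np.linalg.norm(sep, axis=1) ** 3
    integrand = np.cross(np.tile(dl, (n, 1)), sep) / d3[:, None]
    # trapezoid weights
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return MU0 * current / (4 * np.pi) * (integrand * w[:, None]).sum(axis=0)


def free_space_dipole_field(q, r0, r):
    """Magnetic field of a current dipole in an unbounded medium."""
    sep = np.atleast_2d(r) - np.asarray(r0, float)
    d3 = np.linalg.norm(sep, axis=1) ** 3
    B = MU0 / (4 * np.pi) * np.cross(np.asarray(q, float), sep) / d3[:, None]
    return B[0] if np.asarray(r).ndim == 1 else B


def _triangle_solid_angles(verts, faces, obs):
    """Signed solid angle of every triangle seen from ``obs`` (van Oosterom)."""
    R = verts[faces] - obs  # (F, 3, 3)
    r = np.linalg.norm(R, axis=2)  # (F, 3)
    R1, R2, R3 = R[:, 0], R[:, 1], R[:, 2]
    num = np.einsum("ij,ij->i", R1, np.cross(R2, R3))
    den = (
        r[:, 0] * r[:, 1] * r[:, 2]
        + np.einsum("ij,ij->i", R1, R2) * r[:, 2]
        + np.einsum("ij,ij->i", R1, R3) * r[:, 1]
        + np.einsum("ij,ij->i", R2, R3) * r[:, 0]
    )
    with np.errstate(invalid="ignore"):
        omega = 2.0 * np.arctan2(num, den)
    return np.nan_to_num(omega)


def bem_sphere_dipole_field(dipole_pos, dipole_moment, centre, radius, r_obs,
                            subdivisions=4):
    """Dipole-in-conducting-sphere field via a boundary-element computation.

    Solves the surface-potential integral equation on a triangulated
    sphere by vertex collocation (deflated, since the interior Neumann
    potential is defined up to a constant), then adds the volume-current
    contribution to the primary free-space dipole field via the surface
    integral  B_v = -(mu0/4pi) * sum_j sigma V_j A_j n_j x (r-c_j)/|r-c_j|^3.
    Conductivity cancels and is set to 1.
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    verts = np.asarray(mesh.vertices) + np.asarray(centre, float)
    faces = np.asarray(mesh.faces)
    areas = np.asarray(mesh.area_faces)
    normals = np.asarray(mesh.face_normals)
    centroids = verts[faces].mean(axis=1)
    N = verts.shape[0]

    q = np.asarray(dipole_moment, float)
    r0 = np.asarray(dipole_pos, float)

    def v_inf(points):
        sep = points - r0
        return np.einsum("j,ij->i", q, sep) / (
            4 * np.pi * np.linalg.norm(sep, axis=1) ** 3
        )

    # collocation matrix of per-face solid angles, accumulated onto vertices
    K = np.zeros((N, N))
    for i in range(N):
        omega = _triangle_solid_angles(verts, faces, verts[i])
        # spread each face's solid angle evenly over its three vertices
        np.add.at(K[i], faces.ravel(), np.repeat(omega / 3.0, 3))
    # interior check: from inside, the closed surface subtends 4 pi
    inside = _triangle_solid_angles(verts, faces, np.asarray(centre, float)).sum()
    sign = 1.0 if inside > 0 else -1.0
    K *= sign

    # auto-solid-angle diagonal: at a polyhedral vertex the interior solid
    # angle is the row sum of K, not exactly 2 pi; using it makes constants
    # an exact nullspace, which deflation then removes
    A = (np.diag(K.sum(axis=1)) - K) / (2 * np.pi) + np.ones((N, N)) / N
    V = np.linalg.solve(A, 2.0 * v_inf(verts))

    V_face = V[faces].mean(axis=1)
    obs = np.atleast_2d(r_obs)
    out = np.empty((obs.shape[0], 3))
    for k, r in enumerate(obs):
        sep = r - centroids
        d3 = np.linalg.norm(sep, axis=1) ** 3
        Bv = -(MU0 / (4 * np.pi)) * (
            (V_face * areas)[:, None] * np.cross(normals, sep / d3[:, None])
        ).sum(axis=0)
        out[k] = free_space_dipole_field(q, r0, r) + Bv
    return out[0] if np.asarray(r_obs).ndim == 1 else out


def tikhonov_currents_optimizer(A, b, alpha, tol=1e-14):
    """Numerical minimiser of ||A x + b||^2 + alpha ||x||^2."""
    from scipy.optimize import minimize

    A = np.asarray(A, float)
    b = np.asarray(b, float)

    def fun(x):
        r = A @ x + b
        return float(r @ r + alpha * x @ x)

    def jac(x):
        return 2.0 * A.T @ (A @ x + b) + 2.0 * alpha * x

    res = minimize(
        fun, np.zeros(A.shape[1]), jac=jac, method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": tol, "gtol": 1e-16},
    )
    return res.x


def xcorr_bruteforce(e1, e2, max_shift):
    """Double-loop unbiased normalised cross-correlation (reference)."""
    e1 = np.asarray(e1, float)
    e2 = np.asarray(e2, float)
    T = e1.size
    x = e1 - e1.mean()
    y = e2 - e2.mean()
    s1 = np.sqrt((x**2).sum() / T)
    s2 = np.sqrt((y**2).sum() / T)
    out = np.empty(2 * max_shift + 1)
    for j, k in enumerate(range(-max_shift, max_shift + 1)):
        acc = 0.0
        n = 0
        for t in range(T):
            if 0 <= t + k < T:
                acc += x[t] * y[t + k]
                n += 1
        out[j] = acc / (n * s1 * s2)
    return out
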