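"""Conducting-sphere forward model and OPM sensing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hyperscan.forward import (
    GeometryError,
    OPMMode,
    OPMSensor,
    Pose,
    Recording,
    SensorArray,
    SphereModel,
    default_second_axis,
    dipole_field_sphere,
    lead_field,
    lead_field_grid,
    sense,
)
from hyperscan.synthscenario import build_helmet

from .oracles import bem_sphere_dipole_field, free_space_dipole_field

CENTRE = np.zeros(3)


class TestSarvasField:
    def test_radial_dipole_is_silent(self, rng):
        for _ in range(5):
            r0 = rng.uniform(-0.04, 0.04, 3)
            q = r0 / np.linalg.norm(r0)  # radial orientation
            r = rng.uniform(0.1, 0.2, 3)
            B = dipole_field_sphere(r0, q, CENTRE, r)
            assert np.allclose(B, 0.0, atol=1e-18)

    def test_radial_component_equals_free_space_term(self, rng):
        # volume currents contribute no radial field in the sphere model
        r0 = np.array([0.01, 0.03, 0.02])
        q = np.array([0.0, -0.02, 0.03])  # A*m, arbitrary orientation
        for _ in range(5):
            r = rng.normal(size=3)
            r = 0.12 * r / np.linalg.norm(r)
            B = dipole_field_sphere(r0, q, CENTRE, r)
            Binf = free_space_dipole_field(q, r0, r)
            rhat = r / np.linalg.norm(r)
            assert B @ rhat == pytest.approx(Binf @ rhat, rel=1e-10, abs=1e-25)

    def test_matches_bem_oracle(self):
        r0 = np.array([0.02, 0.035, 0.01])
        q = np.array([3e-9, -1e-9, 2e-9])
        q -= (q @ r0) / (r0 @ r0) * r0  # tangential dipole
        obs = np.array([[0.11, 0.02, 0.03], [0.0, 0.13, -0.04], [-0.08, 0.07, 0.09]])
        B = dipole_field_sphere(r0, q, CENTRE, obs)
        Bb = bem_sphere_dipole_field(r0, q, CENTRE, 0.09, obs)
        scale = np.linalg.norm(B, axis=1)
        assert np.all(np.linalg.norm(B - Bb, axis=1) < 0.01 * scale)

    def test_far_field_decay_at_least_inverse_square(self):
        r0 = np.array([0.0, 0.04, 0.0])
        q = np.array([1e-8, 0.0, 0.0])
        d1, d2 = 0.2, 0.4
        B1 = np.linalg.norm(dipole_field_sphere(r0, q, CENTRE, [0, 0, d1]))
        B2 = np.linalg.norm(dipole_field_sphere(r0, q, CENTRE, [0, 0, d2]))
        assert B2 < B1 * (d1 / d2) ** 2 * 1.001

    def test_divergence_free(self, rng):
        r0 = np.array([0.01, 0.03, -0.02])
        q = np.array([0.0, 2e-9, 3e-9])
        h = 1e-5
        for _ in range(3):
            r = rng.normal(size=3)
            r = 0.13 * r / np.linalg.norm(r)
            div = 0.0
            for k in range(3):
                e = np.zeros(3)
                e[k] = h
                div += (
                    dipole_field_sphere(r0, q, CENTRE, r + e)[k]
                    - dipole_field_sphere(r0, q, CENTRE, r - e)[k]
                ) / (2 * h)
            Bmag = np.linalg.norm(dipole_field_sphere(r0, q, CENTRE, r))
            assert abs(div) < 1e-6 * Bmag / h

    def test_centre_evaluation_raises(self):
        with pytest.raises(GeometryError):
            dipole_field_sphere([0.01, 0.02, 0.0], [0, 0, 1e-8], CENTRE, CENTRE)


@pytest.fixture(scope="module")
def helmet():
    return build_helmet(CENTRE, "H")


@pytest.fixture(scope="module")
def model():
    return SphereModel(CENTRE, 0.09)


class TestLeadField:
    def test_linearity_in_moment(self, helmet, model):
        pos = np.array([-0.02, 0.045, 0.02])
        ori = np.array([0.0, 0.0, 1.0])
        L = lead_field(pos, ori, helmet, model)
        # doubling the dipole moment doubles the predicted data
        B2 = np.array(
            [
                dipole_field_sphere(pos, 2 * ori, model.centre, s.position)
                @ s.orientation
                for s in helmet.sensors
            ]
        )
        assert np.allclose(B2, 2 * L, rtol=1e-12)

    def test_radial_source_silent_on_radial_channels(self, helmet, model):
        pos = np.array([0.0, 0.05, 0.0])
        L = lead_field(pos, pos / np.linalg.norm(pos), helmet, model)
        assert np.all(np.abs(L) < 1e-20)

    def test_agrees_with_direct_field_evaluation(self, helmet, model, rng):
        pos = rng.uniform(-0.03, 0.03, 3) + [0, 0.02, 0]
        ori = np.cross(pos, [0, 0, 1.0])
        ori /= np.linalg.norm(ori)
        L = lead_field(pos, ori, helmet, model)
        direct = np.array(
            [
                dipole_field_sphere(pos, ori, model.centre, s.position) @ s.orientation
                for s in helmet.sensors
            ]
        )
        assert np.allclose(L, direct, rtol=1e-12)

    def test_grid_variant_matches_pointwise(self, helmet, model):
        pts = np.array([[0.0, 0.05, 0.01], [-0.02, 0.04, 0.02]])
        G = lead_field_grid(pts, helmet, model)
        for p in range(2):
            for k, e in enumerate(np.eye(3)):
                assert np.allclose(
                    G[p, k], lead_field(pts[p], e, helmet, model), rtol=1e-12
                )

    def test_per_channel_sphere_centres(self, helmet):
        centres = np.tile(np.array([0.0, 0.01, 0.0]), (helmet.n_sensors, 1))
        multi = SphereModel(centres, 0.09)
        shared = SphereModel(np.array([0.0, 0.01, 0.0]), 0.09)
        pos = np.array([-0.02, 0.05, 0.01])
        ori = np.array([1.0, 0, 0])
        assert np.allclose(
            lead_field(pos, ori, helmet, multi), lead_field(pos, ori, helmet, shared)
        )


class TestPoseAndSensing:
    def test_rigid_motion_preserves_distances(self):
        helmet = build_helmet(CENTRE, "H")
        rot = Rotation.from_euler("xyz", [[0, 0, 0], [10, 5, -8]], degrees=True)
        pose = Pose(np.array([0.0, 1.0]), rot, np.array([[0, 0, 0], [0.02, -0.01, 0.015]]))
        R, T = pose.at(0.37)
        moved = R[0].apply(helmet.positions) + T[0]
        d0 = np.linalg.norm(helmet.positions[:, None] - helmet.positions[None], axis=2)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=2)
        assert np.max(np.abs(d0 - d1)) < 1e-12

    def test_zero_field_zero_noise_reads_zero(self):
        helmet = build_helmet(CENTRE, "H", n_sensors=4)
        out, sat = sense(helmet, OPMMode.measurement(), lambda p, t: np.zeros((len(p), 3)), 0.0)
        assert np.all(out == 0.0) and not sat.any()

    def test_saturation_clips_and_flags(self):
        helmet = build_helmet(CENTRE, "H", n_sensors=1, n_nulling=1, cap_angle_deg=1e-6)
        # sensor ~ at the +y pole, radial axis ~ +y
        field = lambda p, t: np.tile([0.0, 6e-9, 0.0], (len(p), 1))
        out, sat = sense(helmet, OPMMode.measurement(), field, 0.0)
        assert out[0, 0] == pytest.approx(5e-9, rel=1e-6)
        assert sat[0, 0]

    def test_gradient_field_projection(self):
        helmet = build_helmet(CENTRE, "H", n_sensors=1, n_nulling=1, cap_angle_deg=1e-6)
        s = helmet.sensors[0]
        G = 2e-9 * np.eye(3) - 2e-9 * np.eye(3).mean() * 0  # diag gradient
        G = np.diag([2e-9, -1e-9, -1e-9])
        field = lambda p, t: p @ G.T
        out, _ = sense(helmet, OPMMode.measurement(), field, 0.0)
        expected = (G @ s.position) @ s.orientation
        assert out[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_linear_below_saturation(self):
        helmet = build_helmet(CENTRE, "H", n_sensors=4)
        f1 = lambda p, t: np.tile([0.5e-9, 0.2e-9, -0.4e-9], (len(p), 1))
        f3 = lambda p, t: 3 * f1(p, t)
        o1, _ = sense(helmet, OPMMode.measurement(), f1, 0.0)
        o3, _ = sense(helmet, OPMMode.measurement(), f3, 0.0)
        assert np.allclose(o3, 3 * o1, rtol=1e-12)

    def test_field_zeroing_mode_reads_two_axes(self):
        helmet = build_helmet(CENTRE, "H", n_sensors=3)
        field = lambda p, t: np.tile([1e-9, 2e-9, 0.5e-9], (len(p), 1))
        out, _ = sense(helmet, OPMMode.field_zeroing(), field, 0.0)
        assert out.shape == (6, 1)
        b = np.array([1e-9, 2e-9, 0.5e-9])
        for i, s in enumerate(helmet.sensors):
            assert out[2 * i, 0] == pytest.approx(b @ s.orientation, rel=1e-12)
            assert out[2 * i + 1, 0] == pytest.approx(b @ s.second_axis, rel=1e-12)

    def test_second_axis_is_orthogonal_projection_of_x(self):
        u = np.array([0.0, 1.0, 0.0])
        v = default_second_axis(u)
        assert np.allclose(v, [1.0, 0, 0])
        u2 = np.array([1.0, 0.0, 0.0])
        assert abs(default_second_axis(u2) @ u2) < 1e-12


class TestRecordingContainer:
    def test_channel_table_mismatch_raises(self):
        import pandas as pd

        with pytest.raises(ValueError):
            Recording(
                np.zeros((3, 10)),
                1200.0,
                pd.DataFrame({"name": ["a"], "helmet": ["H"], "sensor_index": [0]}),
                pd.DataFrame({"time": [], "code": []}),
            )

    def test_event_time_outside_duration_raises(self):
        import pandas as pd

        ch = pd.DataFrame(
            {"name": ["a"], "helmet": ["H"], "sensor_index": [0]}
        )
        with pytest.raises(ValueError):
            Recording(
                np.zeros((1, 10)),
                10.0,
                ch,
                pd.DataFrame({"time": [5.0], "code": ["x"]}),
            )
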