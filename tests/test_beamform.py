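"""LCMV beamformer: covariance, weights, pseudo-T imaging, virtual electrodes."""

import numpy as np
import pandas as pd
import pytest

from hyperscan.beamform import (
    Covariance,
    bandpass,
    beamformer_weights,
    compute_covariance,
    pseudo_t,
    scan_image,
    source_grid,
    virtual_electrode,
)
from hyperscan.forward import Recording, SphereModel, lead_field
from hyperscan.synthscenario import _band_noise, build_helmet

FS = 1200.0
CENTRE = np.zeros(3)


def make_recording(data, events=None):
    n = data.shape[0]
    table = pd.DataFrame(
        {"name": ["H_s%02d" % i for i in range(n)], "helmet": "H",
         "sensor_index": np.arange(n)}
    )
    ev = events if events is not None else pd.DataFrame({"time": [], "code": []})
    return Recording(data, FS, table, ev)


@pytest.fixture(scope="module")
def helmet():
    return build_helmet(CENTRE, "H")


@pytest.fixture(scope="module")
def model():
    return SphereModel(CENTRE, 0.09)


def simulate_dipole_recording(helmet, model, seed, position=None, orientation=None,
                              duration=24.0, amplitude=30e-9, noise=15e-15,
                              on_off=True):
    """Single-dipole session: source on for the first half, off for the second."""
    rng = np.random.default_rng(seed)
    S = int(duration * FS)
    carrier = _band_noise(rng, (13.0, 30.0), FS, S)
    gate = np.ones(S)
    if on_off:
        gate[S // 2 :] = 0.0
    if position is None:
        position = np.array([-0.02, 0.045, 0.02])
    if orientation is None:
        orientation = np.array([0.0, 0.0, 1.0])
        orientation -= (orientation @ position) / (position @ position) * position
        orientation /= np.linalg.norm(orientation)
    L = lead_field(position, orientation, helmet, model)
    data = np.outer(L, amplitude * gate * carrier)
    data += rng.normal(0.0, noise * np.sqrt(FS / 2), data.shape)
    return make_recording(data), position, orientation


class TestCovariance:
    def test_white_noise_approaches_scaled_identity(self, rng):
        n_ch, S = 4, 400_000
        data = rng.normal(size=(n_ch, S))
        rec = make_recording(data)
        cov = compute_covariance(rec, (13.0, 30.0))
        # band-filtered white noise: variance ~ sigma^2 * band/Nyquist
        # (the zero-phase filter's equivalent noise bandwidth is ~0.9x
        # the nominal band, from the squared Butterworth response)
        expected = (30.0 - 13.0) / (FS / 2)
        d = np.diag(cov.C)
        assert np.allclose(d, expected, rtol=0.15)
        off = cov.C - np.diag(d)
        assert np.abs(off).max() < 0.05 * expected

    def test_duplicated_channel_rank_deficient(self, rng):
        x = rng.normal(size=(1, 24_000))
        rec = make_recording(np.vstack([x, x, rng.normal(size=(1, 24_000))]))
        cov = compute_covariance(rec, (13.0, 30.0))
        assert np.linalg.matrix_rank(cov.C, tol=1e-12 * np.abs(cov.C).max()) == 2
        assert np.allclose(cov.C[0], cov.C[1])

    def test_single_dipole_noise_free_is_rank_one(self, helmet, model):
        rec, pos, ori = simulate_dipole_recording(
            helmet, model, seed=0, noise=0.0, on_off=False, duration=6.0
        )
        cov = compute_covariance(rec, (13.0, 30.0))
        s = np.linalg.svd(cov.C, compute_uv=False)
        assert s[1] < 1e-10 * s[0]
        L = lead_field(pos, ori, helmet, model)
        outer = np.outer(L, L)
        assert np.allclose(cov.C / np.trace(cov.C), outer / np.trace(outer), atol=1e-10)

    def test_short_window_warns(self, rng):
        rec = make_recording(rng.normal(size=(2, 2400)))
        with pytest.warns(UserWarning, match="time-constants"):
            compute_covariance(rec, (13.0, 30.0), [(0.0, 0.1)])

    def test_empty_window_raises(self, rng):
        rec = make_recording(rng.normal(size=(2, 2400)))
        with pytest.raises(ValueError):
            compute_covariance(rec, (13.0, 30.0), [(1.0, 1.0)])

    def test_band_above_nyquist_raises(self, rng):
        rec = make_recording(rng.normal(size=(2, 2400)))
        with pytest.raises(ValueError, match="Nyquist"):
            compute_covariance(rec, (13.0, 700.0))


class TestWeights:
    def test_unit_gain_random_geometries(self, helmet, model, rng):
        C = Covariance(np.eye(helmet.n_sensors) * 1e-26, (13, 30), ((0, 1),), 0.0)
        for _ in range(50):
            pos = rng.normal(size=3)
            pos = rng.uniform(0.02, 0.07) * pos / np.linalg.norm(pos)
            ori = np.cross(pos, rng.normal(size=3))
            ori /= np.linalg.norm(ori)
            L = lead_field(pos, ori, helmet, model)
            w = beamformer_weights(L, C)
            assert abs(w.w @ L - 1.0) < 1e-10

    def test_identity_covariance_gives_matched_filter(self, rng):
        L = rng.normal(size=8)
        C = Covariance(np.eye(8), (1, 2), ((0, 1),), 0.0)
        w = beamformer_weights(L, C)
        assert np.allclose(w.w, L / (L @ L), rtol=1e-12)

    def test_minimum_variance_among_unit_gain_probes(self, rng):
        n = 8
        M = rng.normal(size=(n, 2 * n))
        C = Covariance(M @ M.T / (2 * n), (1, 2), ((0, 1),), 0.0)
        L = rng.normal(size=n)
        w = beamformer_weights(L, C)
        var_opt = w.w @ C.C @ w.w
        for _ in range(10_000):
            v = rng.normal(size=n)
            v = v / (v @ L)  # unit gain
            assert v @ C.C @ v >= var_opt - 1e-12

    def test_zero_lead_field_raises(self):
        C = Covariance(np.eye(4), (1, 2), ((0, 1),), 0.0)
        with pytest.raises(ValueError, match="silent"):
            beamformer_weights(np.zeros(4), C)


class TestPseudoT:
    def test_equal_covariances_give_zero(self, rng):
        M = rng.normal(size=(5, 10))
        C = Covariance(M @ M.T, (13, 30), ((0, 1),), 0.0)
        w = beamformer_weights(rng.normal(size=5), C)
        assert pseudo_t(w, C, C) == pytest.approx(0.0, abs=1e-14)

    def test_three_to_one_ratio_gives_unity(self, rng):
        M = rng.normal(size=(5, 10))
        Cc = Covariance(M @ M.T, (13, 30), ((0, 1),), 0.0)
        Ca = Covariance(3 * Cc.C, (13, 30), ((1, 2),), 0.0)
        w = beamformer_weights(rng.normal(size=5), Cc)
        assert pseudo_t(w, Ca, Cc) == pytest.approx(1.0, rel=1e-12)

    def test_zero_control_power_raises(self):
        Ca = Covariance(np.eye(3), (13, 30), ((0, 1),), 0.0)
        Cc = Covariance(np.zeros((3, 3)), (13, 30), ((1, 2),), 0.0)
        w = beamformer_weights(np.ones(3), Ca)
        with pytest.raises(ZeroDivisionError):
            pseudo_t(w, Ca, Cc)

    def test_invariant_to_global_rescaling(self, rng):
        M = rng.normal(size=(5, 20))
        Cc = Covariance(M @ M.T, (13, 30), ((0, 1),), 0.0)
        Ma = rng.normal(size=(5, 20))
        Ca = Covariance(Ma @ Ma.T, (13, 30), ((1, 2),), 0.0)
        w = beamformer_weights(rng.normal(size=5), Cc)
        t1 = pseudo_t(w, Ca, Cc)
        t2 = pseudo_t(
            w,
            Covariance(4 * Ca.C, Ca.band, Ca.window, 0.0),
            Covariance(4 * Cc.C, Cc.band, Cc.window, 0.0),
        )
        assert t1 == pytest.approx(t2, rel=1e-12)


class TestScanImage:
    def test_source_grid_properties(self, model):
        pts = source_grid(model, 0.004)
        r = np.linalg.norm(pts - model.centre, axis=1)
        assert np.all(r <= model.radius)
        assert np.all(r >= 0.01)
        # regular pitch
        ax = np.unique(np.round(pts[:, 0], 9))
        assert np.allclose(np.diff(ax), 0.004)

    def test_localizes_simulated_dipole(self, helmet, model):
        rec, pos, ori = simulate_dipole_recording(helmet, model, seed=3)
        img = scan_image(
            rec, helmet, model,
            active_windows=[(0.0, 12.0)], control_windows=[(12.0, 24.0)],
        )
        err = np.linalg.norm(img.peak - pos)
        assert err <= 0.008  # within two grid steps
        assert img.peak_value > 0  # source on in the active window

    def test_threshold_one_keeps_only_peak(self, helmet, model):
        rec, *_ = simulate_dipole_recording(helmet, model, seed=4, duration=12.0)
        img = scan_image(
            rec, helmet, model,
            active_windows=[(0.0, 6.0)], control_windows=[(6.0, 12.0)],
            threshold_fraction=1.0, grid_pitch=0.008,
        )
        vals = img.thresholded()
        assert np.isfinite(vals).sum() == 1

    def test_overlapping_windows_raise(self, helmet, model, rng):
        rec = make_recording(rng.normal(size=(helmet.n_sensors, 24_000)))
        with pytest.raises(ValueError, match="overlap"):
            scan_image(rec, helmet, model, [(0.0, 5.0)], [(4.0, 9.0)])

    def test_fixed_orientation_mode(self, helmet, model):
        rec, pos, ori = simulate_dipole_recording(helmet, model, seed=5, duration=12.0)
        img = scan_image(
            rec, helmet, model, [(0.0, 6.0)], [(6.0, 12.0)],
            orientation="fixed", fixed_orientation=ori, grid_pitch=0.008,
        )
        assert np.linalg.norm(img.peak - pos) <= 0.012


class TestVirtualElectrode:
    def test_unit_gain_recovers_source_timecourse(self, helmet, model):
        rec, pos, ori = simulate_dipole_recording(
            helmet, model, seed=6, noise=0.0, on_off=False, duration=6.0
        )
        ve = virtual_electrode(rec, helmet, model, pos, ori, band=(2.0, 90.0))
        # noise-free single source: reconstruction equals the generating
        # moment timecourse up to the bandpass applied to both
        src = bandpass(rec.data, (2.0, 90.0), FS)
        L = lead_field(pos, ori, helmet, model)
        truth = src[np.argmax(np.abs(L))] / L[np.argmax(np.abs(L))]
        mid = slice(int(FS), int(5 * FS))
        assert np.corrcoef(ve.timecourse[mid], truth[mid])[0, 1] > 0.999999

    def test_scaling_data_scales_reconstruction(self, helmet, model):
        rec, pos, ori = simulate_dipole_recording(helmet, model, seed=7, duration=6.0)
        ve1 = virtual_electrode(rec, helmet, model, pos, ori, band=(2.0, 90.0))
        rec2 = make_recording(2 * rec.data, rec.events)
        ve2 = virtual_electrode(rec2, helmet, model, pos, ori, band=(2.0, 90.0))
        assert np.allclose(ve2.timecourse, 2 * ve1.timecourse, rtol=1e-10)
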