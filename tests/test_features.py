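"""Feature primitives and per-task extraction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneestab.errors import (DegenerateEllipseError, EmptyInputError,
                             InsufficientHopsError)
from kneestab.features import (extract_cht_features, extract_cmj_features,
                               extract_sls_features, peak_norm,
                               prediction_ellipse, rms_norm, sway_path)
from kneestab.segmentation import segment_cht, segment_cmj, segment_sls
from kneestab.types import G, GrfRecording, ImuRecording, TaskEvents

FS = 500.0


class TestRmsPeak:
    def test_constant_vector(self):
        sig = np.tile([3.0, 0.0, 4.0], (20, 1))     # norm 5
        assert rms_norm(sig) == pytest.approx(5.0)
        assert peak_norm(sig) == pytest.approx(5.0)

    def test_zeros(self):
        assert rms_norm(np.zeros((10, 3))) == 0.0

    def test_three_four_hand_value(self):
        sig = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        assert rms_norm(sig) == pytest.approx(np.sqrt(12.5))
        assert rms_norm(sig) == pytest.approx(3.5355, abs=1e-4)

    def test_impulse_peak(self):
        sig = np.zeros((50, 3))
        sig[17] = [0, 10.0, 0]
        assert peak_norm(sig) == 10.0

    def test_empty_window_raises(self):
        with pytest.raises(EmptyInputError):
            rms_norm(np.zeros((10, 3)), slice(5, 5))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rms_never_exceeds_peak(self, seed):
        sig = np.random.default_rng(seed).normal(size=(40, 3))
        assert rms_norm(sig) <= peak_norm(sig) + 1e-12


class TestSwayPath:
    def test_repeated_point(self):
        assert sway_path(np.tile([1.0, 2.0], (10, 1))) == 0.0

    def test_three_four_five(self):
        assert sway_path([[0, 0], [3, 4]]) == pytest.approx(5.0)

    def test_unit_square_perimeter(self):
        square = [[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]
        assert sway_path(square) == pytest.approx(4.0)

    def test_single_point_raises(self):
        with pytest.raises(EmptyInputError):
            sway_path([[0.0, 0.0]])


class TestPredictionEllipse:
    @staticmethod
    def _anisotropic_cloud(sa=2.0, sb=1.0, n=720, phase=0.0):
        """Deterministic cloud with exact 2:1 axis ratio (orthogonal
        sinusoids over full periods have exactly diagonal covariance)."""
        k = np.arange(n)
        x = sa * np.sqrt(2) * np.cos(2 * np.pi * k / n + phase)
        y = sb * np.sqrt(2) * np.sin(2 * np.pi * k / n + phase)
        return np.column_stack([x, y])

    def test_constructed_two_one_axes(self):
        ell = prediction_ellipse(self._anisotropic_cloud())
        assert ell.a / ell.b == pytest.approx(2.0, rel=1e-9)
        assert ell.ecc == pytest.approx(np.sqrt(1 - 1 / 4), rel=1e-9)
        assert ell.ecc == pytest.approx(0.8660, abs=1e-4)

    def test_area_matches_semi_axes(self):
        ell = prediction_ellipse(self._anisotropic_cloud())
        assert ell.area == pytest.approx(np.pi * ell.a * ell.b)

    def test_isotropic_cloud_low_eccentricity(self, rng):
        # sample-covariance eigenvalue splitting makes the expected
        # eccentricity of an isotropic cloud ≈ (8/N)^(1/4) ≈ 0.1 at
        # N = 1e5; assert a bound with headroom over that floor
        pts = rng.normal(size=(100_000, 2))
        assert prediction_ellipse(pts).ecc < 0.15

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateEllipseError) as exc:
            prediction_ellipse(pts)
        assert exc.value.ecc == 1.0

    def test_chi2_limit_of_small_sample_quantile(self, rng):
        pts = rng.normal(size=(100_000, 2))
        qf = prediction_ellipse(pts, method="f").q
        assert qf == pytest.approx(4.60517, abs=0.001)

    @given(st.floats(0.0, 2 * np.pi))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_eccentricity_rotation_invariant(self, angle):
        pts = self._anisotropic_cloud()
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        ell = prediction_ellipse(pts @ rot.T)
        assert ell.ecc == pytest.approx(np.sqrt(1 - 1 / 4), abs=1e-9)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        pts = self._anisotropic_cloud()
        base = prediction_ellipse(pts)
        scaled = prediction_ellipse(c * pts)
        assert scaled.area == pytest.approx(c ** 2 * base.area, rel=1e-9)
        assert scaled.ecc == pytest.approx(base.ecc, rel=1e-9)
        assert sway_path(c * pts) == pytest.approx(c * sway_path(pts),
                                                   rel=1e-9)
        assert rms_norm(np.column_stack([c * pts, np.zeros(len(pts))])) == \
            pytest.approx(c * rms_norm(
                np.column_stack([pts, np.zeros(len(pts))])), rel=1e-9)


class TestExtractSls:
    def test_noiseless_t_tot_matches_eccentric_duration(self, sls_ideal):
        ev = segment_sls(sls_ideal["pitch"], FS)
        with pytest.warns(UserWarning, match="degenerate"):
            rec = extract_sls_features(sls_ideal["tibia"],
                                       sls_ideal["foot"],
                                       sls_ideal["orient"], ev)
        # configured movement is 4.4 s; the eccentric phase is half
        assert rec.values["T_tot"] == pytest.approx(2.2, abs=3 / FS)
        assert rec.values["wpeak_leg"] == pytest.approx(
            sls_ideal["gt"].true_parameter_values["wpeak_leg"], rel=0.02)

    def test_extraction_is_pure(self, sls_noisy):
        ev = segment_sls(sls_noisy["pitch"], FS)
        a = extract_sls_features(sls_noisy["tibia"], sls_noisy["foot"],
                                 sls_noisy["orient"], ev)
        b = extract_sls_features(sls_noisy["tibia"], sls_noisy["foot"],
                                 sls_noisy["orient"], ev)
        assert a.values == b.values

    def test_sway_parameters_present_and_positive(self, sls_noisy):
        ev = segment_sls(sls_noisy["pitch"], FS)
        rec = extract_sls_features(sls_noisy["tibia"], sls_noisy["foot"],
                                   sls_noisy["orient"], ev)
        assert rec.values["SP"] > 0 and rec.values["SA"] > 0
        assert 0 <= rec.values["SAecc"] <= 1

    def test_missing_stream_named(self, sls_noisy):
        ev = segment_sls(sls_noisy["pitch"], FS)
        with pytest.raises(EmptyInputError, match="foot"):
            extract_sls_features(sls_noisy["tibia"], None,
                                 sls_noisy["orient"], ev)


class TestExtractCht:
    def test_configured_flight_and_contact_recovered(self, cht_ideal):
        ev = segment_cht(cht_ideal["foot"], gyro_smooth=1, acc_smooth=1)
        rec = extract_cht_features(cht_ideal["foot"], cht_ideal["tibia"],
                                   None, ev)
        gt = cht_ideal["gt"].true_parameter_values
        assert rec.values["FT"] == pytest.approx(gt["FT2"], abs=1 / FS)
        assert rec.values["CT"] == pytest.approx(gt["CT2"], abs=1 / FS)
        assert rec.values["T_tot"] == pytest.approx(gt["T_tot"], abs=2 / FS)

    def test_constant_risk_window_rms_equals_peak(self):
        n = 1000
        c = np.deg2rad(120.0)
        rec = ImuRecording(
            t=np.arange(n) / FS, acc=np.tile([0, 0, G], (n, 1)),
            gyro=np.tile([0.0, c, 0.0], (n, 1)),
            mag=np.tile([22.0, 0, -42.0], (n, 1)), fs=FS, location="foot")
        ev = TaskEvents(task="CHT", fs=FS, to=[100, 300, 500],
                        la=[200, 400, 600],
                        risk_windows=[(200, 250), (400, 450), (600, 650)])
        out = extract_cht_features(rec, rec, None, ev)
        assert out.values["RMSw_foot"] == pytest.approx(120.0)
        assert out.values["wpeak_foot"] == pytest.approx(120.0)

    def test_single_hop_insufficient(self, cht_ideal):
        ev = TaskEvents(task="CHT", fs=FS, to=[100], la=[200],
                        risk_windows=[(200, 250)])
        with pytest.raises(InsufficientHopsError):
            extract_cht_features(cht_ideal["foot"], cht_ideal["tibia"],
                                 None, ev)

    def test_hop_distance_passthrough(self, cht_ideal):
        ev = segment_cht(cht_ideal["foot"], gyro_smooth=1, acc_smooth=1)
        rec = extract_cht_features(cht_ideal["foot"], cht_ideal["tibia"],
                                   None, ev, hop_distance=4.85)
        assert rec.values["hop_distance"] == 4.85


class TestExtractCmj:
    def test_constant_net_force_rectangle_integral(self):
        fs, m = 1000.0, 74.0
        bw = m * G
        n = 3000
        grfv = np.full(n, bw)
        grfv[1000:1500] = bw + 200.0
        rec = GrfRecording(t=np.arange(n) / fs, grfv=grfv, fs=fs,
                           body_mass=m)
        ev = TaskEvents(task="CMJ", fs=fs, i_unweight_end=1000,
                        i_flight_start=1500)
        out = extract_cmj_features(rec, ev)
        # trapezoid over the half-open window loses half a sample per edge
        assert out.values["AUC_F"] == pytest.approx(200.0 * 0.5 / m,
                                                    rel=0.01)
        assert out.values["F_max"] == pytest.approx(bw + 200.0)

    def test_triangular_pulse_peak(self):
        fs, m = 1000.0, 74.0
        bw = m * G
        n = 3000
        grfv = np.full(n, bw)
        ramp = np.linspace(0, 800.0, 250)
        grfv[1000:1250] = bw + ramp
        grfv[1250:1500] = bw + ramp[::-1]
        rec = GrfRecording(t=np.arange(n) / fs, grfv=grfv, fs=fs,
                           body_mass=m)
        ev = TaskEvents(task="CMJ", fs=fs, i_unweight_end=1000,
                        i_flight_start=1500)
        out = extract_cmj_features(rec, ev)
        assert out.values["F_max"] == pytest.approx(bw + 800.0)
        assert out.values["F_max"] - bw == pytest.approx(800.0)

    def test_simulated_jump_recovers_takeoff_velocity(self, cmj_ideal):
        ev, _ = segment_cmj(cmj_ideal["grf"])
        out = extract_cmj_features(cmj_ideal["grf"], ev)
        assert out.values["AUC_F"] == pytest.approx(np.sqrt(2 * G * 0.30),
                                                    rel=0.02)

    def test_empty_window_raises(self, cmj_ideal):
        ev = TaskEvents(task="CMJ", fs=1000.0, i_unweight_end=500,
                        i_flight_start=500)
        with pytest.raises(EmptyInputError):
            extract_cmj_features(cmj_ideal["grf"], ev)


def test_degree_conversion_roundtrip():
    """Reported °/s values equal the internal rad/s values times 180/π."""
    internal = 7.5  # rad/s
    sig = np.tile([0.0, internal, 0.0], (10, 1))
    assert rms_norm(np.degrees(sig)) == pytest.approx(
        rms_norm(sig) * 180.0 / np.pi, rel=1e-13)
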