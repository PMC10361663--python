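"""Gaussian center tracking and equations-of-motion extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindleflux.image_prep import LineProfile, SpindleAxis
from spindleflux.kinematics import (
    CenterTrack,
    fit_gaussian,
    fit_kinematics,
    measure_x0,
    track_centers,
    velocity_at_reference,
)


def gaussian_profile(mu, sigma=1.0, amp=5.0, offset=1.0, span=10.0, n=101):
    x = np.linspace(0, span, n)
    return LineProfile(x, offset + amp * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)), 2.0)


class TestGaussianFit:
    def test_exact_recovery(self):
        fit = fit_gaussian(gaussian_profile(4.0))
        assert fit.center == pytest.approx(4.0, abs=1e-6)
        assert fit.sigma == pytest.approx(1.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-6)
        assert fit.offset == pytest.approx(1.0, abs=1e-6)
        assert fit.converged

    def test_constant_offset_only_shifts_offset(self):
        f1 = fit_gaussian(gaussian_profile(3.0))
        prof = gaussian_profile(3.0)
        f2 = fit_gaussian(LineProfile(prof.positions, prof.intensities + 10, 2.0))
        assert f2.center == pytest.approx(f1.center, abs=1e-9)
        assert f2.sigma == pytest.approx(f1.sigma, abs=1e-9)
        assert f2.offset == pytest.approx(f1.offset + 10, abs=1e-6)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(delta=st.floats(-2.0, 2.0))
    def test_translation_equivariance(self, delta):
        base = fit_gaussian(gaussian_profile(5.0))
        shifted = fit_gaussian(gaussian_profile(5.0 + delta))
        assert shifted.center - base.center == pytest.approx(delta, abs=1e-6)

    def test_flat_profile_not_converged(self):
        x = np.linspace(0, 10, 40)
        fit = fit_gaussian(LineProfile(x, np.full(40, 2.0), 2.0))
        assert not fit.converged

    def test_offset_free_mode(self):
        fit = fit_gaussian(gaussian_profile(4.0, offset=0.0), with_offset=False)
        assert fit.center == pytest.approx(4.0, abs=1e-6)
        assert fit.offset == 0.0


class TestTrackCenters:
    def test_linear_motion_recovered(self):
        times = np.arange(10) * 5.0
        profiles = [gaussian_profile(3.0 + 0.1 * i) for i in range(10)]
        track = track_centers(profiles, 0, times)
        slope = np.polyfit(np.arange(10), track.centers, 1)[0]
        assert slope == pytest.approx(0.1, rel=0.05)

    def test_static_pulse_constant_centers(self):
        times = np.arange(6) * 5.0
        profiles = [gaussian_profile(4.2) for _ in range(6)]
        track = track_centers(profiles, 1, times)
        assert np.ptp(track.centers) < 1e-6
        assert track.times[0] == 0.0

    def test_failed_frame_dropped(self):
        times = np.arange(7) * 5.0
        profiles = [gaussian_profile(3.0 + 0.1 * i) for i in range(7)]
        x = profiles[3].positions
        profiles[3] = LineProfile(x, np.full(x.size, 2.0), 2.0)  # flat: fit fails
        track = track_centers(profiles, 0, times)
        assert len(track.centers) == 6
        assert track.n_dropped == 1

    def test_too_few_usable_frames_rejected(self):
        times = np.arange(3) * 5.0
        profiles = [gaussian_profile(3.0) for _ in range(3)]
        with pytest.raises(ValueError, match="usable"):
            track_centers(profiles, 0, times)


class TestFitKinematics:
    def _track(self, t_min, centers):
        t_s = np.asarray(t_min) * 60.0
        return CenterTrack(t_s, np.asarray(centers), np.ones(len(t_s)))

    def test_quadratic_identity(self):
        t = np.linspace(0, 2, 9)  # minutes
        mu = 1 + 0.5 * t + 0.05 * t ** 2
        u0, a, coeffs, r2 = fit_kinematics(self._track(t, mu))
        assert u0 == pytest.approx(0.5, abs=1e-9)
        assert a == pytest.approx(0.1, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_linear_track_zero_acceleration(self):
        t = np.linspace(0, 2, 8)
        u0, a, *_ = fit_kinematics(self._track(t, 2 - 0.7 * t))
        assert a == pytest.approx(0.0, abs=1e-9)
        assert u0 == pytest.approx(-0.7, abs=1e-9)

    def test_time_reversal_negates_linear_velocity(self):
        t = np.linspace(0, 2, 8)
        mu = 1 + 0.4 * t
        u0f, *_ = fit_kinematics(self._track(t, mu))
        u0r, *_ = fit_kinematics(self._track(t, mu[::-1]))
        assert u0r == pytest.approx(-u0f, abs=1e-9)

    def test_duplicate_times_rejected(self):
        track = CenterTrack(np.array([0.0, 0.0, 0.0, 0.0]),
                            np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4))
        with pytest.raises(ValueError, match="duplicate"):
            fit_kinematics(track)


class TestVelocityAtReference:
    def test_zero_distance_returns_u0(self):
        res = velocity_at_reference(u0=-1.3, a=0.4, x0=0.0)
        assert res.t_star == 0.0
        assert res.uc == -1.3

    def test_uniform_motion(self):
        res = velocity_at_reference(u0=-1.0, a=0.0, x0=2.0)
        assert res.t_star == pytest.approx(2.0)
        assert res.uc == pytest.approx(-1.0)

    def test_quadratic_worked_example(self):
        res = velocity_at_reference(u0=-2.0, a=0.2, x0=3.0)
        assert res.t_star == pytest.approx(1.6334, abs=1e-4)
        assert res.uc == pytest.approx(-1.6733, abs=1e-4)
        assert sorted(np.round(res.roots, 4)) == [1.6334, 18.3666]

    def test_no_real_crossing_rejected(self):
        with pytest.raises(ValueError, match="real crossing"):
            velocity_at_reference(u0=0.1, a=1.0, x0=5.0)

    def test_degenerate_rest_rejected(self):
        with pytest.raises(ValueError):
            velocity_at_reference(u0=0.0, a=0.0, x0=1.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(x0=st.floats(0.0, 5.0), u0=st.floats(-3.0, 3.0),
           a=st.floats(-1.0, 1.0))
    def test_substitution_identity(self, x0, u0, a):
        if abs(u0) < 1e-3 and abs(a) < 1e-3:
            return
        if a != 0 and u0 * u0 - 2 * a * x0 < 0:
            return
        res = velocity_at_reference(u0, a, x0)
        assert abs(x0 + u0 * res.t_star + 0.5 * a * res.t_star ** 2) < 1e-9 * max(1, abs(res.t_star) ** 2)
        assert res.uc == u0 + a * res.t_star  # exact identity

    def test_matches_dense_scan_on_random_triples(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 50:
            x0 = rng.uniform(0.1, 4.0)
            u0 = rng.uniform(-3, 3)
            a = rng.uniform(-1, 1)
            if abs(a) > 1e-6 and u0 * u0 - 2 * a * x0 < 0:
                continue
            if abs(u0) < 0.05 and abs(a) < 0.05:
                continue
            res = velocity_at_reference(u0, a, x0)
            if abs(res.t_star) > 10:
                continue
            tt = np.arange(-10, 10, 1e-4)
            xx = x0 + u0 * tt + 0.5 * a * tt ** 2
            sign_change = np.flatnonzero(np.diff(np.sign(xx)) != 0)
            crossings = tt[sign_change] - xx[sign_change] * 1e-4 / (
                xx[sign_change + 1] - xx[sign_change])
            t_scan = crossings[np.argmin(np.abs(crossings))]
            assert abs(t_scan - res.t_star) < 1e-3
            checked += 1


class TestMeasureX0:
    def _axis(self):
        return SpindleAxis((0.0, 0.0), (100.0, 0.0), (4.5, 5.5), 0.1)

    def test_worked_coordinates(self):
        assert measure_x0(self._axis(), 7.0, "chrom_edge") == pytest.approx(1.5)

    def test_on_landmark_is_zero(self):
        assert measure_x0(self._axis(), 5.5, "chrom_edge") == 0.0

    def test_pole_landmark(self):
        assert measure_x0(self._axis(), 7.0, "pole") == pytest.approx(3.0)

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            measure_x0(self._axis(), 12.0, "chrom_edge")
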