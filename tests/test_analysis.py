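"""Track statistics: smoothing, curvature, distribution shape, classifiers."""
import math

import numpy as np
import pytest
from scipy import stats

from mesotail import analysis
from mesotail.analysis import ScalingRow


class TestSmoothPath:
    def test_reproduces_cubic_exactly(self):
        t = np.linspace(0, 1, 50)
        track = np.column_stack([t**3 - 2 * t, 0.5 * t**3 + t**2])
        sm = analysis.smooth_path(track, window=5)
        assert np.allclose(sm, track, atol=1e-9)

    def test_constant_track_unchanged(self):
        track = np.full((30, 2), 3.7)
        assert np.allclose(analysis.smooth_path(track), track)

    def test_outlier_attenuated_endpoints_kept(self):
        t = np.arange(40, dtype=float)
        track = np.column_stack([t, np.zeros_like(t)])
        track[20, 1] = 1.0  # symmetric outlier
        sm = analysis.smooth_path(track)
        assert abs(sm[20, 1]) < 0.8
        assert np.allclose(sm[0], track[0], atol=1e-9)
        assert np.allclose(sm[-1], track[-1], atol=1e-9)

    def test_short_track_passthrough_warns(self):
        track = np.zeros((3, 2))
        with pytest.warns(UserWarning):
            out = analysis.smooth_path(track)
        assert np.allclose(out, track)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            analysis.smooth_path(np.zeros((10, 2)), window=4)


class TestCurvatureSeries:
    def test_circle_curvature_is_inverse_radius(self):
        R, dt = 2.0, 0.05
        t = np.arange(0, 30, dt)
        track = np.column_stack([R * np.cos(0.3 * t), R * np.sin(0.3 * t)])
        cs = analysis.curvature_series(track, dt)
        k = cs.kappa[cs.valid][5:-5]
        assert np.allclose(k, 1 / R, rtol=0.01)

    def test_straight_line_zero_curvature(self):
        dt = 0.1
        t = np.arange(0, 20, dt)
        track = np.column_stack([0.3 * t, -0.1 * t])
        cs = analysis.curvature_series(track, dt)
        assert np.allclose(cs.kappa[cs.valid], 0.0, atol=1e-9)

    def test_sinusoid_matches_closed_form(self):
        A, w, dt = 0.8, 0.7, 0.01
        t = np.arange(0, 25, dt)
        track = np.column_stack([t, A * np.sin(w * t)])
        cs = analysis.curvature_series(track, dt)
        yp = A * w * np.cos(w * t)
        ypp = -A * w**2 * np.sin(w * t)
        expected = ypp / (1 + yp**2) ** 1.5
        sl = slice(10, -10)
        err = np.abs(cs.kappa[sl] - expected[sl])
        assert np.nanmax(err) < 0.02 * np.max(np.abs(expected))

    def test_resampled_circle_keeps_curvature(self):
        R = 3.0
        t = np.arange(0, 60, 0.05)
        track = np.column_stack([R * np.cos(0.2 * t), R * np.sin(0.2 * t)])
        for sub in (1, 4, 10):
            cs = analysis.curvature_series(track[::sub], 0.05 * sub)
            k = cs.kappa[cs.valid][3:-3]
            assert np.allclose(k, 1 / R, rtol=0.02)

    def test_stalled_track_raises(self):
        track = np.zeros((50, 2))
        with pytest.raises(ValueError):
            analysis.curvature_series(track, 1.0)


class TestKappaStats:
    def test_gaussian_samples_look_gaussian(self, rng):
        k = rng.normal(0, 0.4, 10_000)
        cs = analysis.CurvatureSeries(
            t=np.arange(k.size, dtype=float), v=np.ones(k.size),
            omega=k.copy(), kappa=k, v_min=0.0)
        ks = analysis.kappa_stats(cs)
        assert abs(ks.excess_kurtosis) < 0.2
        assert ks.ks_distance < 0.02
        assert ks.kappa_rms == pytest.approx(0.4, rel=0.05)

    def test_sharp_peak_mixture_has_high_kurtosis(self, rng):
        """90% tight + 10% broad Gaussian: the sharply-peaked shape."""
        k = np.where(rng.random(20_000) < 0.9,
                     rng.normal(0, 0.1, 20_000), rng.normal(0, 1.0, 20_000))
        cs = analysis.CurvatureSeries(
            t=np.arange(k.size, dtype=float), v=np.ones(k.size),
            omega=k.copy(), kappa=k, v_min=0.0)
        direct = stats.kurtosis(k, fisher=True, bias=False)
        ks = analysis.kappa_stats(cs)
        assert ks.excess_kurtosis == pytest.approx(direct, rel=1e-9)
        assert ks.excess_kurtosis > 2

    def test_constant_kappa_rms(self):
        k = np.full(500, -0.7)
        cs = analysis.CurvatureSeries(
            t=np.arange(500.0), v=np.ones(500), omega=k.copy(), kappa=k,
            v_min=0.0)
        assert analysis.kappa_stats(cs).kappa_rms == pytest.approx(0.7)

    def test_time_reversal_invariance(self, rng):
        """κ_rms of a track equals that of the reversed track."""
        t = np.arange(0, 40, 0.1)
        track = np.column_stack([
            t + 0.2 * np.sin(0.9 * t), 0.5 * t + 0.3 * np.cos(0.4 * t)])
        a = analysis.kappa_stats(analysis.curvature_series(track, 0.1))
        b = analysis.kappa_stats(analysis.curvature_series(track[::-1], 0.1))
        assert a.kappa_rms == pytest.approx(b.kappa_rms, rel=1e-6)

    def test_requires_enough_samples(self):
        k = np.ones(10)
        cs = analysis.CurvatureSeries(np.arange(10.0), np.ones(10),
                                      k.copy(), k, 0.0)
        with pytest.raises(ValueError):
            analysis.kappa_stats(cs)


class _FakeTraj:
    def __init__(self, t, xy, theta):
        self.t = t
        self.x = xy[:, 0]
        self.y = xy[:, 1]
        self.theta = theta


def _straight_traj(angle_deg, theta=0.0, n=120):
    t = np.arange(n, dtype=float)
    d = np.radians(angle_deg)
    xy = np.column_stack([np.cos(d) * t, np.sin(d) * t]) * 0.1
    return _FakeTraj(t, xy, np.full(n, theta))


class TestClassifyOrientation:
    @pytest.mark.parametrize("angle,expected", [
        (0.0, "long"), (15.0, "long"), (45.0, "skewed"),
        (75.0, "short"), (90.0, "short"), (180.0, "long"),
    ])
    def test_bins(self, angle, expected):
        oc = analysis.classify_orientation(_straight_traj(angle))
        assert oc.label == expected
        assert oc.fractions[expected] > 0.9

    def test_rotation_invariance(self):
        """Rotating trajectory and body frame together keeps the class."""
        for rot in (0.3, 1.2, -2.0):
            oc = analysis.classify_orientation(
                _straight_traj(20.0 + np.degrees(rot), theta=rot))
            assert oc.label == "long"


class TestConcavityClassify:
    def test_exponential_is_concave_up(self):
        F = np.linspace(0, 3, 20)
        assert analysis.concavity_classify(F, np.exp(-F)) == "concave_up"

    def test_plateau_crash_is_concave_down(self):
        F = np.linspace(0, 1, 20)
        V = np.where(F < 0.8, 1.0, (1 - F) / 0.2)
        assert analysis.concavity_classify(F, V) == "concave_down"

    @pytest.mark.parametrize("n", [12, 20, 41])
    def test_pure_linear_is_indeterminate(self, n):
        F = np.linspace(0, 1, n)
        assert analysis.concavity_classify(F, 1 - F) == "indeterminate"

    def test_needs_six_points(self):
        F = np.linspace(0, 2, 4)
        with pytest.raises(ValueError):
            analysis.concavity_classify(F, np.exp(-F))


class TestEntrapment:
    def test_counts_long_pauses_only(self):
        t = np.arange(600.0)
        x = np.concatenate([
            0.1 * np.arange(200),                      # moving
            np.full(100, 0.1 * 199 + 0.0),             # 100 s pause
            0.1 * np.arange(300) + 0.1 * 199,          # moving again
        ])
        tr = _FakeTraj(t, np.column_stack([x, np.zeros_like(x)]), np.zeros_like(x))
        assert analysis.entrapment_events(tr, min_duration=60.0) == 1
        assert analysis.entrapment_events(tr, min_duration=150.0) == 0


class TestScalingFit:
    def test_recovers_generating_slope(self, rng):
        from mesotail.experiments import synthetic_scaling_rows
        rows = synthetic_scaling_rows(24, slope=0.8, rng=rng)
        fit = analysis.scaling_fit(rows)
        assert fit.correlation > 0.99
        assert fit.slope == pytest.approx(0.8, rel=0.05)

    def test_null_case_low_correlation(self, rng):
        rows = [ScalingRow(kappa_rms=1.0 + 0.01 * rng.random(),
                           N=rng.uniform(3, 40), tau=rng.uniform(2, 20),
                           dtheta=rng.uniform(0.3, 1.5), v=rng.uniform(0.02, 0.3))
                for _ in range(40)]
        fit = analysis.scaling_fit(rows)
        assert abs(fit.correlation) < 0.4

    def test_degenerate_spread_rejected(self):
        rows = [ScalingRow(1.0, 10, 5, 0.0, 0.1) for _ in range(8)]
        with pytest.raises(ValueError):
            analysis.scaling_fit(rows)

    def test_needs_six_runs(self):
        rows = [ScalingRow(1.0, 10, 5, 1.0, 0.1) for _ in range(5)]
        with pytest.raises(ValueError):
            analysis.scaling_fit(rows)
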