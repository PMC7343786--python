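"""Waveform construction, trimming, filtering and cycle estimation."""

import numpy as np
import pytest

import plaquesync as ps
from plaquesync.errors import (
    NoDominantFrequencyError,
    TooShortPlaqueError,
    TooShortSeriesError,
)
from plaquesync.waveforms import radial_displacements

from conftest import make_series, sinusoid


def traj_from_rows(rows, cols=None, name="PTS", fs=25.0):
    rows = np.asarray(rows, dtype=float)
    if cols is None:
        cols = np.tile(np.arange(rows.shape[0], dtype=float)[:, None],
                       (1, rows.shape[1]))
    return ps.PixelTrajectory(name, rows, np.asarray(cols, dtype=float), fs)


class TestTrim:
    def test_120_pixels_trimmed_to_70(self):
        traj = traj_from_rows(np.zeros((120, 5)))
        assert ps.trim_plaque_edges(traj, 25).n_pixels == 70

    def test_zero_trim_is_identity(self):
        traj = traj_from_rows(np.zeros((30, 5)))
        out = ps.trim_plaque_edges(traj, 0)
        assert out.n_pixels == 30
        np.testing.assert_array_equal(out.rows, traj.rows)

    def test_short_plaque_raises(self):
        traj = traj_from_rows(np.zeros((50, 5)))
        with pytest.raises(TooShortPlaqueError):
            ps.trim_plaque_edges(traj, 25)

    def test_order_preserved(self):
        rows = np.arange(60, dtype=float)[:, None] * np.ones((1, 4))
        out = ps.trim_plaque_edges(traj_from_rows(rows), 10)
        np.testing.assert_array_equal(out.rows[:, 0], np.arange(10, 50))


class TestWallDiameter:
    fs = 25.0

    def anti_phase_pair(self, amp=2.0, n_cols=5, freq=1.0, duration=4.0):
        t = np.arange(int(duration * self.fs)) / self.fs
        up = 20.0 + amp * np.sin(2 * np.pi * freq * t)
        down = 80.0 - amp * np.sin(2 * np.pi * freq * t)
        cols = np.tile(np.arange(n_cols, dtype=float)[:, None], (1, t.size))
        awl = ps.PixelTrajectory("AWL", np.tile(up, (n_cols, 1)), cols, self.fs)
        pwl = ps.PixelTrajectory("PWL", np.tile(down, (n_cols, 1)), cols, self.fs)
        return awl, pwl

    def test_anti_phase_sinusoids_double_amplitude(self):
        awl, pwl = self.anti_phase_pair(amp=1.5)
        wd = ps.wall_diameter(awl, pwl)
        # sampling does not land exactly on the sinusoid extremes
        assert np.ptp(wd.values) == pytest.approx(2 * 2 * 1.5, rel=0.01)
        assert wd.values.min() >= 0

    def test_noisy_column_not_selected(self):
        awl, pwl = self.anti_phase_pair(n_cols=5)
        rng = np.random.default_rng(0)
        pwl.rows[2] = 80.0 + rng.normal(0, 3.0, pwl.n_frames)  # wreck column 2
        wd = ps.wall_diameter(awl, pwl)
        assert wd.meta["column"] != 2

    def test_static_interfaces_flagged(self):
        cols = np.tile(np.arange(3, dtype=float)[:, None], (1, 50))
        awl = ps.PixelTrajectory("AWL", np.full((3, 50), 20.0), cols, self.fs)
        pwl = ps.PixelTrajectory("PWL", np.full((3, 50), 80.0), cols, self.fs)
        with pytest.warns(UserWarning, match="cyclicity undefined"):
            wd = ps.wall_diameter(awl, pwl)
        assert np.isnan(wd.meta["cyclicity"])
        assert np.ptp(wd.values) == 0.0


class TestPlaqueRadialDistance:
    fs = 25.0

    def make_pair(self, delay=0.0, amp=1.0, n=100, base_top=40.0, base_bot=60.0):
        t = np.arange(n) / self.fs
        top = base_top + amp * np.sin(2 * np.pi * 1.0 * (t - delay))
        bot = base_bot + amp * np.sin(2 * np.pi * 1.0 * t)
        cols = np.tile(np.arange(3, dtype=float)[:, None], (1, n))
        pts = ps.PixelTrajectory("PTS", np.tile(top, (3, 1)), cols, self.fs)
        pbs = ps.PixelTrajectory("PBS", np.tile(bot, (3, 1)), cols, self.fs)
        return pts, pbs

    def test_identical_motion_gives_constant_series(self):
        pts, pbs = self.make_pair(delay=0.0)
        for s in ps.plaque_radial_distance(pts, pbs):
            assert np.ptp(s.values) == pytest.approx(0.0, abs=1e-9)

    def test_delayed_top_oscillates_with_closed_form_amplitude(self):
        # |sin(w(t-tau)) - sin(wt)| = 2|sin(w tau/2)| |cos(w t - w tau/2)|
        delay, amp = 0.2, 1.0
        pts, pbs = self.make_pair(delay=delay, amp=amp)
        series = ps.plaque_radial_distance(pts, pbs)[0]
        predicted = 2 * amp * abs(np.sin(np.pi * 1.0 * delay))
        assert np.ptp(series.values) == pytest.approx(2 * predicted, rel=0.02)

    def test_swapping_surfaces_leaves_series_unchanged(self):
        pts, pbs = self.make_pair(delay=0.15)
        a = ps.plaque_radial_distance(pts, pbs)
        b = ps.plaque_radial_distance(pbs, pts)
        for sa, sb in zip(a, b):
            np.testing.assert_allclose(sa.values, sb.values, atol=1e-12)

    def test_non_negative_by_construction(self):
        pts, pbs = self.make_pair(delay=0.3, base_top=59.0, base_bot=60.0)
        for s in ps.plaque_radial_distance(pts, pbs):
            assert (s.values >= 0).all()


class TestHighpass:
    def test_constant_series_maps_to_zero(self):
        out = ps.highpass(make_series(np.full(200, 7.0)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_cardiac_band_passes_nearly_unattenuated(self):
        x = sinusoid(1.2, duration=40.0)
        out = ps.highpass(x)
        mid = slice(200, 800)
        ratio = np.std(out.values[mid]) / np.std(x.values[mid])
        assert ratio > 0.99

    def test_slow_drift_removed(self):
        x = sinusoid(0.1, duration=60.0)
        out = ps.highpass(x)
        mid = slice(300, 1200)
        assert np.std(out.values[mid]) / np.std(x.values[mid]) < 1e-3

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = make_series(rng.normal(size=300))
        y = make_series(rng.normal(size=300))
        lhs = ps.highpass(make_series(2.0 * x.values + 3.0 * y.values))
        rhs = 2.0 * ps.highpass(x).values + 3.0 * ps.highpass(y).values
        np.testing.assert_allclose(lhs.values, rhs, atol=1e-9)

    def test_short_series_raises(self):
        with pytest.raises(TooShortSeriesError):
            ps.highpass(make_series(np.arange(10.0)))


class TestDominantFrequency:
    def test_pure_tone_window(self):
        win = ps.dominant_frequency(sinusoid(1.0, duration=10.0))
        assert win.f0 == pytest.approx(1.0, abs=0.1)
        assert win.length == 25

    def test_strongest_component_wins(self):
        t = np.arange(250) / 25.0
        x = make_series(
            np.sin(2 * np.pi * 1.0 * t) + 0.3 * np.sin(2 * np.pi * 2.0 * t)
        )
        win = ps.dominant_frequency(x)
        assert win.f0 == pytest.approx(1.0, abs=0.1)

    def test_white_noise_has_no_dominant_frequency(self):
        rng = np.random.default_rng(0)
        x = make_series(rng.normal(size=250))
        with pytest.raises(NoDominantFrequencyError):
            ps.dominant_frequency(x)

    def test_window_fits_inside_series(self):
        win = ps.dominant_frequency(sinusoid(0.9, duration=4.0))
        assert win.start + win.length <= 100
        assert win.start >= win.length  # past the filter warm-up


class TestDisplacementSeries:
    def test_frame_one_positions_equal_contour(self):
        rows = 40.0 + np.cumsum(np.ones((4, 10)), axis=1) - 1
        traj = traj_from_rows(rows)
        series = radial_displacements(traj, "PTS_radial")
        assert len(series) == 4
        for p, s in enumerate(series):
            assert s.values[0] == rows[p, 0]
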