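"""Bleb detection and angular-coordination statistics."""

import numpy as np
import pytest

from blebflow import (angular_intensity_distribution, bleb_angle_histogram,
                      bleb_frequency, consecutive_bleb_angles, detect_blebs,
                      front_angle_series)
from blebflow.blebs import BlebEvent
from blebflow.geometry import fold_angle_deg


class TestAngularIntensityDistribution:
    @staticmethod
    def disk(value=50.0):
        from skimage.draw import disk as skdisk

        frame = np.zeros((128, 128))
        frame[skdisk((64, 64), 40)] = value
        return frame, frame > 0

    def test_uniform_disk_flat(self):
        frame, mask = self.disk()
        _, dist = angular_intensity_distribution(frame, mask, (64, 64),
                                                 n_bins=36)
        assert dist.std() / dist.mean() < 0.03

    def test_single_blob_argmax(self):
        frame, mask = self.disk(value=1.0)
        ang = np.deg2rad(40.0)
        by, bx = 64 + 30 * np.sin(ang), 64 + 30 * np.cos(ang)
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        frame += 500 * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / 18.0)
        frame[~mask] = 0
        centres, dist = angular_intensity_distribution(
            frame, mask, (64, 64), n_bins=36)
        assert abs(centres[np.argmax(dist)] - 40.0) <= 10.0

    def test_two_blob_mass_ratio(self):
        from skimage.draw import disk as skdisk

        frame = np.zeros((128, 128))
        mask = np.zeros((128, 128), bool)
        mask[skdisk((64, 64), 40)] = True
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        for ang_deg, amp in ((45.0, 1000.0), (165.0, 500.0)):
            a = np.deg2rad(ang_deg)
            by, bx = 64 + 30 * np.sin(a), 64 + 30 * np.cos(a)
            frame += amp * np.exp(-((xx - bx) ** 2 + (yy - by) ** 2)
                                  / 18.0)
        frame[~mask] = 0
        centres, dist = angular_intensity_distribution(
            frame, mask, (64, 64), n_bins=12)
        m_a = dist[1]  # sector [30, 60)
        m_b = dist[5]  # sector [150, 180)
        assert m_a / m_b == pytest.approx(2.0, rel=0.1)

    def test_centroid_outside_mask_rejected(self):
        frame, mask = self.disk()
        with pytest.raises(ValueError):
            angular_intensity_distribution(frame, mask, (2, 2))


class TestFrontAngleSeries:
    @staticmethod
    def blob_frames(angles_deg, r=30.0):
        n = len(angles_deg)
        frames = np.zeros((n, 128, 128))
        masks, cents = [], []
        from skimage.draw import disk as skdisk

        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        base = np.zeros((128, 128), bool)
        base[skdisk((64, 64), 40)] = True
        for i, ang_deg in enumerate(angles_deg):
            a = np.deg2rad(ang_deg)
            by, bx = 64 + r * np.sin(a), 64 + r * np.cos(a)
            f = 10.0 * base + 500 * np.exp(
                -((xx - bx) ** 2 + (yy - by) ** 2) / 18.0)
            f[~base] = 0
            frames[i] = f
            masks.append(base)
            cents.append((64.0, 64.0))
        return frames, masks, cents

    def test_static_blob_constant(self):
        frames, masks, cents = self.blob_frames([40.0] * 30)
        series = front_angle_series(frames, masks, cents,
                                    frame_interval_s=0.5, band_px=None)
        assert np.allclose(series.angles_deg, 40.0, atol=3.0)

    def test_step_smoothed_monotone(self):
        angles = [0.0] * 60 + [90.0] * 60
        frames, masks, cents = self.blob_frames(angles)
        series = front_angle_series(frames, masks, cents,
                                    frame_interval_s=0.5, sigma_s=25.0,
                                    band_px=None)
        mid = series.angles_deg[40:80]
        assert np.all(np.diff(mid) >= -1.0)  # monotone through the step
        cross = np.argmin(np.abs(series.angles_deg - 45.0))
        assert abs(cross - 60) * 0.5 <= 25.0  # within sigma of the step

    def test_wrap_safe_crossing_zero(self):
        angles = [350.0] * 60 + [10.0] * 60
        frames, masks, cents = self.blob_frames(angles)
        series = front_angle_series(frames, masks, cents,
                                    frame_interval_s=0.5, band_px=None)
        # path stays near 0/360, never wanders through 180
        dist_to_180 = np.abs(series.angles_deg - 180.0)
        assert dist_to_180.min() > 90.0


class TestDetectBlebs:
    def test_bleb_free_movie_empty(self, plain_movie):
        params, movie, truth, contours, masks = plain_movie
        cents = [m.centroid() for m in masks]
        front = front_angle_series(movie.actin, masks, cents,
                                   params.frame_interval_s)
        events = detect_blebs(contours, front, params.frame_interval_s,
                              params.pixel_size_um)
        assert events == []

    def test_scheduled_blebs_recovered(self, bleb_movie):
        params, movie, truth, contours, masks = bleb_movie
        cents = [m.centroid() for m in masks]
        front = front_angle_series(movie.actin, masks, cents,
                                   params.frame_interval_s)
        events = detect_blebs(contours, front, params.frame_interval_s,
                              params.pixel_size_um)
        assert len(events) == len(truth.true_bleb_events)
        for event, (t_true, a_true) in zip(events,
                                           truth.true_bleb_events):
            assert abs(event.time_s - t_true) <= 1.0
            assert fold_angle_deg(event.perimeter_angle_deg
                                  - fold_angle_deg(a_true)) <= 10.0

    def test_too_few_frames_rejected(self, bleb_movie):
        params, movie, truth, contours, masks = bleb_movie
        front = front_angle_series(movie.actin[:5], masks[:5],
                                   [m.centroid() for m in masks[:5]],
                                   params.frame_interval_s)
        with pytest.raises(ValueError):
            detect_blebs(contours[:5], front, params.frame_interval_s,
                         params.pixel_size_um)

    def test_intensity_scale_invariance(self, bleb_movie):
        """Detection depends only on geometry, so contours (hence
        events) are identical under global intensity scaling."""
        from blebflow import segment_movie

        params, movie, truth, contours, masks = bleb_movie
        contours2, masks2 = segment_movie(movie.membrane[:40] * 3.7,
                                          pixel_size=params.pixel_size_um)
        cents = [m.centroid() for m in masks2]
        front = front_angle_series(movie.actin[:40] * 3.7, masks2, cents,
                                   params.frame_interval_s)
        events_a = detect_blebs(contours[:40], front,
                                params.frame_interval_s,
                                params.pixel_size_um)
        events_b = detect_blebs(contours2, front,
                                params.frame_interval_s,
                                params.pixel_size_um)
        assert [e.frame_index for e in events_a] == \
            [e.frame_index for e in events_b]


class TestConsecutiveAngles:
    @staticmethod
    def event_at(angle_deg, t=0.0, r=35.0):
        a = np.deg2rad(angle_deg)
        return BlebEvent(time_s=t, frame_index=0,
                         perimeter_angle_deg=fold_angle_deg(angle_deg),
                         initiation_point_px=np.array(
                             [r * np.cos(a), r * np.sin(a)]),
                         centroid_speed_peak_um_min=5.0)

    @pytest.mark.parametrize("a,b,expected", [
        (10.0, 30.0, 20.0),
        (45.0, 45.0, 0.0),
        (0.0, 180.0, 180.0),
        (-20.0, 20.0, 40.0),
    ])
    def test_geometry(self, a, b, expected):
        angles = consecutive_bleb_angles(
            [self.event_at(a, 0.0), self.event_at(b, 1.0)])
        assert angles[0] == pytest.approx(expected, abs=1e-9)

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            consecutive_bleb_angles([self.event_at(0.0)])

    def test_fold_symmetry(self):
        """An event at -20 deg (i.e. 340) and one at +20 both report a
        20 deg perimeter angle."""
        assert self.event_at(-20.0).perimeter_angle_deg == \
            pytest.approx(20.0)
        assert self.event_at(20.0).perimeter_angle_deg == \
            pytest.approx(20.0)


class TestBlebFrequency:
    @pytest.mark.parametrize("n,duration,expected", [
        (5, 125.0, 2.4), (0, 60.0, 0.0), (10, 125.0, 4.8),
    ])
    def test_counting(self, n, duration, expected):
        events = [TestConsecutiveAngles.event_at(0.0, t=float(i))
                  for i in range(n)]
        assert bleb_frequency(events, duration) == pytest.approx(expected)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            bleb_frequency([], 0.0)


class TestBlebAngleHistogram:
    def test_all_front_one_bin(self):
        events = [TestConsecutiveAngles.event_at(5.0, t=float(i))
                  for i in range(10)]
        stats = bleb_angle_histogram(events, bin_width_deg=20.0)
        assert stats.histogram_counts[0] == 10
        assert stats.histogram_counts.sum() == 10

    def test_bin_width_must_divide(self):
        with pytest.raises(ValueError):
            bleb_angle_histogram([], bin_width_deg=50.0)

    def test_front_biased_schedule_correlates_with_actin(self):
        """Bleb angles drawn proportional to a front-peaked actin
        distribution: per-bin frequency tracks per-bin actin."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        bins = np.arange(0, 180, 20) + 10.0
        actin = np.exp(-bins / 60.0)
        probs = actin / actin.sum()
        events = []
        for i, b in enumerate(rng.choice(len(bins), size=400, p=probs)):
            ang = bins[b] + rng.uniform(-10, 10)
            events.append(TestConsecutiveAngles.event_at(
                abs(ang), t=float(i)))
        stats = bleb_angle_histogram(events, (bins, actin),
                                     bin_width_deg=20.0)
        rho = spearmanr(stats.histogram_counts, stats.histogram_actin)[0]
        assert rho > 0.8
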