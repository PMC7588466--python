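"""Generator contracts: determinism, conservation, calibration, and the
statistical structure the downstream analyses assume."""

import numpy as np
import pytest

from blebflow import fit_decay, track_metrics
from blebflow.polarity import IntensityProfile
from blebflow.synthetic import (BlebSpec, SimulationParams,
                                simulate_cell_movie,
                                simulate_intensity_profile,
                                simulate_perimeter_signals, simulate_track)


def small_params(**kw):
    base = dict(n_frames=6, seed=1, store_flow=True)
    base.update(kw)
    return SimulationParams(**base)


class TestSimulateCellMovie:
    def test_deterministic(self):
        a, _ = simulate_cell_movie(small_params())
        b, _ = simulate_cell_movie(small_params())
        assert np.array_equal(a.membrane, b.membrane)
        assert np.array_equal(a.actin, b.actin)

    def test_tiff_round_trip_bit_identical(self, tmp_path):
        import hashlib

        movie, _ = simulate_cell_movie(small_params())
        h = []
        for name in ("a.tif", "b.tif"):
            movie.save(tmp_path / name)
            h.append(hashlib.sha256((tmp_path / name).read_bytes())
                     .hexdigest())
        assert h[0] == h[1]

    def test_no_forcing_static(self):
        _, truth = simulate_cell_movie(small_params(
            noise_sd=1e-9, retrograde_speed_um_min=1e-9))
        xy = truth.true_track.xy_um
        assert np.allclose(xy, xy[0], atol=1e-6)
        ref = truth.true_contours[0].points
        for c in truth.true_contours[1:]:
            assert np.allclose(c.points, ref)

    def test_conservation_without_blebs(self):
        movie, _ = simulate_cell_movie(small_params(n_frames=12,
                                                    noise_sd=0.0))
        totals = movie.actin.sum(axis=(1, 2))
        assert (totals.max() - totals.min()) / totals.mean() < 0.005

    def test_flow_calibration_round_trip(self):
        params = small_params(noise_sd=0.0)
        movie, truth = simulate_cell_movie(params)
        n = movie.shape[0]
        c0 = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        r = np.hypot(xx - c0, yy - c0)
        px = params.pixel_size_um
        band = ((r <= params.cell_radius_um / px)
                & (r > (params.cell_radius_um
                        - params.cortex_thickness_um) / px))
        mean_speed = truth.true_flow_fields[0].mean_speed(band)
        assert mean_speed == pytest.approx(
            params.retrograde_speed_um_min, rel=0.01)

    def test_arc_mode_unwrapped_decay(self):
        """Arc-coordinate movies carry an exponential cortical envelope
        in arc length, recoverable by the decay fitter."""
        params = small_params(n_frames=2, noise_sd=0.0,
                              texture_amplitude=0.0,
                              decay_coordinate="arc",
                              actin_decay_length_um=5.0)
        movie, truth = simulate_cell_movie(params)
        n = movie.shape[0]
        c0 = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        r = np.hypot(xx - c0, yy - c0)
        px = params.pixel_size_um
        R = params.cell_radius_um
        band = ((r <= (R - 0.3) / px) & (r > (R - 1.4) / px))
        rel = np.abs(np.angle(np.exp(1j * (
            np.arctan2(yy - c0, xx - c0)
            - np.deg2rad(params.front_direction_deg)))))
        s = (R * rel)[band]
        vals = movie.actin[0][band]
        order = np.argsort(s)
        s_sorted = s[order] + np.arange(len(s)) * 1e-9  # break exact ties
        fit = fit_decay(IntensityProfile(positions_um=s_sorted,
                                         intensities=vals[order]),
                        window=(0.0, float(s.max())))
        assert fit.lam == pytest.approx(5.0, abs=0.05)

    def test_overlapping_blebs_rejected(self):
        sched = (BlebSpec(10.0, 40.0, 2.0, 6.0),
                 BlebSpec(12.0, 50.0, 2.0, 6.0))
        with pytest.raises(ValueError, match="overlapping bleb"):
            simulate_cell_movie(small_params(n_frames=40,
                                             bleb_schedule=sched))

    @pytest.mark.parametrize("field,value", [
        ("cell_radius_um", -1.0), ("noise_sd", -0.1),
        ("actin_decay_length_um", 0.0), ("frame_interval_s", 0.0),
    ])
    def test_invalid_params_rejected(self, field, value):
        with pytest.raises(ValueError):
            simulate_cell_movie(small_params(**{field: value}))

    def test_bleb_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_cell_movie(small_params(
                bleb_schedule=(BlebSpec(1e4, 0.0, 2.0, 6.0),)))


class TestSimulateIntensityProfile:
    def test_closed_form_values(self):
        prof = simulate_intensity_profile(100, 5, 10, 15, 151, 0, 0)
        assert prof.intensities[0] == pytest.approx(110.0)
        i5 = np.argmin(np.abs(prof.positions_um - 5.0))
        assert prof.intensities[i5] == pytest.approx(100 / np.e + 10,
                                                     rel=1e-3)

    def test_flat_limit(self):
        prof = simulate_intensity_profile(100, 1e9, 10, 15, 50, 0, 0)
        assert np.allclose(prof.intensities, 110.0, rtol=1e-6)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_intensity_profile(100, 5, 10, 15, 50, -1.0, 0)

    def test_noisy_recovery_statistics(self):
        """Full-extent fits of 2 %-noise profiles: spread within 10 %,
        median bias below 2 %."""
        lams = []
        for seed in range(100):
            prof = simulate_intensity_profile(100, 5, 10, 15, 150, 2.0,
                                              seed)
            fit = fit_decay(prof, window=(0.0, 15.0))
            assert fit.converged
            lams.append(fit.lam)
        lams = np.array(lams)
        assert abs(np.median(lams) - 5.0) / 5.0 < 0.02
        iqr = np.percentile(lams, 75) - np.percentile(lams, 25)
        assert iqr / 5.0 < 0.10


class TestSimulateTrack:
    def test_straight_when_fully_persistent(self):
        track = simulate_track(3.0, 1.0, 20, 2.0, seed=4)
        speed, straightness = track_metrics(track)
        assert straightness == pytest.approx(1.0)
        steps = np.diff(track.xy_um, axis=0)
        assert np.allclose(np.hypot(steps[:, 0], steps[:, 1]), 6.0)

    def test_uncorrelated_walk_is_tortuous(self):
        vals = [track_metrics(simulate_track(3.0, 0.0, 1000, 1.0, s))[1]
                for s in range(200)]
        assert np.mean(vals) < 0.2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_track(3.0, 0.5, 1, 1.0, 0)


class TestSimulatePerimeterSignals:
    @staticmethod
    def circle_contour():
        from blebflow.segmentation import CellContour

        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = np.column_stack([64 + 35 * np.cos(th),
                               64 + 35 * np.sin(th)])
        return CellContour(points=pts, frame_index=0,
                           centroid=np.array([64.0, 64.0]))

    def test_identical_patterns_unity_ratio(self):
        from blebflow import perimeter_ratio_profile

        cont = self.circle_contour()
        e, m = simulate_perimeter_signals(cont, lambda f: 1.0,
                                          lambda f: 1.0, (128, 128))
        prof = perimeter_ratio_profile(e, m, cont)
        assert np.nanmax(np.abs(prof.ratios - 1.0)) < 1e-9

    def test_scaled_pattern_normalizes_away(self):
        from blebflow import perimeter_ratio_profile

        cont = self.circle_contour()
        e, m = simulate_perimeter_signals(cont, lambda f: 2.0,
                                          lambda f: 1.0, (128, 128))
        prof = perimeter_ratio_profile(e, m, cont)
        assert np.nanmax(np.abs(prof.ratios - 1.0)) < 1e-9

    def test_step_recovered_at_arc_positions(self):
        from blebflow import perimeter_ratio_profile

        cont = self.circle_contour()
        e, m = simulate_perimeter_signals(
            cont, lambda f: 2.0 if 0.25 < f < 0.75 else 1.0,
            lambda f: 1.0, (128, 128))
        prof = perimeter_ratio_profile(e, m, cont)
        # two-level profile with mean 1: levels 1/1.5 and 2/1.5
        lo = np.nanmedian(prof.ratios[:80])
        hi = np.nanmedian(prof.ratios[95:170])
        assert lo == pytest.approx(2 / 3, rel=0.05)
        assert hi == pytest.approx(4 / 3, rel=0.05)

    def test_degenerate_contour_rejected(self):
        from blebflow.segmentation import CellContour

        with pytest.raises(ValueError):
            CellContour(points=np.array([[0, 0], [1, 1]]), frame_index=0,
                        centroid=np.array([0.5, 0.5]))
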