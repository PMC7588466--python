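"""Region advection and projected-velocity measurement contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blebflow import (PolarityAxis, TrackedRegion, VelocityField,
                      advect_region, initialize_front_region,
                      mean_projected_velocity, partition_cortex,
                      polarity_axis)
from blebflow.segmentation import CellContour

PX = 0.286
N = 128
C0 = (N - 1) / 2.0


def uniform_field(vx, vy, t=0.0):
    return VelocityField(vx=np.full((N, N), float(vx)),
                         vy=np.full((N, N), float(vy)),
                         valid=np.ones((N, N), bool), pixel_size=PX,
                         time_s=t)


def scattered_region(n=50, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(30, 98, size=(n, 2))
    return TrackedRegion(points_px=pts, valid=np.ones(n, bool),
                         pixel_size=PX)


def circle_contour(r_um=10.0):
    th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = r_um / PX
    pts = np.column_stack([C0 + r * np.cos(th), C0 + r * np.sin(th)])
    return CellContour(points=pts, frame_index=0,
                       centroid=np.array([C0, C0]), pixel_size=PX)


AXIS = PolarityAxis(p=np.array([-1.0, 0.0]), origin=np.array([C0, C0]))


class TestPolarityAxis:
    def test_two_point_masses_align_with_y(self):
        frame = np.zeros((64, 64))
        mask = np.zeros((64, 64), bool)
        frame[10, 32] = frame[54, 32] = 100.0
        mask[10, 32] = mask[54, 32] = True
        axis = polarity_axis(frame, mask)
        assert abs(axis.p[1]) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_disk_undefined(self):
        from skimage.draw import disk as skdisk

        frame = np.zeros((64, 64))
        frame[skdisk((32, 32), 20)] = 50.0
        mask = frame > 0
        with pytest.raises(ValueError, match="axis undefined"):
            polarity_axis(frame, mask)

    def test_crescent_matches_dense_oracle(self):
        """Crescent at 30 deg: implementation agrees with a direct
        eigen-decomposition of the explicit weighted pixel list."""
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        r = np.hypot(xx - C0, yy - C0)
        ang = np.arctan2(yy - C0, xx - C0)
        rel = np.angle(np.exp(1j * (ang - np.deg2rad(30.0))))
        mask = (r < 40) & (r > 30) & (np.abs(rel) < np.deg2rad(60))
        frame = np.where(mask, 100.0 * np.exp(-np.abs(rel)), 0.0)
        axis = polarity_axis(frame, mask)
        # oracle: weighted covariance of the dense pixel list
        ys, xs = np.nonzero(mask)
        w = frame[ys, xs]
        pos = np.column_stack([xs, ys]).astype(float)
        mu = (w[:, None] * pos).sum(0) / w.sum()
        d = pos - mu
        cov = np.einsum("i,ij,ik->jk", w, d, d) / w.sum()
        evals, evecs = np.linalg.eigh(cov)
        gc = pos.mean(axis=0)
        offset = mu - gc
        if evals[1] / evals[0] >= 1.5:
            e = evecs[:, 1]
            expected = -np.sign(offset @ e) * e if abs(offset @ e) > 1e-6 \
                else e
        else:
            expected = -offset / np.hypot(*offset)
        dot = abs(float(axis.p @ expected))
        assert np.rad2deg(np.arccos(min(dot, 1.0))) < 2.0

    def test_front_band_cell_points_front_to_rear(self, plain_movie):
        params, movie, truth, contours, masks = plain_movie
        axis = polarity_axis(movie.actin[0], masks[0])
        front = np.deg2rad(params.front_direction_deg)
        expected_front = np.array([np.cos(front), np.sin(front)])
        assert float(axis.front_direction @ expected_front) > 0.99


class TestAdvectRegion:
    def test_zero_field_identity(self):
        reg = scattered_region()
        out = advect_region(reg, [uniform_field(0, 0)], 0.0, 10.0)
        assert np.array_equal(out.points_px, reg.points_px)

    def test_constant_field_linear_displacement(self):
        reg = scattered_region()
        out = advect_region(reg, [uniform_field(0.0, -2.0)], 0.0, 10.0)
        disp_um = (out.points_px - reg.points_px) * PX
        assert np.allclose(disp_um[:, 0], 0.0, atol=1e-9)
        assert np.allclose(disp_um[:, 1], -1.0 / 3.0, atol=1e-9)

    def test_rigid_rotation_matches_analytic(self):
        omega = 0.1  # rad/s
        yy, xx = np.mgrid[0:N, 0:N].astype(float)
        vx = -omega * 60.0 * (yy - C0) * PX
        vy = omega * 60.0 * (xx - C0) * PX
        field = VelocityField(vx=vx, vy=vy, valid=np.ones((N, N), bool),
                              pixel_size=PX)
        reg = scattered_region()
        out = advect_region(reg, [field], 0.0, 10.0, substep_s=0.125)
        th = omega * 10.0
        rot = np.column_stack([
            C0 + (reg.points_px[:, 0] - C0) * np.cos(th)
            - (reg.points_px[:, 1] - C0) * np.sin(th),
            C0 + (reg.points_px[:, 0] - C0) * np.sin(th)
            + (reg.points_px[:, 1] - C0) * np.cos(th)])
        err_um = np.max(np.hypot(*(out.points_px - rot).T)) * PX
        assert err_um < 1e-3

    def test_points_leaving_domain_frozen(self):
        field = uniform_field(200.0, 0.0)
        field.valid[:, 100:] = False
        reg = scattered_region()
        out = advect_region(reg, [field], 0.0, 5.0)
        assert not out.valid.all() and out.valid.any()
        frozen = ~out.valid
        assert np.all(out.points_px[frozen, 0] <= 101)

    def test_region_lost_raises(self):
        field = uniform_field(1.0, 0.0)
        field.valid[:] = False
        reg = scattered_region()
        with pytest.raises(ValueError, match="region lost"):
            advect_region(reg, [field], 0.0, 1.0)


class TestPartitionCortex:
    def test_circle_quarters_equal(self):
        part = partition_cortex(circle_contour(), AXIS, n=4,
                                thickness_um=1.7, pixel_size=PX)
        counts = np.array([len(r) for r in part.regions])
        assert counts.max() - counts.min() <= 0.01 * counts.mean() + 1
        assert part.labels == ["front", "centre-front", "centre-back",
                               "back"]

    def test_single_region_is_full_band(self):
        part1 = partition_cortex(circle_contour(), AXIS, n=1,
                                 thickness_um=1.7, pixel_size=PX)
        part4 = partition_cortex(circle_contour(), AXIS, n=4,
                                 thickness_um=1.7, pixel_size=PX)
        assert len(part1.regions[0]) == pytest.approx(
            sum(len(r) for r in part4.regions), rel=0.02)

    def test_thin_band_area_matches_annulus_sector(self):
        thickness = 0.5
        part = partition_cortex(circle_contour(), AXIS, n=4,
                                thickness_um=thickness, pixel_size=PX,
                                spacing_um=0.25)
        area_est = len(part.regions[0]) * 0.25 ** 2
        expected = 2 * np.pi * 10.0 / 4 * thickness
        assert area_est == pytest.approx(expected, rel=0.05)

    def test_excessive_thickness_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="inradius"):
            partition_cortex(circle_contour(), AXIS, n=4,
                             thickness_um=50.0, pixel_size=PX)


class TestInitializeFrontRegion:
    def test_quarter_arc_centred_on_front(self):
        reg = initialize_front_region(circle_contour(), AXIS,
                                      width_um=1.7, arc_fraction=0.25,
                                      pixel_size=PX)
        ang = np.rad2deg(np.arctan2(reg.points_px[:, 1] - C0,
                                    reg.points_px[:, 0] - C0))
        assert ang.min() == pytest.approx(-45.0, abs=3.0)
        assert ang.max() == pytest.approx(45.0, abs=3.0)

    def test_full_fraction_covers_band(self):
        reg = initialize_front_region(circle_contour(), AXIS,
                                      width_um=1.7, arc_fraction=1.0,
                                      pixel_size=PX)
        part = partition_cortex(circle_contour(), AXIS, n=4,
                                thickness_um=1.7, pixel_size=PX)
        union = np.vstack(part.regions)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(reg.points_px).query(union)
        # every partition point has a seed point within one sample cell
        assert (d * PX < 0.5).mean() >= 0.99

    def test_width_clipped_to_mask(self):
        mask = np.zeros((N, N), bool)
        yy, xx = np.mgrid[0:N, 0:N].astype(float)
        mask[np.hypot(xx - C0, yy - C0) <= 10.0 / PX] = True
        reg = initialize_front_region(circle_contour(), AXIS,
                                      width_um=25.0, arc_fraction=0.25,
                                      pixel_size=PX, mask=mask)
        r = np.hypot(reg.points_px[:, 0] - C0, reg.points_px[:, 1] - C0)
        assert np.all(r <= 10.0 / PX + 1.0)


class TestMeanProjectedVelocity:
    AXIS_Y = PolarityAxis(p=np.array([0.0, 1.0]), origin=np.array([C0, C0]))

    def fields(self, vx, vy, ramp=False):
        times = np.arange(0.0, 10.5, 0.5)
        return [uniform_field(vx * (t / 10 if ramp else 1.0),
                              vy * (t / 10 if ramp else 1.0), t=t)
                for t in times]

    def test_constant_aligned_field_exact(self):
        res = mean_projected_velocity(scattered_region(),
                                      self.fields(0.0, 3.7), self.AXIS_Y,
                                      T_bleb=10.0, delta_T=10.0)
        assert res.v_bar_um_min == pytest.approx(3.7, rel=1e-12)
        assert res.v_bar_um_min == pytest.approx(
            res.d_bar_um / (res.delta_T_s / 60.0), rel=1e-12)

    def test_orthogonal_field_zero(self):
        res = mean_projected_velocity(scattered_region(),
                                      self.fields(3.7, 0.0), self.AXIS_Y,
                                      T_bleb=10.0)
        assert res.v_bar_um_min == pytest.approx(0.0, abs=1e-12)

    def test_linear_ramp_halves(self):
        res = mean_projected_velocity(scattered_region(),
                                      self.fields(0.0, 3.0, ramp=True),
                                      self.AXIS_Y, T_bleb=10.0)
        assert res.v_bar_um_min == pytest.approx(1.5, rel=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_linearity_in_field(self, c):
        base = mean_projected_velocity(scattered_region(),
                                       self.fields(1.0, 2.0), self.AXIS_Y,
                                       T_bleb=10.0)
        scaled = mean_projected_velocity(scattered_region(),
                                         self.fields(c, 2.0 * c),
                                         self.AXIS_Y, T_bleb=10.0)
        assert scaled.v_bar_um_min == pytest.approx(
            c * base.v_bar_um_min, rel=1e-6)

    def test_field_reversal_negates(self):
        fwd = mean_projected_velocity(scattered_region(),
                                      self.fields(1.0, 2.0), self.AXIS_Y,
                                      T_bleb=10.0)
        rev = mean_projected_velocity(scattered_region(),
                                      self.fields(-1.0, -2.0),
                                      self.AXIS_Y, T_bleb=10.0)
        assert rev.v_bar_um_min == pytest.approx(-fwd.v_bar_um_min,
                                                 rel=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(vx=st.floats(-5, 5), vy=st.floats(-5, 5),
       dt=st.floats(1.0, 20.0))
def test_constant_field_displacement_property(vx, vy, dt):
    """RK4 through any constant field is exact linear motion."""
    reg = scattered_region(n=10, seed=1)
    out = advect_region(reg, [uniform_field(vx, vy)], 0.0, dt)
    disp_um = (out.points_px - reg.points_px)[out.valid] * PX
    assert np.allclose(disp_um[:, 0], vx * dt / 60.0, atol=1e-9)
    assert np.allclose(disp_um[:, 1], vy * dt / 60.0, atol=1e-9)
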