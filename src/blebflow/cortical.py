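"""Cortical region tracking: polarity axis, leading-edge region seeding,
advection through the velocity field, cortical partitioning, and
time-averaged projected velocities.

The measurement chain: seed a sub-region B0 on the leading edge, advect
it through the estimated velocity field by integrating dx/dt = v(x, t),
and average v·p (p = front-to-rear polarity axis, so retrograde motion is
positive) over the region and over the ΔT = 10 s window preceding a bleb.
The average velocity v̄ equals the total backward displacement d̄ divided
by ΔT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (cumulative_arclength, outward_normals,
                       polygon_centroid, resample_closed_polyline)


@dataclass
class PolarityAxis:
    """Unit front-to-rear polarity vector with its origin (px)."""

    p: np.ndarray
    origin: np.ndarray
    frame_index: int = 0
    anisotropy: float = np.nan
    skew_px: float = np.nan

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        norm = np.hypot(*self.p)
        if not np.isclose(norm, 1.0, atol=1e-9):
            self.p = self.p / norm
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def front_direction(self) -> np.ndarray:
        """Unit vector pointing toward the cell front (−p)."""
        return -self.p


@dataclass
class TrackedRegion:
    """Dense point-sample representation of an advected sub-region.

    Spatial means over the valid points stand in for the area integrals
    of the projected-velocity measure; accuracy is controlled by the
    sampling density (default 1 point per 0.25 µm²).
    """

    points_px: np.ndarray
    valid: np.ndarray
    pixel_size: float
    time_s: float = 0.0
    seed_width_um: float | None = None
    seed_arc_fraction: float | None = None

    def __post_init__(self) -> None:
        self.points_px = np.asarray(self.points_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.points_px) != len(self.valid):
            raise ValueError("points and validity flags must match")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean())


@dataclass
class CorticalPartition:
    """n equal-arc cortical regions of fixed inward thickness.

    ``regions[i]`` is an (Ni, 2) point array; region 0 is centred on the
    front point.  For n = 4 the labels follow the conventional
    front / centre-front / centre-back / back naming around the
    perimeter.
    """

    regions: list[np.ndarray]
    labels: list[str]
    thickness_um: float
    pixel_size: float

    def as_tracked_regions(self, time_s: float = 0.0) -> list[TrackedRegion]:
        return [TrackedRegion(points_px=r, valid=np.ones(len(r), dtype=bool),
                              pixel_size=self.pixel_size, time_s=time_s)
                for r in self.regions]


def polarity_axis(actin_frame: np.ndarray, mask,
                  min_anisotropy: float = 1.05,
                  skew_tol_px: float = 0.5,
                  frame_index: int = 0) -> PolarityAxis:
    """Front-rear axis from intensity-weighted principal component
    analysis of the masked pixel positions.

    Between the two covariance eigenvectors, the axis is the one along
    which the intensity distribution is asymmetric (largest displacement
    of the intensity-weighted centroid from the geometric centroid) —
    for round cells with a front-enriched cortical band the *minor*
    eigenvector carries the polarity while the major one reflects the
    tangential spread of the band.  When no significant asymmetry exists
    the principal eigenvector is used; when the distribution is also
    isotropic the axis is undefined.  The sign makes p point from the
    high-intensity (front) side toward the low-intensity side.
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask_arr.any():
        raise ValueError("empty mask")
    frame = np.asarray(actin_frame, dtype=float)
    ys, xs = np.nonzero(mask_arr)
    w = np.clip(frame[ys, xs], 0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("total masked intensity must be > 0")
    pos = np.column_stack([xs, ys]).astype(float)
    wc = (w[:, None] * pos).sum(axis=0) / total
    gc = pos.mean(axis=0)
    d = pos - wc
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    cov /= total
    evals, evecs = np.linalg.eigh(cov)
    ratio = evals[1] / max(evals[0], 1e-12)
    offset = wc - gc
    skew = float(np.hypot(*offset))
    strong_anisotropy = 1.5
    if ratio >= strong_anisotropy:
        # clearly elongated distribution: the shape axis carries the
        # polarity; orient it by the intensity asymmetry when present
        e = evecs[:, 1]
        s = float(offset @ e)
        if abs(s) >= 1e-6:
            p = -np.sign(s) * e
        else:
            p = e if (e[0] > 0 or (e[0] == 0 and e[1] > 0)) else -e
    elif skew >= skew_tol_px:
        # round cell: the eigenvector basis is noise-dominated, but the
        # displacement of the intensity-weighted centroid from the
        # geometric centroid points squarely at the enriched front
        p = -offset / skew
    elif ratio >= min_anisotropy:
        e = evecs[:, 1]
        p = e if (e[0] > 0 or (e[0] == 0 and e[1] > 0)) else -e
    else:
        raise ValueError("axis undefined: isotropic intensity distribution")
    return PolarityAxis(p=p, origin=gc, frame_index=frame_index,
                        anisotropy=float(ratio), skew_px=skew)


def front_point_index(points: np.ndarray, axis: PolarityAxis) -> int:
    """Index of the contour point where the front direction (−p) from the
    centroid intersects the contour."""
    c = polygon_centroid(points)
    d = points - c
    d = d / np.maximum(np.hypot(d[:, 0], d[:, 1]), 1e-12)[:, None]
    return int(np.argmax(d @ axis.front_direction))


def _band_samples(contour, width_um: float, pixel_size: float,
                  spacing_um: float = 0.5, arc_multiple: int = 1
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """Regular point samples of the inward cortical band.

    Returns (points_px (N,2), arc position of each point in µm measured
    from the first contour vertex, perimeter in µm).  ``arc_multiple``
    rounds the number of arc samples to a multiple (so equal-arc
    partitions receive equal sample counts).
    """
    pts = np.asarray(contour.points, dtype=float)
    perimeter_um = cumulative_arclength(pts)[-1] * pixel_size
    n_arc = max(int(round(perimeter_um / spacing_um)), 16)
    n_arc = arc_multiple * max(int(round(n_arc / arc_multiple)), 1)
    ring = resample_closed_polyline(pts, n_arc)
    normals = outward_normals(ring)
    n_depth = max(int(round(width_um / spacing_um)), 1)
    depths_px = ((np.arange(n_depth) + 0.5) * (width_um / n_depth)
                 / pixel_size)
    samples = (ring[None, :, :]
               - depths_px[:, None, None] * normals[None, :, :])
    arc = np.tile(np.arange(n_arc) * (perimeter_um / n_arc), n_depth)
    return samples.reshape(-1, 2), arc, perimeter_um


def initialize_front_region(contour, axis: PolarityAxis, width_um: float,
                            arc_fraction: float, pixel_size: float,
                            spacing_um: float = 0.5, mask=None,
                            time_s: float = 0.0) -> TrackedRegion:
    """Seed the leading-edge region B0: an inward band of depth
    ``width_um`` spanning ``arc_fraction`` of the perimeter, centred on
    the front intersection of −p with the contour.  Points outside the
    cell mask (if given) are clipped."""
    if width_um <= 0:
        raise ValueError("width must be > 0")
    if not 0 < arc_fraction <= 1:
        raise ValueError("arc_fraction must be in (0, 1]")
    pts_all, arc, perimeter = _band_samples(contour, width_um, pixel_size,
                                            spacing_um)
    ring = resample_closed_polyline(np.asarray(contour.points, float),
                                    max(int(round(perimeter / spacing_um)),
                                        16))
    front_idx = front_point_index(ring, axis)
    s_front = front_idx * (perimeter / len(ring))
    s_rel = np.mod(arc - s_front + perimeter / 2, perimeter) - perimeter / 2
    # each sample represents a spacing-wide arc cell; include cells
    # overlapping the window
    keep = np.abs(s_rel) <= arc_fraction * perimeter / 2 + spacing_um / 2
    pts = pts_all[keep]
    if mask is not None:
        mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
        inside = ndimage.map_coordinates(
            mask_arr.astype(float), np.stack([pts[:, 1], pts[:, 0]]),
            order=0, mode="constant", cval=0.0) > 0.5
        pts = pts[inside]
    if len(pts) == 0:
        raise ValueError("empty seed region")
    return TrackedRegion(points_px=pts, valid=np.ones(len(pts), dtype=bool),
                         pixel_size=pixel_size, time_s=time_s,
                         seed_width_um=width_um,
                         seed_arc_fraction=arc_fraction)


def partition_cortex(contour, axis: PolarityAxis, n: int = 4,
                     thickness_um: float = 1.7,
                     pixel_size: float = 1.0, spacing_um: float = 0.5,
                     mask=None) -> CorticalPartition:
    """Split the cortical band into n equal-arc regions, region 0 centred
    on the front point."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if thickness_um <= 0:
        raise ValueError("thickness must be > 0")
    pts = np.asarray(contour.points, dtype=float)
    c = polygon_centroid(pts)
    inradius_um = float(np.min(np.hypot(*(pts - c).T))) * pixel_size
    if thickness_um > inradius_um:
        warnings.warn("cortex thickness exceeds the inradius; band clipped",
                      stacklevel=2)
        thickness_um = inradius_um
    samples, arc, perimeter = _band_samples(contour, thickness_um,
                                            pixel_size, spacing_um,
                                            arc_multiple=2 * n)
    ring = resample_closed_polyline(pts, max(int(round(perimeter
                                                       / spacing_um)), 16))
    s_front = front_point_index(ring, axis) * (perimeter / len(ring))
    s_rel = np.mod(arc - s_front + perimeter / (2 * n), perimeter)
    region_idx = np.minimum((s_rel / (perimeter / n)).astype(int), n - 1)
    if mask is not None:
        mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
        inside = ndimage.map_coordinates(
            mask_arr.astype(float),
            np.stack([samples[:, 1], samples[:, 0]]),
            order=0, mode="constant", cval=0.0) > 0.5
        samples, region_idx = samples[inside], region_idx[inside]
    regions = [samples[region_idx == i] for i in range(n)]
    if n == 4:
        labels = ["front", "centre-front", "centre-back", "back"]
    else:
        labels = [f"region_{i + 1}" for i in range(n)]
    return CorticalPartition(regions=regions, labels=labels,
                             thickness_um=thickness_um,
                             pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# advection


def _field_at(fields, t: float):
    """Pair of (field, weight) for linear interpolation in time, with the
    end fields held constant outside the covered span."""
    if len(fields) == 1:
        return fields[0], fields[0], 0.0
    times = np.array([f.time_s for f in fields])
    if t <= times[0]:
        return fields[0], fields[0], 0.0
    if t >= times[-1]:
        return fields[-1], fields[-1], 0.0
    j = int(np.searchsorted(times, t, side="right"))
    w = (t - times[j - 1]) / (times[j] - times[j - 1])
    return fields[j - 1], fields[j], float(w)


def _sample_velocity(fields, pts_px: np.ndarray, t: float, pixel_size: float
                     ) -> np.ndarray:
    """Velocity (px/s) at points, bilinear in space, linear in time."""
    fa, fb, w = _field_at(fields, t)
    coords = np.stack([pts_px[:, 1], pts_px[:, 0]])
    vx = ndimage.map_coordinates(fa.vx, coords, order=1, mode="nearest")
    vy = ndimage.map_coordinates(fa.vy, coords, order=1, mode="nearest")
    if w > 0:
        vx = (1 - w) * vx + w * ndimage.map_coordinates(
            fb.vx, coords, order=1, mode="nearest")
        vy = (1 - w) * vy + w * ndimage.map_coordinates(
            fb.vy, coords, order=1, mode="nearest")
    return np.column_stack([vx, vy]) / (pixel_size * 60.0)


def _inside_valid(fields, pts_px: np.ndarray, t: float) -> np.ndarray:
    fa, _, _ = _field_at(fields, t)
    coords = np.stack([pts_px[:, 1], pts_px[:, 0]])
    return ndimage.map_coordinates(fa.valid.astype(float), coords, order=0,
                                   mode="constant", cval=0.0) > 0.5


def advect_region(region: TrackedRegion, fields, t0: float, t1: float,
                  substep_s: float | None = None) -> TrackedRegion:
    """Integrate the region's sample points through dx/dt = v(x, t) from
    t0 to t1 by RK4 with sub-stepping.

    Points that leave the field's valid domain are frozen in place and
    flagged invalid.  Raises ValueError("region lost") when no point
    survives.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("no velocity fields supplied")
    if substep_s is None:
        if len(fields) > 1:
            dt_f = np.diff([f.time_s for f in fields]).min()
            substep_s = dt_f / 4.0
        else:
            substep_s = max((t1 - t0) / 16.0, 1e-6)
    pts = region.points_px.copy()
    valid = region.valid.copy()
    n_steps = max(int(np.ceil((t1 - t0) / substep_s)), 1)
    h = (t1 - t0) / n_steps
    px = region.pixel_size
    for k in range(n_steps):
        t = t0 + k * h
        act = valid.copy()
        if not act.any():
            break
        p = pts[act]
        k1 = _sample_velocity(fields, p, t, px)
        k2 = _sample_velocity(fields, p + 0.5 * h * k1, t + 0.5 * h, px)
        k3 = _sample_velocity(fields, p + 0.5 * h * k2, t + 0.5 * h, px)
        k4 = _sample_velocity(fields, p + h * k3, t + h, px)
        new = p + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        inside = _inside_valid(fields, new, t + h)
        moved = pts[act]
        moved[inside] = new[inside]
        pts[act] = moved
        idx = np.nonzero(act)[0]
        valid[idx[~inside]] = False
    if not valid.any():
        raise ValueError("region lost: every point left the flow domain")
    return TrackedRegion(points_px=pts, valid=valid,
                         pixel_size=region.pixel_size, time_s=t1,
                         seed_width_um=region.seed_width_um,
                         seed_arc_fraction=region.seed_arc_fraction)


@dataclass
class ProjectedFlowResult:
    """Time-averaged projected velocity of an advected region.

    v̄ (µm/min) equals d̄ (µm) divided by ΔT expressed in minutes;
    rearward (retrograde) motion is positive because p points front to
    rear.
    """

    v_bar_um_min: float
    d_bar_um: float
    delta_T_s: float
    T_bleb_s: float
    region_label: str = ""
    valid_fraction: float = 1.0
    partial: bool = False


def mean_projected_velocity(region: TrackedRegion, fields,
                            axis: PolarityAxis, T_bleb: float,
                            delta_T: float = 10.0,
                            region_label: str = "",
                            substep_s: float | None = None
                            ) -> ProjectedFlowResult:
    """Average v·p over the advected region and the ΔT window before the
    bleb, time-integrated with the composite trapezoidal rule.

    The region is advected from t0 = T_bleb − ΔT; at every sample time
    the spatial mean of the projected velocity over the currently valid
    points (the |B(t)|⁻¹-normalized area integral) is recorded, and the
    trapezoidal integral over the window divided by ΔT gives v̄.
    """
    fields = list(fields)
    t0 = T_bleb - delta_T
    times = sorted({f.time_s for f in fields if t0 < f.time_s < T_bleb}
                   | {t0, T_bleb})
    means = []
    partial = False
    current = region
    p = axis.p
    for i, t in enumerate(times):
        if i > 0:
            try:
                current = advect_region(current, fields, times[i - 1], t,
                                        substep_s=substep_s)
            except ValueError:
                partial = True
                break
        pts = current.points_px[current.valid]
        v = _sample_velocity(fields, pts, t, current.pixel_size)
        v_um_min = v * (current.pixel_size * 60.0)
        means.append(float(np.mean(v_um_min @ p)))
    used_times = np.array(times[:len(means)])
    if len(means) < 2:
        raise ValueError("region lost: projection window empty")
    v_bar = float(np.trapezoid(np.array(means), used_times)
                  / (used_times[-1] - used_times[0]))
    d_bar = v_bar * delta_T / 60.0
    return ProjectedFlowResult(v_bar_um_min=v_bar, d_bar_um=d_bar,
                               delta_T_s=delta_T, T_bleb_s=T_bleb,
                               region_label=region_label,
                               valid_fraction=current.valid_fraction,
                               partial=partial)
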