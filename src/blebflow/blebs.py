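"""Bleb detection and angular-coordination statistics.

Blebs are detected as local maxima of the centre-of-mass velocity of the
segmented cell; the angle of each event relative to the (temporally
smoothed) actin front is the angle of the contour point with the maximal
outward edge velocity at that time point, folded to [0°, 180°]
(0° = front, 180° = rear).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .geometry import fold_angle_deg, outward_normals, wrap_angle_deg
from .segmentation import CellContour


@dataclass
class BlebEvent:
    """One detected protrusion event."""

    time_s: float
    frame_index: int
    perimeter_angle_deg: float  # [0, 180] relative to the smoothed front
    initiation_point_px: np.ndarray
    centroid_speed_peak_um_min: float
    absolute_angle_deg: float = np.nan  # image-frame angle about centroid

    def __post_init__(self) -> None:
        if not 0.0 <= self.perimeter_angle_deg <= 180.0:
            raise ValueError("perimeter angle must be in [0, 180] deg")


@dataclass
class FrontAngleSeries:
    """Per-frame front angle (deg, [0, 360), image frame) after circular
    Gaussian smoothing over time."""

    angles_deg: np.ndarray
    frame_interval_s: float
    sigma_s: float = 25.0
    flags: np.ndarray | None = None

    def at_frame(self, f: int) -> float:
        return float(self.angles_deg[f])


@dataclass
class BlebStats:
    """Aggregate bleb statistics of one movie."""

    frequency_per_min: float
    consecutive_angles_deg: np.ndarray
    histogram_bin_edges_deg: np.ndarray | None = None
    histogram_counts: np.ndarray | None = None
    histogram_actin: np.ndarray | None = None


def angular_intensity_distribution(actin_frame: np.ndarray, mask,
                                   centroid, n_bins: int = 360,
                                   band_px: float | None = None,
                                   reduce: str = "sum",
                                   subsample: int = 3
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Angularly integrated masked intensity about the centroid.

    Returns (bin centre angles deg in [0, 360), per-bin intensity).
    ``band_px`` restricts the integration to a perimeter band of that
    thickness (pixels whose distance from the mask edge is below
    ``band_px``); None integrates the whole masked area.  ``reduce``
    selects the per-sector statistic: "sum" (angular integral) or
    "mean", which cancels the sector-to-sector pixel-count variation of
    the raster.  Empty sectors yield 0.
    """
    from scipy import ndimage

    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    frame = np.asarray(actin_frame, dtype=float)
    cx, cy = np.asarray(centroid, dtype=float)
    if not mask_arr[int(round(cy)), int(round(cx))]:
        raise ValueError("centroid must lie inside the mask")
    sel = mask_arr
    if band_px is not None:
        dist = ndimage.distance_transform_edt(mask_arr)
        sel = mask_arr & (dist <= band_px)
    ys, xs = np.nonzero(sel)
    vals = frame[ys, xs]
    # subdivide pixels so sector boundaries cut through pixels instead
    # of swallowing them whole (anti-aliased angular binning)
    s = max(int(subsample), 1)
    offs = (np.arange(s) + 0.5) / s - 0.5
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    sub_y = (ys[:, None] + oy.ravel()[None, :]).ravel()
    sub_x = (xs[:, None] + ox.ravel()[None, :]).ravel()
    sub_v = np.repeat(vals, s * s) / (s * s)
    ang = wrap_angle_deg(np.rad2deg(np.arctan2(sub_y - cy, sub_x - cx)))
    idx = np.minimum((ang / 360.0 * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=sub_v, minlength=n_bins)
    if reduce == "mean":
        counts = np.bincount(idx, minlength=n_bins) / (s * s)
        sums = np.where(counts > 0, sums / np.maximum(counts, 1e-12), 0.0)
    elif reduce != "sum":
        raise ValueError(f"unknown reduce {reduce!r}")
    centres = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    return centres, sums


def front_angle_series(actin_frames: np.ndarray, masks, centroids,
                       frame_interval_s: float, sigma_s: float = 25.0,
                       n_bins: int = 360,
                       angular_sigma_deg: float = 10.0,
                       band_px: float | None = 3.0
                       ) -> FrontAngleSeries:
    """Front angle per frame: argmax of the angular actin distribution,
    smoothed over time with a circular-safe Gaussian (applied to the unit
    vectors (cos θ, sin θ), then renormalized).

    The per-frame distribution uses sector means over a thin perimeter
    band (raster count variation cancelled) smoothed circularly over
    ``angular_sigma_deg`` so that speckle does not masquerade as the
    front; ``band_px=None`` integrates the whole cell area instead.
    Frames with a (near-)uniform distribution carry the previous angle
    and are flagged.
    """
    n = len(actin_frames)
    raw = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    sigma_bins = angular_sigma_deg / (360.0 / n_bins)
    prev = 0.0
    for f in range(n):
        centres, dist = angular_intensity_distribution(
            actin_frames[f], masks[f], centroids[f], n_bins=n_bins,
            band_px=band_px, reduce="mean")
        if sigma_bins > 0:
            dist = gaussian_filter1d(dist, sigma_bins, mode="wrap")
        if dist.max() <= 0 or (dist.std() < 1e-9 * max(dist.mean(), 1e-12)):
            raw[f] = prev
            flags[f] = True
        else:
            raw[f] = centres[int(np.argmax(dist))]
            prev = raw[f]
    sigma_frames = sigma_s / frame_interval_s
    rad = np.deg2rad(raw)
    c = gaussian_filter1d(np.cos(rad), sigma_frames, mode="nearest")
    s = gaussian_filter1d(np.sin(rad), sigma_frames, mode="nearest")
    smooth = wrap_angle_deg(np.rad2deg(np.arctan2(s, c)))
    return FrontAngleSeries(angles_deg=smooth,
                            frame_interval_s=frame_interval_s,
                            sigma_s=sigma_s, flags=flags)


def centroid_velocity_series(contours: list[CellContour],
                             frame_interval_s: float, pixel_size: float,
                             drift_correction: bool = False) -> np.ndarray:
    """Centre-of-mass speed (µm/min) between consecutive frames; entry k
    is the speed over the step k-1 -> k (entry 0 is 0)."""
    from .geometry import polygon_centroid

    cents = np.array([polygon_centroid(c.points) for c in contours])
    disp = np.diff(cents, axis=0)
    if drift_correction:
        disp = disp - disp.mean(axis=0, keepdims=True)
    speed = np.hypot(disp[:, 0], disp[:, 1]) * pixel_size \
        / frame_interval_s * 60.0
    return np.concatenate([[0.0], speed])


def _edge_velocity(prev: CellContour, curr: CellContour
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-point outward edge displacement (px) from prev to curr.

    Both contours must be resampled to the same point count; each current
    point is matched to its nearest predecessor point and the
    displacement is projected on the current outward normal.
    Returns (outward displacement per point, current points).
    """
    a = np.asarray(prev.points, dtype=float)
    b = np.asarray(curr.points, dtype=float)
    tree = cKDTree(a)
    _, idx = tree.query(b)
    disp = b - a[idx]
    normals = outward_normals(b)
    return np.sum(disp * normals, axis=1), b


def detect_blebs(contours: list[CellContour], front: FrontAngleSeries,
                 frame_interval_s: float, pixel_size: float,
                 prominence_k: float = 3.0, min_separation_s: float = 2.0,
                 min_prominence_um_min: float = 2.0,
                 n_resample: int = 360,
                 drift_correction: bool = False) -> list[BlebEvent]:
    """Detect bleb events from per-frame contours.

    Local maxima of the centre-of-mass speed with prominence above
    max(prominence_k · 1.4826 · MAD, min_prominence_um_min) and mutual
    separation of at least ``min_separation_s`` are events.  Per event
    the initiation point is the contour point with maximal outward edge
    velocity; its angle about the centroid, measured relative to the
    smoothed front and folded to [0°, 180°], is the event angle.
    An empty list (no maxima above threshold) is a valid outcome.
    """
    if len(contours) < 10:
        raise ValueError("need >= 10 frames")
    from .geometry import polygon_centroid
    from .segmentation import resample_contour

    res = [resample_contour(c, n_resample) for c in contours]
    speed = centroid_velocity_series(res, frame_interval_s, pixel_size,
                                     drift_correction=drift_correction)
    med = np.median(speed)
    mad = np.median(np.abs(speed - med)) * 1.4826
    prominence = max(prominence_k * mad, min_prominence_um_min)
    distance = max(int(round(min_separation_s / frame_interval_s)), 1)
    peaks, _ = find_peaks(speed, prominence=prominence, distance=distance)
    events: list[BlebEvent] = []
    for f in peaks:
        out, pts = _edge_velocity(res[f - 1], res[f])
        # a bleb is an outward protrusion: centroid-speed maxima whose
        # dominant edge motion is inward are retraction recoils, not
        # initiation events
        if out.max() <= np.abs(out.min()):
            continue
        i_max = int(np.argmax(out))
        cent = polygon_centroid(pts)
        d = pts[i_max] - cent
        abs_angle = wrap_angle_deg(np.rad2deg(np.arctan2(d[1], d[0])))
        rel = fold_angle_deg(abs_angle - front.at_frame(f))
        # speed[f] measures the step f-1 -> f, so the event time is the
        # midpoint of that interval
        events.append(BlebEvent(
            time_s=(f - 0.5) * frame_interval_s, frame_index=f,
            perimeter_angle_deg=float(rel),
            initiation_point_px=pts[i_max].copy(),
            centroid_speed_peak_um_min=float(speed[f]),
            absolute_angle_deg=float(abs_angle)))
    return events


def consecutive_bleb_angles(events: list[BlebEvent],
                            contours: list[CellContour] | None = None
                            ) -> np.ndarray:
    """Unsigned angle (deg, [0, 180]) between the centre-to-initiation
    lines of each consecutive event pair; centres are taken from each
    event's own frame."""
    if len(events) < 2:
        raise ValueError("need >= 2 events")
    from .geometry import polygon_centroid

    out = []
    for a, b in zip(events, events[1:]):
        if a.initiation_point_px is None or b.initiation_point_px is None:
            warnings.warn("missing initiation point; pair skipped",
                          stacklevel=2)
            continue
        if contours is not None:
            ca = polygon_centroid(contours[a.frame_index].points)
            cb = polygon_centroid(contours[b.frame_index].points)
        else:
            ca = cb = np.array([0.0, 0.0])
        va = a.initiation_point_px - ca
        vb = b.initiation_point_px - cb
        ang_a = np.rad2deg(np.arctan2(va[1], va[0]))
        ang_b = np.rad2deg(np.arctan2(vb[1], vb[0]))
        out.append(fold_angle_deg(ang_b - ang_a))
    return np.asarray(out, dtype=float)


def bleb_frequency(events: list[BlebEvent], duration_s: float) -> float:
    """Blebs per minute over an observation window of ``duration_s``."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return len(events) / (duration_s / 60.0)


def bleb_angle_histogram(events: list[BlebEvent],
                         actin_distribution: tuple[np.ndarray, np.ndarray]
                         | None = None,
                         bin_width_deg: float = 20.0) -> BlebStats:
    """Histogram of event angles folded to [0°, 180°], optionally paired
    with the mean normalized actin intensity per angular bin.

    ``actin_distribution`` is (angles deg relative to front in [0, 180],
    intensities); intensities are averaged within each bin and normalized
    to unit mean.
    """
    if not np.isclose(180.0 / bin_width_deg, round(180.0 / bin_width_deg)):
        raise ValueError("bin width must divide 180 degrees")
    n_bins = int(round(180.0 / bin_width_deg))
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    angles = np.array([e.perimeter_angle_deg for e in events])
    counts, _ = np.histogram(angles, bins=edges)
    actin_binned = None
    if actin_distribution is not None:
        a_ang, a_int = actin_distribution
        idx = np.clip(np.digitize(a_ang, edges) - 1, 0, n_bins - 1)
        sums = np.bincount(idx, weights=a_int, minlength=n_bins)
        ns = np.bincount(idx, minlength=n_bins)
        actin_binned = np.where(ns > 0, sums / np.maximum(ns, 1), 0.0)
        if actin_binned.mean() > 0:
            actin_binned = actin_binned / actin_binned.mean()
    if len(events):
        times = np.array([e.time_s for e in events])
        duration = max(times.max() - times.min(), 1e-9)
        freq = bleb_frequency(events, duration) if duration > 0 else 0.0
    else:
        freq = 0.0
    cons = (consecutive_bleb_angles(events) if len(events) >= 2
            else np.array([]))
    return BlebStats(frequency_per_min=freq, consecutive_angles_deg=cons,
                     histogram_bin_edges_deg=edges,
                     histogram_counts=counts, histogram_actin=actin_binned)
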