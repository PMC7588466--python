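"""Front-rear polarity metrics: intensity profiles along the polarity
axis, the F/M five-sector ratio, perimeter marker/membrane ratio
profiles, and migration-track statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import resample_closed_polyline


@dataclass
class IntensityProfile:
    """1D intensity profile along the front-rear axis (front at 0 µm)."""

    positions_um: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.shape != self.intensities.shape:
            raise ValueError("positions and intensities must match")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def normalized_50(self) -> np.ndarray:
        """Length-normalized 50-bin copy with unit mean (the classic
        '50 segments' representation of a front-rear profile)."""
        x = self.positions_um
        edges = np.linspace(x[0], x[-1], 51)
        idx = np.clip(np.digitize(x, edges) - 1, 0, 49)
        sums = np.bincount(idx, weights=self.intensities, minlength=50)
        counts = np.bincount(idx, minlength=50)
        filled = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        # linear fill of empty bins from neighbours
        if np.any(np.isnan(filled)):
            good = ~np.isnan(filled)
            filled = np.interp(np.arange(50), np.nonzero(good)[0],
                               filled[good])
        mean = filled.mean()
        return filled / mean if mean > 0 else filled


@dataclass
class PerimeterProfile:
    """Ratio profile along the cell outline, arc position normalized to
    [0, 1) starting at the leading edge, mean-normalized to 1."""

    arc_positions: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        valid = np.isfinite(self.ratios)
        mean = self.ratios[valid].mean()
        if not np.isclose(mean, 1.0, atol=1e-6):
            raise ValueError("profile must be mean-normalized to 1")


@dataclass
class Track:
    """Time-ordered migration track: times in minutes, positions in µm."""

    t_min: np.ndarray
    xy_um: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if len(self.t_min) < 2:
            raise ValueError("track needs >= 2 points")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("track times must be strictly increasing")


def front_rear_profile(actin_frame: np.ndarray, mask, axis,
                       pixel_size: float,
                       threshold: float | str | None = None,
                       band_um: float | None = None,
                       statistic: str = "mean") -> IntensityProfile:
    """Average masked intensity in 1 px slabs perpendicular to the
    polarity axis, positions measured from the frontmost slab.

    ``statistic`` selects the per-slab reducer: "mean" (the classic
    per-row average) or "median", which is robust against the few
    boundary pixels per slab that straddle the cortex edges.

    ``threshold`` excludes dim (cytosolic) pixels from the slab averages
    so the profile reflects the cortical signal: "otsu" applies an Otsu
    cut on the masked intensities, a float is an absolute cut, None keeps
    everything.  Excluded pixels are treated as intensity 0 and dropped.
    ``band_um`` restricts the profile to the cortical band (pixels within
    that distance of the mask edge), the standard choice when fitting the
    transport-decay model to the cortical signal.
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask_arr.any():
        raise ValueError("empty mask")
    frame = np.asarray(actin_frame, dtype=float)
    if band_um is not None:
        dist = ndimage.distance_transform_edt(mask_arr)
        # one-pixel inset guards against rasterization spillover of the
        # mask boundary contaminating the band with background pixels
        mask_arr = mask_arr & (dist > 1.0) & (dist <= band_um / pixel_size)
    ys, xs = np.nonzero(mask_arr)
    vals = frame[ys, xs]
    if threshold == "otsu":
        level = threshold_otsu(vals)
    elif threshold is None:
        level = -np.inf
    else:
        level = float(threshold)
    keep = vals > level
    if not keep.any():
        raise ValueError("threshold removed every masked pixel")
    # coordinate along p (front -> rear): front pixels have the smallest t
    t = xs[keep] * axis.p[0] + ys[keep] * axis.p[1]
    t = t - t.min()
    slab = np.floor(t).astype(int)
    counts = np.bincount(slab)
    nonempty = counts > 0
    if statistic == "mean":
        sums = np.bincount(slab, weights=vals[keep])
        stats = sums[nonempty] / counts[nonempty]
    elif statistic == "median":
        order = np.argsort(slab, kind="stable")
        splits = np.split(vals[keep][order],
                          np.cumsum(counts[nonempty])[:-1])
        stats = np.array([np.median(s) for s in splits])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    # each slab is positioned at the mean axial coordinate of its own
    # pixels (not the nominal bin centre), which keeps the profile
    # faithful when pixels fill a slab unevenly
    pos_sums = np.bincount(slab, weights=t)
    positions = pos_sums[nonempty] / counts[nonempty] * pixel_size
    return IntensityProfile(positions_um=positions - positions[0],
                            intensities=np.clip(stats, 0, None))


def fm_ratio(actin_frame: np.ndarray, mask, axis) -> float:
    """Front/middle polarity index.

    The masked extent along the polarity axis is split into five
    equal-length sectors (1 = front ... 5 = rear); returns
    mean(sector 1) / mean(sector 3).
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask_arr.any():
        raise ValueError("empty mask")
    frame = np.asarray(actin_frame, dtype=float)
    ys, xs = np.nonzero(mask_arr)
    t = xs * axis.p[0] + ys * axis.p[1]
    length = t.max() - t.min()
    if length < 5:
        raise ValueError("cell extent along axis below 5 px")
    sector = np.clip(((t - t.min()) / length * 5).astype(int), 0, 4)
    vals = frame[ys, xs]
    m_front = vals[sector == 0].mean()
    m_mid = vals[sector == 2].mean()
    if m_mid == 0:
        raise ValueError("undefined ratio: middle sector mean is 0")
    return float(m_front / m_mid)


def perimeter_ratio_profile(ecad_frame: np.ndarray, mem_frame: np.ndarray,
                            contour, axis=None, n_samples: int = 360
                            ) -> PerimeterProfile:
    """Pointwise marker/membrane ratio along the contour, normalized to
    mean 1; arc position 0 is the leading edge (intersection of the
    front direction −p with the contour) when an axis is given, else the
    first contour vertex.  Samples with non-positive membrane signal are
    masked (NaN); warns when more than 10 % are masked.
    """
    ecad = np.asarray(ecad_frame, dtype=float)
    mem = np.asarray(mem_frame, dtype=float)
    if ecad.shape != mem.shape:
        raise ValueError("frames must share geometry")
    pts = resample_closed_polyline(contour.points, n_samples)
    if axis is not None:
        from .cortical import front_point_index
        start = front_point_index(pts, axis)
        pts = np.roll(pts, -start, axis=0)
    coords = np.stack([pts[:, 1], pts[:, 0]])
    e = ndimage.map_coordinates(ecad, coords, order=1, mode="nearest")
    m = ndimage.map_coordinates(mem, coords, order=1, mode="nearest")
    ratio = np.where(m > 0, e / np.where(m > 0, m, 1.0), np.nan)
    n_masked = int(np.sum(~np.isfinite(ratio)))
    if n_masked > 0.1 * n_samples:
        warnings.warn(f"{n_masked}/{n_samples} perimeter samples have "
                      "non-positive membrane signal", stacklevel=2)
    valid = np.isfinite(ratio)
    if not valid.any():
        raise ValueError("membrane signal non-positive everywhere on path")
    ratio = ratio / ratio[valid].mean()
    return PerimeterProfile(arc_positions=np.arange(n_samples) / n_samples,
                            ratios=ratio)


def track_metrics(track: Track) -> tuple[float, float]:
    """(speed µm/min, straightness) of a migration track.

    speed = total path length / elapsed time; straightness = net
    displacement / path length, in [0, 1] (1 for collinear monotone
    motion).
    """
    dt = track.t_min[-1] - track.t_min[0]
    if dt <= 0:
        raise ValueError("zero elapsed time")
    steps = np.diff(track.xy_um, axis=0)
    path = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    net = float(np.hypot(*(track.xy_um[-1] - track.xy_um[0])))
    speed = path / dt
    straightness = net / path if path > 0 else 1.0
    return speed, min(straightness, 1.0)


def subtract_constant_drift(track: Track, drift_um_min: np.ndarray) -> Track:
    """Remove a constant drift velocity (µm/min, 2-vector) from a track.

    Helper for tissue-drift-contaminated tracks; synthetic tracks are
    drift-free so this is untested against real drift fields.
    """
    drift = np.asarray(drift_um_min, dtype=float)
    t = (track.t_min - track.t_min[0])[:, None]
    return Track(t_min=track.t_min, xy_um=track.xy_um - t * drift)
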