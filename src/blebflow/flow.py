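"""Dense intracellular velocimetry and kymograph analysis.

``estimate_flow`` wraps a variational optical-flow solver (TV-L1) behind a
calibrated contract: input two frames plus the cell mask, output a
:class:`VelocityField` in µm/min valid only inside the mask.  A
``ground_truth`` backend passes an injected field through verbatim so the
downstream advection/projection stages can be tested independently of
flow accuracy.

Kymograph velocimetry follows the classic manual procedure: reslice the
movie along a line of configurable width, read the angle α between a
bright trace and the spatial axis, and convert it to a speed via
v = (pixel_size / frame_interval) · 1/tan(α).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.registration import optical_flow_tvl1


@dataclass
class VelocityField:
    """Per-frame 2D velocity raster in µm/min.

    ``vx``/``vy`` follow the image axes (x right, y down); ``valid`` flags
    the pixels where the field is defined (inside the cell mask).
    """

    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    pixel_size: float
    time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.vx.shape != self.vy.shape or self.vx.shape != self.valid.shape:
            raise ValueError("component and validity rasters must share shape")
        if not (np.all(np.isfinite(self.vx[self.valid]))
                and np.all(np.isfinite(self.vy[self.valid]))):
            raise ValueError("non-finite velocities inside the valid domain")

    def speed(self) -> np.ndarray:
        """Magnitude raster (µm/min), NaN outside the valid domain."""
        s = np.hypot(self.vx, self.vy)
        return np.where(self.valid, s, np.nan)

    def mean_speed(self, where: np.ndarray | None = None) -> float:
        sel = self.valid if where is None else (self.valid & where)
        return float(np.hypot(self.vx[sel], self.vy[sel]).mean())


def estimate_flow(frame_a: np.ndarray, frame_b: np.ndarray, mask,
                  pixel_size: float, dt_s: float,
                  regularization: float = 0.05,
                  backend: str = "tvl1",
                  ground_truth: VelocityField | None = None,
                  time_s: float = 0.0) -> VelocityField:
    """Estimate the velocity field carrying frame_a into frame_b.

    ``regularization`` is the smoothness weight of the TV-L1 energy
    (larger = smoother).  ``mask`` is the :class:`CellMask` (or bool
    array) of frame_a; with the ``ground_truth`` backend the injected
    field is returned bit-identically.
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if backend == "ground_truth":
        if ground_truth is None:
            raise ValueError("ground_truth backend needs an injected field")
        return ground_truth
    if backend != "tvl1":
        raise ValueError(f"unknown flow backend {backend!r}")
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share shape")
    if not mask_arr.any():
        raise ValueError("empty mask")
    # brightness-constancy data term is scale-sensitive; normalize jointly
    scale = max(frame_a.max(), frame_b.max(), 1e-12)
    flow = optical_flow_tvl1(frame_a / scale, frame_b / scale,
                             attachment=regularization * 300.0)
    # optical_flow_tvl1's (row, col) output registers frame_b onto
    # frame_a; its sign equals the forward motion a -> b
    to_um_min = pixel_size / dt_s * 60.0
    vx = (flow[1] * to_um_min).astype(np.float64)
    vy = (flow[0] * to_um_min).astype(np.float64)
    return VelocityField(vx=vx, vy=vy, valid=mask_arr, pixel_size=pixel_size,
                         time_s=time_s)


def estimate_flow_sequence(frames: np.ndarray, masks, pixel_size: float,
                           frame_interval_s: float, stride: int = 1,
                           **kwargs) -> list[VelocityField]:
    """Flow between frames k and k+stride for every valid k, stamped at
    the time of frame k.  A stride > 1 trades temporal resolution for
    larger (better-conditioned) per-pair displacements."""
    fields = []
    for k in range(len(frames) - stride):
        fields.append(estimate_flow(
            frames[k], frames[k + stride], masks[k], pixel_size,
            dt_s=stride * frame_interval_s,
            time_s=k * frame_interval_s, **kwargs))
    return fields


def save_velocity_field(field: VelocityField, path) -> None:
    """Write a velocity field as a two-channel (vx, vy) float32 TIFF
    with a JSON metadata sidecar (calibration, time stamp, validity
    encoded as NaN outside the mask)."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    vx = np.where(field.valid, field.vx, np.nan).astype(np.float32)
    vy = np.where(field.valid, field.vy, np.nan).astype(np.float32)
    tifffile.imwrite(path, np.stack([vx, vy]), photometric="minisblack")
    meta = {"pixel_size_um": field.pixel_size, "time_s": field.time_s,
            "units": "um/min", "channels": ["vx", "vy"]}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_velocity_field(path) -> VelocityField:
    """Read a velocity field written by :func:`save_velocity_field`."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    valid = np.isfinite(stack[0]) & np.isfinite(stack[1])
    return VelocityField(vx=np.nan_to_num(stack[0]),
                         vy=np.nan_to_num(stack[1]), valid=valid,
                         pixel_size=float(meta["pixel_size_um"]),
                         time_s=float(meta.get("time_s", 0.0)))


# ---------------------------------------------------------------------------
# kymographs


@dataclass
class Kymograph:
    """Space-time reslice: one row per frame, one column per step along
    the line."""

    data: np.ndarray
    p0: tuple[float, float]
    p1: tuple[float, float]
    width: int
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_space(self) -> int:
        return self.data.shape[1]

    def time_reversed(self) -> "Kymograph":
        return Kymograph(data=self.data[::-1].copy(), p0=self.p0, p1=self.p1,
                         width=self.width, pixel_size=self.pixel_size,
                         frame_interval=self.frame_interval)


@dataclass
class KymographMeasurement:
    """One bright-trace reading: angle α (deg, between trace and the
    spatial axis) and the converted speed in µm/min."""

    alpha_deg: float
    velocity_um_min: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_deg <= 90.0:
            raise ValueError("alpha must be in (0, 90] degrees")
        if self.velocity_um_min < 0:
            raise ValueError("velocity must be >= 0")


def reslice_kymograph(frames: np.ndarray, p0, p1, width: int = 4,
                      pixel_size: float = 1.0, frame_interval: float = 1.0,
                      exclude_frames=None) -> Kymograph:
    """Reslice a (T, H, W) stack along the line p0 -> p1 ((x, y) px).

    Intensity is averaged across ``width`` parallel 1 px-spaced offsets
    centred on the line, sampled at 1 px steps along it.  Frames listed in
    ``exclude_frames`` (e.g. blebbing time points) are dropped.
    """
    frames = np.asarray(frames, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    length = float(np.hypot(*(p1 - p0)))
    if length < 2.0:
        raise ValueError("line shorter than 2 px")
    n_samples = int(np.floor(length)) + 1
    d = (p1 - p0) / length
    normal = np.array([-d[1], d[0]])
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    s = np.arange(n_samples, dtype=float)
    # (n_offsets, n_samples, 2) sample positions in (x, y)
    pos = (p0[None, None, :] + s[None, :, None] * d[None, None, :]
           + offsets[:, None, None] * normal[None, None, :])
    coords = np.stack([pos[..., 1], pos[..., 0]])  # (row, col)
    keep = [t for t in range(frames.shape[0])
            if exclude_frames is None or t not in set(exclude_frames)]
    rows = np.empty((len(keep), n_samples))
    for i, t in enumerate(keep):
        samples = ndimage.map_coordinates(frames[t], coords.reshape(2, -1),
                                          order=1, mode="nearest")
        rows[i] = samples.reshape(width, n_samples).mean(axis=0)
    return Kymograph(data=rows, p0=tuple(p0), p1=tuple(p1), width=width,
                     pixel_size=pixel_size, frame_interval=frame_interval)


def save_kymograph(kymo: Kymograph, path,
                   measurements=None) -> None:
    """Write a kymograph as float32 TIFF; optional measurements go to a
    CSV next to it (alpha_deg, velocity_um_min, score)."""
    from pathlib import Path

    import pandas as pd
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, kymo.data.astype(np.float32),
                     photometric="minisblack")
    if measurements:
        pd.DataFrame([{"alpha_deg": m.alpha_deg,
                       "velocity_um_min": m.velocity_um_min,
                       "score": m.score} for m in measurements]).to_csv(
            path.with_suffix(".csv"), index=False)


def velocity_from_angle(alpha_deg: float, pixel_size: float,
                        frame_interval: float) -> float:
    """Convert a kymograph trace angle to a speed in µm/min.

    α is the angle between the bright trace and the spatial axis of the
    kymograph (in kymograph pixel coordinates: 1 px along space, 1 frame
    along time).  A static structure gives a time-parallel trace,
    α = 90°, speed 0.  v = (pixel_size / frame_interval) / tan(α),
    converted from µm/s to µm/min.
    """
    if not 0.0 < alpha_deg <= 90.0:
        raise ValueError("alpha must be in (0, 90] degrees")
    if alpha_deg == 90.0:
        return 0.0
    v_um_s = (pixel_size / frame_interval) / np.tan(np.deg2rad(alpha_deg))
    return float(v_um_s * 60.0)


def detect_kymograph_angle(kymo: Kymograph, roi: tuple[int, int] | None = None,
                           max_traces: int = 1,
                           angle_step_deg: float = 0.5,
                           contrast_k: float = 2.0,
                           manual_alpha_deg: float | None = None,
                           detrend: bool = False
                           ) -> list[KymographMeasurement]:
    """Find the dominant bright-trace orientation(s) in a kymograph.

    Scores each candidate angle by the peak directional line-integral
    contrast (a Radon-style sweep restricted to the spatial window
    ``roi``, given as a (start, stop) column range).  ``detrend``
    subtracts each column's temporal mean first, removing static
    structure so only moving traces score.  Raises
    ValueError("no trace found") when no angle scores above
    ``contrast_k`` robust standard deviations of the score curve.  A
    manual angle override bypasses detection (mirroring the original
    manual measurement).
    """
    if manual_alpha_deg is not None:
        return [KymographMeasurement(
            alpha_deg=manual_alpha_deg,
            velocity_um_min=velocity_from_angle(
                manual_alpha_deg, kymo.pixel_size, kymo.frame_interval))]
    data = kymo.data
    if roi is not None:
        lo, hi = roi
        if lo < 0 or hi > data.shape[1] or hi - lo < 4:
            raise ValueError("roi outside kymograph spatial extent")
        data = data[:, lo:hi]
    if detrend:
        img = data - data.mean(axis=0, keepdims=True)
    else:
        img = data - np.median(data)
    n_t, n_s = img.shape
    centre = np.array([(n_s - 1) / 2.0, (n_t - 1) / 2.0])  # (x=space, y=time)
    half_len = min(n_t, n_s) / 2.0 - 1.0
    s = np.linspace(-half_len, half_len, int(2 * half_len) + 1)
    n_off = int(np.hypot(n_t, n_s))
    offs = np.arange(n_off, dtype=float) - (n_off - 1) / 2.0

    angles = np.arange(angle_step_deg, 90.0 + angle_step_deg / 2,
                       angle_step_deg)
    scores = np.empty(angles.size)
    for i, a in enumerate(angles):
        rad = np.deg2rad(a)
        d = np.array([np.cos(rad), np.sin(rad)])   # (dx=space, dy=time)
        p = np.array([-d[1], d[0]])
        # (n_off, n_s_samples, 2) positions
        pos = (centre[None, None, :] + s[None, :, None] * d[None, None, :]
               + offs[:, None, None] * p[None, None, :])
        coords = np.stack([pos[..., 1].ravel(), pos[..., 0].ravel()])
        vals = ndimage.map_coordinates(img, coords, order=1, mode="constant",
                                       cval=0.0).reshape(n_off, s.size)
        cov = ndimage.map_coordinates(np.ones_like(img), coords, order=1,
                                      mode="constant",
                                      cval=0.0).reshape(n_off, s.size)
        coverage = cov.sum(axis=1)
        line_means = vals.sum(axis=1) / np.maximum(coverage, 1e-9)
        # lines mostly outside the window would score on a handful of
        # samples; require most of the line to lie inside
        line_means[coverage < 0.7 * s.size] = -np.inf
        scores[i] = line_means.max()

    # an aligned line integral preserves a trace's amplitude while
    # structureless intensity averages down along the line, so a genuine
    # trace scores well above the image's own intensity spread
    height = contrast_k * float(img.std())
    peaks, props = find_peaks(scores, height=height,
                              distance=max(1, int(5.0 / angle_step_deg)))
    heights = list(props["peak_heights"])
    peaks = list(peaks)
    near_90 = any(angles[i] > 85.0 for i in peaks)
    if scores[-1] > height and not near_90:
        peaks.append(scores.size - 1)  # time-parallel trace (alpha = 90)
        heights.append(scores[-1])
    if not peaks:
        raise ValueError("no trace found")
    order = np.argsort(-np.asarray(heights))[:max_traces]
    out = []
    for idx in np.asarray(peaks)[order]:
        alpha = float(angles[idx])
        out.append(KymographMeasurement(
            alpha_deg=alpha,
            velocity_um_min=velocity_from_angle(alpha, kymo.pixel_size,
                                                kymo.frame_interval),
            score=float(scores[idx])))
    return out
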