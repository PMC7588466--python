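"""Synthetic blebbing-cell movie generator with full ground truth.

Emulates the statistical structure of time-lapse recordings of a
bleb-migrating cell: a roughly circular cell carrying a bright membrane
ring, a cortical actin band enriched at the front and decaying rearward
exponentially, tangential retrograde cortical flow away from the front on
both sides, and discrete bleb events (transient outward bulges with
cytoplasmic influx and local actin depletion).  Every downstream analysis
stage can therefore be tested against known ground truth without any
microscopy data.

Coordinate conventions follow :mod:`blebflow.geometry`: image origin
top-left, x rightward, y downward; perimeter angles are measured from the
front direction, increasing counterclockwise in this frame.

The steady front-enriched intensity envelope is static (the front
polymerization source balances rearward transport and decay) while a
multiplicative speckle texture rides on it, advecting away from the front
at the retrograde speed — this is what gives optical flow something to
measure.  The texture is renormalized per frame so the above-background
band total is exactly conserved in the bleb-free, noise-free case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import VelocityField
from .geometry import fold_angle_deg, polygon_centroid, wrap_signed_deg
from .movie import CellMovie
from .polarity import IntensityProfile, Track
from .segmentation import CellContour


@dataclass(frozen=True)
class BlebSpec:
    """One scheduled bleb: onset time (s), perimeter angle relative to the
    front (deg), maximal outward amplitude (µm) and total lifetime (s)."""

    time_s: float
    angle_deg: float
    amplitude_um: float
    duration_s: float


@dataclass
class SimulationParams:
    """Ground-truth parameters of a synthetic blebbing-cell movie.

    Defaults mirror the acquisition conditions the analyses assume:
    0.286 µm/px, 500 ms/frame, 490 frames, a ~10 µm cell, a 1.7 µm
    cortical band.  ``actin_decay_length_um`` is the ground-truth decay
    length λ*, ``retrograde_speed_um_min`` the ground-truth flow speed v*,
    and ``background`` the ground-truth I_BG*.
    """

    cell_radius_um: float = 10.0
    pixel_size_um: float = 0.286
    frame_interval_s: float = 0.5
    n_frames: int = 490
    cortex_thickness_um: float = 1.7
    # off-lattice by default: a real cell's polarity axis is arbitrary
    # with respect to the camera grid
    front_direction_deg: float = 30.0
    actin_peak: float = 100.0
    actin_decay_length_um: float = 7.0
    background: float = 10.0
    retrograde_speed_um_min: float = 6.0
    bleb_schedule: tuple[BlebSpec, ...] = ()
    noise_sd: float = 2.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0
    # decay coordinate of the actin envelope: "axial" = distance along the
    # front-rear axis (the transport model's coordinate), "arc" = arc
    # length along the cortex from the front point
    decay_coordinate: str = "axial"
    membrane_peak: float = 100.0
    membrane_sigma_um: float = 0.4
    cytosol_level: float = 8.0
    bleb_half_width_deg: float = 15.0
    bleb_depletion: float = 0.5
    bleb_growth_fraction: float = 0.25
    bleb_refractory_s: float = 6.0
    bleb_cytoplasmic_inflow: bool = True
    texture_amplitude: float = 0.3
    texture_harmonics: tuple[int, int] = (8, 40)
    image_margin_um: float = 3.0
    store_flow: bool = True

    def validate(self) -> None:
        positive = {
            "cell_radius_um": self.cell_radius_um,
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "cortex_thickness_um": self.cortex_thickness_um,
            "actin_peak": self.actin_peak,
            "actin_decay_length_um": self.actin_decay_length_um,
            "background": self.background,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.retrograde_speed_um_min < 0:
            raise ValueError("retrograde_speed_um_min must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.decay_coordinate not in ("axial", "arc"):
            raise ValueError(
                f"unknown decay coordinate {self.decay_coordinate!r}")
        duration = self.n_frames * self.frame_interval_s
        blebs = sorted(self.bleb_schedule, key=lambda b: b.time_s)
        for b in blebs:
            if not (0.0 <= b.time_s <= duration):
                raise ValueError(
                    f"bleb at t={b.time_s}s outside movie duration {duration}s")
            if b.amplitude_um <= 0 or b.duration_s <= 0:
                raise ValueError("bleb amplitude and duration must be > 0")
        # reject re-blebbing at the same perimeter site within the
        # refractory window: physically one membrane patch cannot re-bleb
        # immediately, and overlapping bumps would corrupt ground truth
        for a, b in zip(blebs, blebs[1:]):
            close_in_time = (b.time_s - a.time_s) < max(
                self.bleb_refractory_s, a.duration_s)
            close_in_angle = fold_angle_deg(
                b.angle_deg - a.angle_deg) < 2 * self.bleb_half_width_deg
            if close_in_time and close_in_angle:
                raise ValueError(
                    "overlapping bleb events at the same angle within the "
                    f"refractory window: t={a.time_s}s/{b.time_s}s at "
                    f"{a.angle_deg}deg/{b.angle_deg}deg")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the analyses must recover."""

    true_flow_fields: list[VelocityField] | None
    true_decay_length_um: float
    true_retrograde_speed_um_min: float
    true_background: float
    true_bleb_events: list[tuple[float, float]]  # (time s, angle deg)
    true_contours: list[CellContour]
    true_track: Track
    front_direction_deg: float

    def __post_init__(self) -> None:
        if self.true_bleb_events != sorted(self.true_bleb_events):
            raise ValueError("bleb events must be sorted by time")

    def save(self, directory: str | Path) -> None:
        """Write ground truth as JSON (parameters, schedule) and CSV
        (track, contours)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump({
                "true_decay_length_um": self.true_decay_length_um,
                "true_retrograde_speed_um_min":
                    self.true_retrograde_speed_um_min,
                "true_background": self.true_background,
                "front_direction_deg": self.front_direction_deg,
                "true_bleb_events": self.true_bleb_events,
            }, fh, indent=2)
        pd.DataFrame({
            "t_min": self.true_track.t_min,
            "x_um": self.true_track.xy_um[:, 0],
            "y_um": self.true_track.xy_um[:, 1],
        }).to_csv(directory / "track.csv", index=False)
        rows = []
        for c in self.true_contours:
            for i, (x, y) in enumerate(c.points):
                rows.append((c.frame_index, i, x, y))
        pd.DataFrame(rows, columns=["frame", "vertex_index", "x", "y"]).to_csv(
            directory / "contours.csv", index=False)


def _bleb_growth(tau: np.ndarray, growth_s: float, retract_s: float
                 ) -> np.ndarray:
    """Smooth grow-then-retract envelope in [0, 1]; tau is time since onset."""
    g = np.zeros_like(tau, dtype=float)
    grow = (tau >= 0) & (tau < growth_s)
    g[grow] = np.sin(0.5 * np.pi * tau[grow] / growth_s) ** 2
    ret = (tau >= growth_s) & (tau < growth_s + retract_s)
    g[ret] = np.cos(0.5 * np.pi * (tau[ret] - growth_s) / retract_s) ** 2
    return g


def _bleb_growth_rate(tau: float, growth_s: float, retract_s: float) -> float:
    """d/dtau of :func:`_bleb_growth` (1/s)."""
    if 0 <= tau < growth_s:
        return float(np.pi / (2 * growth_s)
                     * np.sin(np.pi * tau / growth_s))
    if growth_s <= tau < growth_s + retract_s:
        return float(-np.pi / (2 * retract_s)
                     * np.sin(np.pi * (tau - growth_s) / retract_s))
    return 0.0


class _Texture:
    """Zero-mean, unit-variance speckle pattern on the arc coordinate.

    The two cortex sides (left/right of the front) carry independent
    phase sets — speckles on opposite sides of a real cell are
    uncorrelated.
    """

    def __init__(self, params: SimulationParams, rng: np.random.Generator):
        k_lo, k_hi = params.texture_harmonics
        self.L = np.pi * params.cell_radius_um  # half perimeter, µm
        self.k = np.arange(k_lo, k_hi + 1)
        amp = rng.uniform(0.5, 1.0, size=self.k.size)
        self.amp = amp / np.sqrt(0.5 * np.sum(amp ** 2))  # unit variance
        self.phase = rng.uniform(0, 2 * np.pi, size=(2, self.k.size))

    def __call__(self, u: np.ndarray, side: np.ndarray) -> np.ndarray:
        base = 2 * np.pi * np.outer(u.ravel(), self.k / self.L)
        out_a = np.cos(base + self.phase[0]) @ self.amp
        out_b = np.cos(base + self.phase[1]) @ self.amp
        return np.where(side.ravel() >= 0, out_a, out_b).reshape(u.shape)


def simulate_cell_movie(params: SimulationParams
                        ) -> tuple[CellMovie, SyntheticGroundTruth]:
    """Render a two-channel synthetic movie plus its ground truth.

    Identical ``params`` (including ``seed``) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    R_um = params.cell_radius_um
    R_px = R_um / px
    max_amp = max((b.amplitude_um for b in params.bleb_schedule), default=0.0)
    half_px = int(np.ceil((R_um + max_amp + params.image_margin_um) / px))
    n = 2 * half_px
    c0 = (n - 1) / 2.0

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dx, dy = xx - c0, yy - c0
    r_px = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    front = np.deg2rad(params.front_direction_deg)
    rel = np.angle(np.exp(1j * (theta - front)))  # (-pi, pi]

    if params.decay_coordinate == "axial":
        # true axial depth from the front-most point, per pixel
        fx, fy = np.cos(front), np.sin(front)
        decay_dist = np.clip(R_um - (dx * fx + dy * fy) * px, 0.0, None)
    else:
        decay_dist = R_um * np.abs(rel)
    envelope = params.actin_peak * np.exp(
        -decay_dist / params.actin_decay_length_um)

    texture = _Texture(params, rng)
    v_um_s = params.retrograde_speed_um_min / 60.0
    th_px = params.cortex_thickness_um / px
    sig_m = params.membrane_sigma_um / px
    hw = np.deg2rad(params.bleb_half_width_deg)

    blebs = sorted(params.bleb_schedule, key=lambda b: b.time_s)
    bleb_rel = [np.angle(np.exp(1j * (rel - np.deg2rad(b.angle_deg))))
                for b in blebs]
    tapers = [np.where(np.abs(br) < hw,
                       np.cos(0.5 * np.pi * br / hw) ** 2, 0.0)
              for br in bleb_rel]

    theta_c = np.linspace(-np.pi, np.pi, 720, endpoint=False)
    rel_c = np.angle(np.exp(1j * (theta_c - front)))

    membrane = np.empty((params.n_frames, n, n), dtype=np.float32)
    actin = np.empty_like(membrane)
    contours: list[CellContour] = []
    track_xy = np.empty((params.n_frames, 2))
    flow_fields: list[VelocityField] | None = [] if params.store_flow else None

    target_total: float | None = None
    for f in range(params.n_frames):
        t = f * params.frame_interval_s
        # deformed radius field (px) and per-bleb envelopes
        R_field = np.full_like(r_px, R_px)
        bump_norm = np.zeros_like(r_px)
        growth_rates: list[float] = []
        for b, taper in zip(blebs, tapers):
            growth_s = params.bleb_growth_fraction * b.duration_s
            retract_s = b.duration_s - growth_s
            g = _bleb_growth(np.array([t - b.time_s]), growth_s, retract_s)[0]
            growth_rates.append(
                _bleb_growth_rate(t - b.time_s, growth_s, retract_s))
            if g > 0:
                R_field = R_field + (b.amplitude_um / px) * g * taper
                bump_norm = np.maximum(bump_norm, g * taper)

        inside = r_px <= R_field
        band = inside & (r_px > R_field - th_px)
        interior = inside & ~band

        mem = params.membrane_peak * np.exp(
            -((r_px - R_field) ** 2) / (2 * sig_m ** 2))
        mem[interior] += params.cytosol_level

        # pattern f(s - vt) streams away from the front on both sides
        u = R_um * np.abs(rel) - v_um_s * t
        factor = np.clip(
            1.0 + params.texture_amplitude * texture(u, np.sign(rel)),
            0.2, None)
        # soften the band's inner edge over ~1 px: the cortex fades into
        # the cytosol rather than stepping, and a hard step would alias
        # against any sub-pixel band-boundary estimate downstream
        inner_soft = np.clip(r_px - (R_field - th_px), 0.0, 1.0)
        above_bg = envelope * factor * inner_soft
        band_sum = float(np.sum(above_bg[band]))
        if target_total is None:
            target_total = float(np.sum(envelope[band]))
        if band_sum > 0:
            above_bg = above_bg * (float(np.sum(envelope[band])) / band_sum)
        act = np.zeros_like(mem)
        act[inside] = params.background
        act[band] += (above_bg * (1.0 - params.bleb_depletion * bump_norm)
                      )[band]

        if params.noise_sd > 0:
            if params.noise_model == "gaussian":
                mem = mem + rng.normal(0, params.noise_sd, mem.shape)
                act = act + rng.normal(0, params.noise_sd, act.shape)
            else:
                gain = params.actin_peak / params.noise_sd ** 2
                mem = rng.poisson(np.clip(mem, 0, None) * gain) / gain
                act = rng.poisson(np.clip(act, 0, None) * gain) / gain
        membrane[f] = mem
        actin[f] = act

        # ground-truth contour at this frame
        R_c = np.full_like(theta_c, R_px)
        for b in blebs:
            growth_s = params.bleb_growth_fraction * b.duration_s
            retract_s = b.duration_s - growth_s
            g = _bleb_growth(np.array([t - b.time_s]), growth_s, retract_s)[0]
            if g > 0:
                br = np.angle(np.exp(
                    1j * (rel_c - np.deg2rad(b.angle_deg))))
                taper_c = np.where(np.abs(br) < hw,
                                   np.cos(0.5 * np.pi * br / hw) ** 2, 0.0)
                R_c = R_c + (b.amplitude_um / px) * g * taper_c
        pts = np.column_stack([c0 + R_c * np.cos(theta_c),
                               c0 + R_c * np.sin(theta_c)])
        cent = polygon_centroid(pts)
        contours.append(CellContour(points=pts, frame_index=f,
                                    centroid=cent,
                                    arc_length_um=None, pixel_size=px))
        track_xy[f] = cent * px

        if flow_fields is not None:
            vx = np.zeros_like(r_px, dtype=np.float32)
            vy = np.zeros_like(vx)
            side = np.sign(rel)
            speed = params.retrograde_speed_um_min
            vx[band] = (-np.sin(theta) * side * speed)[band].astype(np.float32)
            vy[band] = (np.cos(theta) * side * speed)[band].astype(np.float32)
            if params.bleb_cytoplasmic_inflow:
                for b, taper, rate in zip(blebs, tapers, growth_rates):
                    if rate > 0:  # growth phase: cytoplasm streams outward
                        vr = b.amplitude_um * rate * 60.0 * taper
                        sel = interior & (taper > 0)
                        vx[sel] += (np.cos(theta) * vr)[sel]
                        vy[sel] += (np.sin(theta) * vr)[sel]
            flow_fields.append(VelocityField(
                vx=vx, vy=vy, valid=inside.copy(), pixel_size=px,
                time_s=t))

    movie = CellMovie(membrane=membrane, actin=actin,
                      pixel_size=px, frame_interval=params.frame_interval_s)
    t_min = np.arange(params.n_frames) * params.frame_interval_s / 60.0
    truth = SyntheticGroundTruth(
        true_flow_fields=flow_fields,
        true_decay_length_um=params.actin_decay_length_um,
        true_retrograde_speed_um_min=params.retrograde_speed_um_min,
        true_background=params.background,
        true_bleb_events=[(b.time_s, b.angle_deg) for b in blebs],
        true_contours=contours,
        true_track=Track(t_min=t_min, xy_um=track_xy),
        front_direction_deg=params.front_direction_deg,
    )
    return movie, truth


def simulate_intensity_profile(I0: float, lam: float, bg: float,
                               x_max: float, n_points: int,
                               noise_sd: float, seed: int
                               ) -> IntensityProfile:
    """Sample I(x) = I0·exp(−x/λ) + bg plus zero-mean Gaussian noise on a
    uniform grid of ``n_points`` positions over [0, x_max] µm."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.linspace(0.0, x_max, n_points)
    intensity = I0 * np.exp(-x / lam) + bg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0, noise_sd, x.shape)
    return IntensityProfile(positions_um=x,
                            intensities=np.clip(intensity, 0, None))


def simulate_track(step_speed: float, persistence: float, n_steps: int,
                   dt: float, seed: int) -> Track:
    """Correlated random walk in the plane.

    ``persistence`` in [0, 1] scales the per-step turning: 1 gives a
    straight line, 0 gives uncorrelated (uniform) turning.  ``step_speed``
    is in µm/min, ``dt`` in minutes.
    """
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must be in [0, 1]")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    turns = (1.0 - persistence) * rng.uniform(-np.pi, np.pi, n_steps)
    headings = rng.uniform(0, 2 * np.pi) + np.cumsum(turns)
    step = step_speed * dt
    xy = np.zeros((n_steps + 1, 2))
    xy[1:] = np.cumsum(
        step * np.column_stack([np.cos(headings), np.sin(headings)]), axis=0)
    return Track(t_min=dt * np.arange(n_steps + 1), xy_um=xy)


def simulate_perimeter_signals(contour: CellContour, ecad_pattern,
                               mem_pattern, shape: tuple[int, int],
                               line_sigma_px: float = 1.0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Render two signals along a contour with matched geometry.

    ``ecad_pattern`` and ``mem_pattern`` are callables of the normalized
    arc position in [0, 1) (measured from the first contour vertex,
    following contour orientation); both must be non-negative on [0, 1).
    Returns the (ecad, membrane) frames of the requested shape: each pixel
    within 3 sigma of the contour carries the pattern value of its nearest
    contour sample, shaped by a Gaussian cross-section.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("degenerate contour: need >= 3 points")
    from .geometry import resample_closed_polyline
    dense = resample_closed_polyline(pts, max(len(pts) * 4, 720))
    frac = np.arange(len(dense)) / len(dense)
    e_vals = np.asarray([float(ecad_pattern(f)) for f in frac])
    m_vals = np.asarray([float(mem_pattern(f)) for f in frac])
    if np.any(e_vals < 0) or np.any(m_vals < 0):
        raise ValueError("patterns must be non-negative")

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    tree = cKDTree(dense)
    dist, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel()]),
                           distance_upper_bound=3.0 * line_sigma_px)
    hit = np.isfinite(dist)
    weight = np.zeros(h * w)
    weight[hit] = np.exp(-dist[hit] ** 2 / (2 * line_sigma_px ** 2))
    ecad = np.zeros(h * w)
    mem = np.zeros(h * w)
    ecad[hit] = e_vals[idx[hit]] * weight[hit]
    mem[hit] = m_vals[idx[hit]] * weight[hit]
    return ecad.reshape(shape), mem.reshape(shape)


def default_bleb_schedule(n_blebs: int, t_start: float, spacing_s: float,
                          angle_sigma_deg: float, seed: int,
                          amplitude_um: float = 2.0,
                          duration_s: float = 6.0,
                          jitter_s: float = 1.0) -> tuple[BlebSpec, ...]:
    """Draw a front-centred bleb schedule: onset times spaced by
    ``spacing_s`` (± uniform jitter), angles wrapped-normal about the front
    with spread ``angle_sigma_deg``."""
    rng = np.random.default_rng(seed)
    out = []
    t = t_start
    for _ in range(n_blebs):
        ang = float(wrap_signed_deg(rng.normal(0.0, angle_sigma_deg)))
        out.append(BlebSpec(time_s=round(t, 3), angle_deg=ang,
                            amplitude_um=amplitude_um,
                            duration_s=duration_s))
        t += spacing_s + rng.uniform(-jitter_s, jitter_s)
    return tuple(out)
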