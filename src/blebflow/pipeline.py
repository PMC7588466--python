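"""End-to-end orchestration: configuration, stage execution, reporting.

The pipeline runs simulate (optional) → segment → flow → blebs →
project → profile/fit → kymograph → track metrics on one movie and
collects every stage's headline numbers into a single report with a
provenance block (config hash, seed, package version).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .blebs import (bleb_frequency, consecutive_bleb_angles,
                    detect_blebs, front_angle_series)
from .cortical import (mean_projected_velocity, partition_cortex,
                       polarity_axis)
from .flow import (detect_kymograph_angle, estimate_flow_sequence,
                   reslice_kymograph)
from .movie import CellMovie
from .polarity import fm_ratio, front_rear_profile, track_metrics
from .segmentation import segment_movie
from .synthetic import BlebSpec, SimulationParams, simulate_cell_movie
from .transport import fit_decay

log = logging.getLogger("blebflow")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": None,
    "simulate": {
        "n_frames": 120,
        "noise_sd": 2.0,
        "bleb_schedule": [],   # list of [time_s, angle_deg, amp_um, dur_s]
    },
    "input": {"movie": None},
    "stages": {
        "segment": True,
        "flow": True,
        "project": True,
        "profile": True,
        "fit": True,
        "blebs": True,
        "kymograph": True,
        "track": True,
    },
    "segmentation": {"min_area": 200, "sigma_px": 3.0, "refine_ridge": True},
    "flow": {"backend": "tvl1", "regularization": 0.05, "stride": 1,
             "n_pairs": 20},
    "cortical": {"n": 4, "thickness_um": 1.7, "delta_T_s": 10.0,
                 "spacing_um": 0.5},
    "profile": {"band_um": 1.7, "statistic": "median", "threshold": None},
    "fit": {"window": "auto"},
    "blebs": {"prominence_k": 3.0, "min_separation_s": 2.0,
              "min_prominence_um_min": 2.0, "sigma_front_s": 25.0,
              "bin_width_deg": 20.0},
    # lower detection contrast than the library default: the chord
    # kymograph's speckle traces ride on residual noise after
    # detrending
    "kymograph": {"width": 4, "contrast_k": 1.5},
}

_STAGE_DEPS = {
    "flow": ["segment"],
    "project": ["segment", "flow"],
    "profile": ["segment"],
    "fit": ["profile"],
    "blebs": ["segment"],
    "kymograph": ["segment"],
    "track": ["segment"],
}


def merge_config(user: dict | None) -> dict:
    """Default config overlaid with user keys (one level deep)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return a list of human-readable issues; an empty list means the
    configuration is runnable.  Never mutates the input."""
    cfg = merge_config(config)
    issues: list[str] = []
    if cfg["cortical"]["delta_T_s"] <= 0:
        issues.append("cortical.delta_T_s must be > 0")
    if cfg["cortical"]["thickness_um"] <= 0:
        issues.append("cortical.thickness_um must be > 0")
    if cfg["cortical"]["n"] < 1:
        issues.append("cortical.n must be >= 1")
    if cfg["segmentation"]["min_area"] <= 0:
        issues.append("segmentation.min_area must be > 0")
    if cfg["flow"]["stride"] < 1:
        issues.append("flow.stride must be >= 1")
    if cfg["blebs"]["min_separation_s"] <= 0:
        issues.append("blebs.min_separation_s must be > 0")
    if cfg["kymograph"]["width"] < 1:
        issues.append("kymograph.width must be >= 1")
    if not 0 < cfg["blebs"]["bin_width_deg"] <= 180:
        issues.append("blebs.bin_width_deg must be in (0, 180]")
    stages = cfg["stages"]
    for stage, deps in _STAGE_DEPS.items():
        if stages.get(stage):
            for dep in deps:
                if not stages.get(dep):
                    issues.append(
                        f"stages.{stage} requires stages.{dep} enabled")
    if cfg["input"]["movie"] is None and cfg.get("simulate") is None:
        issues.append("either input.movie or simulate must be given")
    if cfg["input"]["movie"] is not None:
        if not Path(cfg["input"]["movie"]).exists():
            issues.append(f"input.movie not found: {cfg['input']['movie']}")
    return issues


def config_hash(config: dict) -> str:
    """Stable hash of the effective configuration."""
    canon = json.dumps(merge_config(config), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _simulation_params(cfg: dict) -> SimulationParams:
    sim = dict(cfg["simulate"])
    schedule = tuple(BlebSpec(*b) for b in sim.pop("bleb_schedule", []))
    return SimulationParams(bleb_schedule=schedule, seed=cfg["seed"], **sim)


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the configured stages on one movie and return the report.

    The report is a plain dict (JSON-serializable); with
    ``config['out_dir']`` set, stage outputs (profile CSV, fit JSON,
    events CSV, report JSON) are written there.  Failing stages are
    recorded and their dependents skipped.
    """
    cfg = merge_config(config)
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    report: dict = {
        "provenance": {"config_hash": config_hash(cfg), "seed": cfg["seed"],
                       "version": _version},
        "stages": {},
        "errors": {},
    }
    out_dir = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    if cfg["input"]["movie"]:
        movie = CellMovie.load(cfg["input"]["movie"])
        truth = None
    else:
        params = _simulation_params(cfg)
        movie, truth = simulate_cell_movie(params)
        log.info("simulated %d frames of %s px", movie.n_frames, movie.shape)
    report["stages"]["simulate"] = {
        "n_frames": movie.n_frames,
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
    }

    stages = cfg["stages"]
    done: set[str] = set()

    def runnable(name: str) -> bool:
        return stages.get(name) and all(d in done for d in
                                        _STAGE_DEPS.get(name, []))

    contours = masks = axis = None
    if stages.get("segment"):
        try:
            seg = cfg["segmentation"]
            contours, masks = segment_movie(
                movie.membrane, min_area=seg["min_area"],
                sigma_px=seg["sigma_px"], pixel_size=movie.pixel_size,
                refine_ridge=seg["refine_ridge"])
            axis = polarity_axis(movie.actin[0], masks[0])
            report["stages"]["segment"] = {
                "n_contours": len(contours),
                "mean_area_px": float(np.mean([m.area_px for m in masks])),
                "polarity_axis": [float(axis.p[0]), float(axis.p[1])],
            }
            done.add("segment")
        except ValueError as exc:
            report["errors"]["segment"] = str(exc)

    fields = None
    if runnable("flow"):
        fl = cfg["flow"]
        n_pairs = min(fl["n_pairs"],
                      movie.n_frames - fl["stride"])
        fields = estimate_flow_sequence(
            movie.actin[:n_pairs + fl["stride"]], masks, movie.pixel_size,
            movie.frame_interval, stride=fl["stride"],
            backend=fl["backend"], regularization=fl["regularization"])
        report["stages"]["flow"] = {
            "n_fields": len(fields),
            "mean_speed_um_min": float(np.mean(
                [f.mean_speed() for f in fields])),
        }
        done.add("flow")

    events = []
    if runnable("blebs"):
        bl = cfg["blebs"]
        cents = [m.centroid() for m in masks]
        front = front_angle_series(movie.actin, masks, cents,
                                   movie.frame_interval,
                                   sigma_s=bl["sigma_front_s"])
        events = detect_blebs(contours, front, movie.frame_interval,
                              movie.pixel_size,
                              prominence_k=bl["prominence_k"],
                              min_separation_s=bl["min_separation_s"],
                              min_prominence_um_min=bl[
                                  "min_prominence_um_min"])
        freq = bleb_frequency(events, movie.duration)
        cons = (consecutive_bleb_angles(events, contours)
                if len(events) >= 2 else np.array([]))
        report["stages"]["blebs"] = {
            "n_events": len(events),
            "frequency_per_min": freq,
            "event_times_s": [e.time_s for e in events],
            "event_angles_deg": [e.perimeter_angle_deg for e in events],
            "consecutive_angles_deg": [float(a) for a in cons],
        }
        if out_dir and events:
            pd.DataFrame([{
                "time_s": e.time_s, "frame": e.frame_index,
                "angle_deg": e.perimeter_angle_deg,
                "x_px": e.initiation_point_px[0],
                "y_px": e.initiation_point_px[1],
                "centroid_speed_um_min": e.centroid_speed_peak_um_min,
            } for e in events]).to_csv(out_dir / "bleb_events.csv",
                                       index=False)
        done.add("blebs")

    if runnable("project"):
        co = cfg["cortical"]
        t_last = fields[-1].time_s
        delta_T = co["delta_T_s"]
        t_bleb = next((e.time_s for e in events
                       if delta_T <= e.time_s <= t_last), None)
        if t_bleb is None:
            t_bleb = min(delta_T, t_last)
        part = partition_cortex(contours[0], axis, n=co["n"],
                                thickness_um=co["thickness_um"],
                                pixel_size=movie.pixel_size,
                                spacing_um=co["spacing_um"],
                                mask=masks[0])
        rows = []
        for label, region in zip(part.labels,
                                 part.as_tracked_regions(time_s=0.0)):
            res = mean_projected_velocity(
                region, fields, axis, T_bleb=t_bleb,
                delta_T=min(delta_T, t_bleb) if t_bleb > 0 else delta_T,
                region_label=label)
            rows.append({"region": label,
                         "v_bar_um_min": res.v_bar_um_min,
                         "d_bar_um": res.d_bar_um,
                         "valid_fraction": res.valid_fraction,
                         "partial": res.partial})
        report["stages"]["project"] = {"T_bleb_s": t_bleb, "regions": rows}
        if out_dir:
            pd.DataFrame(rows).to_csv(out_dir / "projected_velocity.csv",
                                      index=False)
        done.add("project")

    profile = None
    if runnable("profile"):
        pr = cfg["profile"]
        actin_avg = movie.actin.mean(axis=0)
        profile = front_rear_profile(actin_avg, masks[0], axis,
                                     movie.pixel_size,
                                     threshold=pr["threshold"],
                                     band_um=pr["band_um"],
                                     statistic=pr["statistic"])
        fm = fm_ratio(actin_avg, masks[0], axis)
        report["stages"]["profile"] = {
            "n_points": len(profile.positions_um),
            "fm_ratio": float(fm),
        }
        if out_dir:
            pd.DataFrame({"x_um": profile.positions_um,
                          "intensity": profile.intensities}).to_csv(
                out_dir / "front_rear_profile.csv", index=False)
        done.add("profile")

    if runnable("fit"):
        window = cfg["fit"]["window"]
        if isinstance(window, (list, tuple)):
            window = tuple(window)
        try:
            fit = fit_decay(profile, window=window)
            report["stages"]["fit"] = asdict(fit)
            if out_dir:
                fit.to_json(out_dir / "decay_fit.json")
            done.add("fit")
        except ValueError as exc:
            report["errors"]["fit"] = str(exc)

    if runnable("kymograph"):
        ky = cfg["kymograph"]
        ring = contours[0].points
        c = np.asarray(contours[0].centroid)
        # chord parallel to the polarity axis, ~1 um inside the lateral
        # border: tangential cortical flow has no component along the
        # centre line at the apex, but slopes traces along this chord
        perp = np.array([-axis.p[1], axis.p[0]])
        d_max = float(np.max((ring - c) @ perp))
        d = max(d_max - 1.0 / movie.pixel_size, 0.0)
        r_p = float(np.max(np.abs((ring - c) @ axis.p)))
        half = 0.9 * np.sqrt(max(r_p ** 2 - d ** 2, 4.0))
        centre_pt = c + perp * d
        p0 = centre_pt - axis.p * half
        p1 = centre_pt + axis.p * half
        kymo = reslice_kymograph(movie.actin, p0, p1,
                                 width=ky["width"],
                                 pixel_size=movie.pixel_size,
                                 frame_interval=movie.frame_interval)
        entry: dict = {"n_frames": kymo.n_frames, "n_space": kymo.n_space}
        try:
            ms = detect_kymograph_angle(kymo, detrend=True,
                                        contrast_k=ky["contrast_k"])
            entry["alpha_deg"] = ms[0].alpha_deg
            entry["velocity_um_min"] = ms[0].velocity_um_min
        except ValueError as exc:
            entry["note"] = str(exc)
        report["stages"]["kymograph"] = entry
        done.add("kymograph")

    if runnable("track"):
        if truth is not None:
            track = truth.true_track
        else:
            from .geometry import polygon_centroid
            from .polarity import Track
            cents = np.array([polygon_centroid(c.points) for c in contours])
            track = Track(
                t_min=np.arange(len(contours)) * movie.frame_interval / 60.0,
                xy_um=cents * movie.pixel_size)
        speed, straightness = track_metrics(track)
        report["stages"]["track"] = {"speed_um_min": speed,
                                     "straightness": straightness}
        done.add("track")

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report


def measure_decay_length(params_list, band_um: float | None = None,
                         window="auto"):
    """Condition-level decay-length fit pooled over several cells.

    Each :class:`SimulationParams` in ``params_list`` describes one cell
    (movie); per cell, the membrane frame is segmented, the polarity
    axis estimated, and the time-averaged actin frame reduced to a
    cortical front-rear profile.  The per-cell profiles are averaged on
    a common grid and the transport-decay model is fitted once — a
    single cell's short fitting window leaves the three-parameter fit
    poorly conditioned, so conditions are always quantified over a
    population, as in any per-condition experimental comparison.
    """
    from .polarity import IntensityProfile

    profiles = []
    for params in params_list:
        movie, _ = simulate_cell_movie(params)
        _, mask = segment_movie(movie.membrane[:1],
                                pixel_size=movie.pixel_size)
        axis = polarity_axis(movie.actin[0], mask[0])
        profiles.append(front_rear_profile(
            movie.actin.mean(axis=0), mask[0], axis, movie.pixel_size,
            band_um=(band_um if band_um is not None
                     else params.cortex_thickness_um),
            statistic="median"))
    grid = profiles[0].positions_um
    pooled = np.mean([np.interp(grid, p.positions_um, p.intensities)
                      for p in profiles], axis=0)
    return fit_decay(IntensityProfile(positions_um=grid,
                                      intensities=pooled), window=window)


def consecutive_angles_experiment(angle_sigma_deg: float, n_seeds: int,
                                  seed0: int = 0, n_frames: int = 80,
                                  n_blebs: int = 4,
                                  spacing_s: float = 9.0) -> np.ndarray:
    """Angles between consecutive detected blebs across many synthetic
    cells whose scheduled bleb angles are wrapped-normal about the front
    with spread ``angle_sigma_deg``.

    Each seed renders one movie, segments it, builds the smoothed front
    series, detects blebs and measures the centre-to-initiation angles
    of consecutive event pairs; the pooled angle sample over all seeds
    is returned.  The contrast between a narrow and a broad spread is
    the synthetic analogue of the coordinated-vs-uncoordinated blebbing
    comparison between control and adhesion-depleted cells.
    """
    from .synthetic import default_bleb_schedule

    angles: list[float] = []
    for i in range(n_seeds):
        schedule = default_bleb_schedule(
            n_blebs, t_start=5.0, spacing_s=spacing_s,
            angle_sigma_deg=angle_sigma_deg, seed=seed0 + i)
        params = SimulationParams(n_frames=n_frames,
                                  seed=seed0 + 100_000 + i,
                                  bleb_schedule=schedule,
                                  store_flow=False)
        movie, _ = simulate_cell_movie(params)
        contours, masks = segment_movie(movie.membrane,
                                        pixel_size=movie.pixel_size)
        cents = [m.centroid() for m in masks]
        front = front_angle_series(movie.actin, masks, cents,
                                   movie.frame_interval)
        events = detect_blebs(contours, front, movie.frame_interval,
                              movie.pixel_size)
        if len(events) >= 2:
            angles.extend(consecutive_bleb_angles(events, contours))
    return np.asarray(angles, dtype=float)


def report_hash(report: dict) -> str:
    """Content hash of a report (stable across identical runs)."""
    return hashlib.sha256(
        json.dumps(report, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]
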