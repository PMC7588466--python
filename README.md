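# blebflow

Quantitative analysis of bleb-driven cell migration from two-channel
(membrane + actin) fluorescence time-lapse movies, together with a
ground-truth-annotated synthetic movie generator so every stage can be
validated without microscopy data.

Bleb-migrating cells (such as primordial germ cells) polarize by
enriching cortical actomyosin at their front. Contractility drives a
retrograde cortical actin flow at speed *v*; adhesion to neighbouring
cells opposes that flow with an effective friction *γ*, so
*v* = *F*<sub>contraction</sub>/*γ*. Actin transported rearward
depolymerizes at a constant rate *k*₋, and mass conservation of the flux
*j* = *v·c* then forces an exponential steady-state profile behind the
front,

&nbsp;&nbsp;&nbsp;&nbsp;*I*(*x*) = *I*₀ · exp(−*x*/*λ*) + *I*<sub>BG</sub>,&nbsp;&nbsp;&nbsp;&nbsp;*λ* = *v*/*k*₋ = *F*<sub>contraction</sub>/(*γ·k*₋),

so the decay length *λ* scales inversely with friction: depleting the
adhesion receptor lengthens the actin tail and delocalizes the
bleb-prone region. The package measures every quantity in this picture:

- **`synthetic`** — renders blebbing-cell movies (0.286 µm/px, 500 ms
  frames, ~10 µm cell, 1.7 µm cortex) with known flow speed, decay
  length, bleb schedule, contours and track.
- **`segmentation`** — Gaussian blur (σ = 3 px), Otsu threshold, hole
  filling, largest component, sub-pixel contour snapped to the membrane
  ridge.
- **`flow`** — dense variational optical flow (TV-L1) calibrated to
  µm/min, plus kymograph reslicing (line width 4) and the trace-angle
  velocimetry *v* = (µm/px ÷ s/frame) · 1/tan α.
- **`cortical`** — intensity-weighted polarity axis, leading-edge region
  seeding, RK4 advection of regions through the velocity field,
  *n* = 4 equal-arc cortical partitions of 1.7 µm thickness, and the
  time-averaged projected velocity v̄ = d̄/ΔT over the ΔT = 10 s window
  before each bleb (retrograde motion positive).
- **`polarity`** — front-rear intensity profiles, the five-sector F/M
  polarity ratio, perimeter marker/membrane ratio profiles, and
  migration-track speed/straightness.
- **`transport`** — the transport-decay model: analytic solution,
  nonlinear fit of (*I*₀, *λ*, *I*<sub>BG</sub>) on the window from
  2 µm behind the intensity peak to the 50 %-of-peak crossing, an
  upwind finite-difference PDE oracle for *λ* = *v*/*k*₋, and
  control-vs-knockdown decay-length comparison.
- **`blebs`** — bleb detection as prominent maxima of centre-of-mass
  speed, event angles from the maximal outward edge velocity relative
  to the σ = 25 s smoothed actin front, bleb frequency, consecutive-bleb
  angles and angular histograms.
- **`pipeline` / `cli`** — YAML-configured end-to-end orchestration
  (`blebflow run`), per-stage subcommands, deterministic reports.

## Worked example

```python
from blebflow import (fit_decay, front_rear_profile, polarity_axis,
                      segment_frame)
from blebflow.synthetic import SimulationParams, simulate_cell_movie

params = SimulationParams(n_frames=490, seed=1,
                          actin_decay_length_um=7.0,
                          retrograde_speed_um_min=6.0)
movie, truth = simulate_cell_movie(params)
_, mask = segment_frame(movie.membrane[0], pixel_size=params.pixel_size_um)
axis = polarity_axis(movie.actin[0], mask)
profile = front_rear_profile(movie.actin.mean(axis=0), mask, axis,
                             params.pixel_size_um, band_um=1.7,
                             statistic="median")
fit = fit_decay(profile)
print(f"lambda = {fit.lam:.2f} um  (truth {truth.true_decay_length_um})")
print(f"window = {fit.window[0]:.1f}-{fit.window[1]:.1f} um, "
      f"r^2 = {fit.r_squared:.3f}")
```

prints (one 490-frame cell, seed 1):

```
lambda = 7.09 um  (truth 7.0)
window = 2.0-5.7 um, r^2 = 1.000
```

A single cell's short fitting window leaves the three-parameter fit
with an intrinsic spread of roughly ±15 %, which is why condition-level
comparisons pool profiles over several cells
(`blebflow.pipeline.measure_decay_length`); pooled over eight cells the
same measurement returns λ within a few percent of truth.

The full pipeline on one synthetic cell:

```bash
blebflow run --seed 3 --out results/
```

writes `report.json` with segmentation, flow, projected-velocity,
profile/fit, kymograph, bleb and track sections.

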