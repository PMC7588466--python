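# Methods

This note records the models, conventions, numerical choices and known
limitations of the package, in the order data flows through it.

## Coordinate and unit conventions

Images use the raster convention: origin top-left, x rightward
(columns), y downward (rows). Angles are computed with `atan2(dy, dx)`
in this frame; perimeter angles are reported relative to the front
direction and folded to [0°, 180°] where only the deviation from the
front matters. Contours are simple closed polygons with positive
shoelace area in this frame. Velocities are µm/min throughout; lengths
µm; times s (tracks use minutes, matching migration-rate conventions).
The polarity axis **p** is a unit vector pointing front → rear, so
retrograde (rearward) motion projects positively.

## Synthetic movie generator

The generator renders the statistical structure the analyses assume,
not membrane mechanics:

- **Geometry.** A circular cell (default radius 10 µm) at 0.286 µm/px.
  Frame interval 500 ms, default 490 frames. The front direction
  defaults to 30° — deliberately off-lattice, since a real cell's
  polarity is arbitrary with respect to the camera grid and exact
  axis/grid alignment maximizes raster aliasing in every downstream
  profile.
- **Membrane channel.** A Gaussian-profile ring (σ 0.4 µm) on the cell
  outline plus a dim cytosolic plateau.
- **Actin channel.** A cortical band (1.7 µm) whose above-background
  envelope decays exponentially with decay length λ\* away from the
  front. Two decay coordinates are supported: `axial` (default;
  distance along the front-rear axis, the transport model's own
  coordinate) and `arc` (arc length along the cortex). The band's
  inner edge fades into the cytosol over ~1 px rather than stepping —
  a hard step would alias against any sub-pixel band-boundary estimate
  downstream. Background I_BG\* fills the interior.
- **Flow and texture.** The envelope is static (the front
  polymerization source balances transport and decay) while a
  multiplicative speckle texture rides on it, streaming away from the
  front at the retrograde speed v\* on both sides; the two sides carry
  independent speckle phases. The texture is a band-limited harmonic
  sum (default harmonics 8–40 of the half-perimeter, amplitude 0.3)
  and is renormalized per frame so the above-background band total is
  exactly conserved in the bleb-free case — the physical counterpart
  of the front source balancing outflow and depolymerization. The
  ground-truth velocity field is tangential in the band (±v\* away from
  the front), zero in the deep cytoplasm, with an optional radial
  outflow under growing blebs (cytoplasmic influx).
- **Blebs.** Outward radial bumps with cosine-tapered angular support
  (half-width 15°), growing over 25 % of their lifetime (default 6 s)
  and retracting over the rest, with transient local depletion
  (default 50 %) of the cortical actin envelope. Ground-truth event
  time is the scheduled onset; the maximal growth rate — what
  centroid-velocity detection responds to — occurs ~0.75 s later,
  inside the ±1 s matching tolerance used in validation. Re-blebbing
  at the same angle within a refractory window is rejected.
- **Noise.** Additive Gaussian (default sd 2, i.e. 2 % of the actin
  peak) or optional Poisson mode.

What the generator does **not** emulate: cell shape irregularity and
elongation, photobleaching, depth effects, membrane folds, neighbour
cells, and tissue drift. Passing tests therefore demonstrate
correctness of the measurement chain on data obeying the model's
assumptions, not robustness to every real-microscopy artifact.

## Segmentation

Gaussian blur (σ = 3 px) → Otsu threshold → hole filling → largest
connected component (ties broken by smallest centroid row, then
column) → marching-squares contour at the Otsu level. Because a bright
membrane *ring* thresholds into a band straddling the true outline, the
Otsu contour sits half a band width outside the cell; each vertex is
therefore snapped along its normal to the local intensity ridge
(parabolic sub-pixel refinement), and the mask is re-rasterized from
the refined polygon so mask and contour stay mutually consistent.
Vertices whose profile increases monotonically inward (filled,
ridge-free objects) are left at the thresholded boundary, so disk
phantoms are unaffected. On ring phantoms this recovers the enclosed
area to ~1 %.

## Flow estimation

`estimate_flow` wraps scikit-image's TV-L1 variational optical flow (a
brightness-constancy data term with total-variation regularization,
deterministic) behind a calibrated contract: frames are jointly
normalized, the solver runs on the full frame, the result is converted
to µm/min and flagged valid only inside the cell mask. The default
smoothness weight (`regularization=0.05`, the solver's native
attachment of 15) recovers the generator's cortical flow speed to a few
percent when averaged over several frame pairs. A `ground_truth`
backend returns an injected field verbatim so advection and projection
can be tested independently of flow accuracy. The synthetic-data
recovery check compares the mean tangential speed in the cortical band
against v\* — the projected v̄ of a front region is geometrically
smaller (it averages the axial component of a tangential flow), so v\*
calibration is checked on speed, not on v̄.

## Kymographs

Reslicing samples the movie along a line at 1 px steps, averaging
across `width` (default 4) parallel offsets. Trace angles are found by
a directional line-integral sweep (a Radon-style scoring restricted to
the spatial window of interest): for each candidate angle α between
trace and spatial axis, the maximal line-mean over perpendicular
offsets is recorded; genuine traces keep their amplitude under aligned
integration while structureless intensity averages down, so peaks are
accepted above `contrast_k` (default 2) times the image's intensity
standard deviation. Lines with less than 70 % in-window coverage are
excluded (a partially covered line scores on a handful of samples).
α = 90° (a time-parallel trace, zero speed) is handled at the sweep
boundary. Speeds follow v = (pixel size / frame interval) · 1/tan α,
reported in µm/min. A manual angle override reproduces the classic
manual measurement; a per-frame exclusion list allows dropping
blebbing time points.

## Polarity axis

The axis derives from the intensity-weighted second moments of the
masked pixels. For clearly elongated distributions (eigenvalue ratio
≥ 1.5) the principal eigenvector is used, oriented by the intensity
asymmetry. For round cells the eigenvector basis is noise-dominated —
worse, a front-enriched cortical *band* has its major axis
perpendicular to the polarity (the band's tangential spread at the
front dominates) — so the axis is instead taken from the displacement
of the intensity-weighted centroid relative to the geometric centroid,
which points squarely at the enriched front. Distributions that are
both isotropic and symmetric raise "axis undefined", and callers may
supply a manual axis.

## Region tracking and projected velocity

Tracked regions are dense point samples (default 1 point per 0.25 µm²)
rather than meshes; spatial means over valid points stand in for
area-normalized integrals, with accuracy set by sampling density.
Advection integrates dx/dt = v(x, t) by RK4 with sub-steps of at most a
quarter frame interval, bilinear interpolation in space and linear in
time; points leaving the field's valid domain are frozen and excluded
from subsequent means, preventing extrapolation outside the flow's
domain of validity. The cortical partition splits the contour at equal
arc-length breakpoints with region 1 centred on the front point
(labels front / centre-front / centre-back / back for n = 4, thickness
1.7 µm inward). The projected measure records the spatial mean of v·p
at each sample time and integrates over the ΔT = 10 s window before a
bleb by the composite trapezoidal rule; v̄ = d̄/ΔT holds exactly by
construction. The time integral of spatial means is divided by ΔT
literally; weighting by the instantaneous region size differs
negligibly for near-incompressible bands.

## Front-rear profiles and the decay fit

Profiles average masked intensity in 1 px slabs perpendicular to the
axis. Each slab is positioned at the mean axial coordinate of its own
pixels, and an optional cortical-band restriction (with a one-pixel
inset guarding against mask-boundary spillover) plus a median slab
statistic make the profile robust to the handful of edge pixels per
slab; the median variant is the pipeline default for transport-model
fits. A threshold option ("otsu" or absolute) excludes dim cytosolic
pixels, reproducing the zero-and-exclude convention of per-row
profiling plugins.

The decay fit minimizes least squares of I(x) = I₀·e^{−(x−x₀)/λ} + I_BG
with positivity bounds (trust-region reflective; the bounded
continuation of the classic Levenberg–Marquardt fit), initialized from
the tail minimum (I_BG), the windowed peak (I₀) and the log-linear
slope (λ), with deterministic multi-starts keeping the lowest-SSR
solution — the short window makes the surface shallow with degenerate
corners. The automatic window runs from 2 µm behind the intensity peak
to the first crossing below 50 % of the raw peak; when the background
exceeds half the peak the cutoff is recomputed relative to the
background-subtracted peak. Fits with λ above ten window spans or
vanishing amplitude are reported as non-converged ("unresolved on
window"). r² is evaluated on the fitted window only.

Two measurement regimes matter. (1) *Parameter recovery* on standalone
profiles fits the full profile extent (manual window), where the
three parameters are well conditioned: at 2 % noise the median λ̂ bias
is ~1 % and the IQR ~6 %. (2) *Cortical movie profiles* use the
automatic window, which spans only ~0.4–0.7 λ; there a ±15 % per-cell
spread is intrinsic (the residual valley across ±15 % in λ is < 0.3 %
of the signal range), so condition-level decay lengths are always
measured on a profile pooled over several cells
(`measure_decay_length`, default 8 cells per condition in the
acceptance analysis), mirroring per-condition pooling in experimental
comparisons. Time-averaging each movie's actin channel before
profiling removes the advecting speckle.

## Transport PDE oracle

∂c/∂t = −v ∂c/∂x − k₋c is integrated by first-order upwind differences
with an influx boundary v·c(0) = source. The discrete steady state is
an exact geometric decay with λ_dx = dx / ln(1 + k₋dx/v) =
(v/k₋)(1 + k₋dx/2v + …), so the decay-length error is first order in
dx — the convergence check in the tests measures exactly this. CFL
violations are rejected with a suggested dt.

## Bleb detection and coordination

Centre-of-mass speed between consecutive (360-point resampled)
contours is scanned for peaks with prominence above
max(k·1.4826·MAD, 2 µm/min), k = 3, separated by ≥ 2 s. The absolute
floor exists because a purely relative MAD rule flags noise peaks on
protrusion-free movies; both knobs are configuration. Each event is
timestamped at the midpoint of the centroid step its speed sample
measures. Peaks whose
dominant edge motion is inward are discarded as retraction recoils —
blebs are outward events. Per event, each current contour point is
matched to its nearest predecessor point and the displacement projected
on the outward normal; the maximum identifies the initiation point, and
its angle about the centroid minus the smoothed front angle, folded to
[0°, 180°], is the event angle.

The front series takes the per-frame argmax of the angular actin
distribution — sector means over a thin perimeter band, anti-aliased
by 3×3 pixel subdivision and circularly smoothed over 10° — then
smooths over time with a σ = 25 s Gaussian applied to unit vectors
(cos θ, sin θ) and renormalized, the standard wrap-safe construction.
Consecutive-bleb angles connect each event's initiation point to its
own frame's cell centre. The coordination experiment contrasts narrow
(σ = 15°) and broad (σ = 60°) front-centred scheduled angle
distributions via the fraction of consecutive angles within 40°,
pooled over 50 cells per condition (80-frame movies, four blebs
~9 s apart — the contrast is scale-free, so short movies suffice and
keep the analysis fast).

## Pipeline

`run_pipeline` executes simulate → segment → flow → blebs → project →
profile/fit → kymograph → track with declared stage dependencies,
records failing stages and skips their dependents, and emits a
JSON-serializable report with a provenance block (config hash, seed,
version); identical config + seed gives an identical report hash. The
pipeline kymograph line runs parallel to the polarity axis along a
cortical chord (within ~1 µm of the border) rather than through the
cell centre: tangential cortical flow has no component along the
centre line at the apex, whereas along the chord the speckle traces
slope at the retrograde speed. Kymograph angle detection there uses
per-column temporal detrending to remove the static envelope.

## Known limitations

- The synthetic cell is circular; shape-driven behaviours (elongation,
  polarity from geometry) are untested.
- Optical flow accuracy is quoted for the default texture; very low
  SNR or large inter-frame displacements (> ~2 px) degrade it.
- The single-cell automatic-window decay fit is reported with its
  intrinsic spread; per-cell λ values should not be over-interpreted
  without pooling.
- Drift correction is a constant-velocity helper only; no tissue-drift
  model is included.
- Bleb neck geometry, lifetimes and retraction kinematics are out of
  scope.
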