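# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic-data tests demonstrate.

## Simulator

### Transport model

Molecules are independent.  Positions live on a 1-D axis with the origin
at the spindle center and poles at ±L/2 (L = `spindle_length`, default
10 μm, a typical HeLa metaphase spindle).  The state per molecule is
(position, bound flag, motor state, fluorescent flag).  Updates use a
fixed sub-step `dt_sim` (default 0.1 s) with exponential-waiting-time
transition probabilities, `1 − exp(−k·dt)`; at the default rates
(≤ 1 s⁻¹) the first-order discretization error is below 1%.  An exact
event-driven scheme was considered and rejected as needless complexity
at these rates.

Per sub-step:

- **Unbound** molecules take a Gaussian diffusion step of sd
  `sqrt(2 D dt)` and reflect at the field boundary.  D defaults to
  15 μm²/s, a realistic cytoplasmic diffusion coefficient for a free
  GFP-fusion protein (free GFP is ~25 μm²/s; larger fusions are slower).
- **Binding** occurs on the spindle (|x| ≤ L/2) at
  `k_on_base` (default 0.3 s⁻¹), multiplied by `k_on_chrom_boost`
  inside the chromosome band (|x| ≤ `chromosome_band_halfwidth`,
  default 1 μm).  The boost is a minimal stand-in for the
  chromosome-centered Ran-GTP gradient.  With the default
  k_on = 0.3 s⁻¹ and k_off = ln2/25 s⁻¹ ≈ 0.028 s⁻¹ the equilibrium
  bound fraction is ≈ 0.92, i.e. a strongly spindle-enriched reporter.
- **Unbinding** uses a scalar `k_off` or a per-zone (pole,
  intermediate, chromosome) triple, zones being equal thirds of each
  half-spindle — the same partition the analysis uses.
- **Advection**: bound non-motor molecules move poleward (away from
  x = 0, sign(0) taken as +) at `flux_velocity`; molecules that rolled a
  motor state when they bound move at their motor's velocity instead.
  Motor states are assigned per binding event with probabilities
  `p_motor_poleward` / `p_motor_equatorward` (equatorward only outside
  the chromosome band, where such a run is meaningful).  Boundary
  rules: crossing a pole clamps the molecule at the pole and unbinds
  it; an equatorward motor reaching the chromosome-band edge stops
  there and drops its motor state.  These rules keep trajectories
  physical; nothing in the modeled experiments constrains them further.

Photo events flip fluorescence flags (bright→dark for a bleach,
dark→bright for an activation) inside a half-spindle or a 2-μm-wide
axis-perpendicular stripe, each molecule independently with the stated
efficiency.  The reporter starts bright for FRAP-style runs and dark for
photoactivation-style runs (`reporter_initially_bright`).

### Rendering

The reporter channel bins fluorescent molecules to the nearest pixel
(0.1 μm), convolves with a Gaussian point-spread of sd 1 px, scales by
`photons_per_molecule` and adds `background_level`; Poisson shot noise
and Gaussian read noise follow.  The transverse coordinate is a static
per-molecule jitter fraction times the spindle half-width — deliberately
*not* tapered with the spindle outline, so that a fixed-width profile
band captures a constant fraction of molecules at every axial position
and band-averaged intensity stays proportional to linear density.  The
reference channel renders a static elliptical spindle envelope with a
Gaussian dip (35% deep) at the chromosome band — the "gap" in
microtubule staining at the chromosome plate — re-noised each frame.
There is no tubulin turnover: the reference channel exists as a spatial
landmark only.

All randomness flows from one `numpy.random.Generator`; a fixed
`rng_seed` gives bit-identical stacks.

### Experiment presets

The presets encode the study conditions the simulator emulates:

- `frap_preset`: one pre-bleach frame, bleach of one half-spindle (95%
  efficiency) at frame 1, then 5-s frames to 120 s; 20,000 molecules;
  transport off; uniform k_off = ln2/25 s⁻¹; 20 s of kinetic burn-in
  before the first frame so binding is at steady state.
- `frap_zone_preset`: same, with chromosome-boosted *exchange* — a 4×
  on-rate boost (localization) plus per-zone off-rates giving half-lives
  of 40/30/20 s for pole/intermediate/chromosome.  A boosted on-rate
  alone cannot reorder recovery rates: in the reaction-dominant regime a
  zone's single-exponential recovery rate is its k_off regardless of
  k_on, so the faster chromosome-zone recovery that motivates this
  preset is configured where it physically lives, in the off-rates.
- `pa_flux_preset` / `pa_poleward_preset` / `pa_equatorward_preset`:
  dark reporter, a 2-μm activation stripe at frame 1 (near the
  chromosome band at +1.8 μm, or near a pole at +3.6 μm), 5-s frames
  for ~45 s, 15,000 molecules.  These run in the transport-dominated
  limit (k_off = 0 over the tracking window): with appreciable turnover
  the simulator's unbound pool — confined to a closed 2-D field rather
  than diluting into a 3-D cytoplasm — rebinds across the whole spindle
  and builds a background that no single-Gaussian tracker can fully
  reject.  Real pulses lose molecules to a much larger volume, so the
  coherent-pulse limit is the faithful emulation of a trackable
  experiment.  The flux preset advects at 0.69 μm/min; the motor presets
  give every bound molecule a motor (1.53 μm/min poleward, or
  2.94 μm/min equatorward), so the configured pulse velocity is the
  known truth the analysis must recover.

## Image preparation

- **Registration** is rigid (rotation + translation), frame 0 as the
  target, estimated on the reference channel and applied to both
  channels.  Rotation is found by maximizing the phase-correlation peak
  over a coarse 1° grid (±15°) with bounded scalar refinement;
  translation by upsampled phase cross-correlation (1/50 px).  On
  synthetic transforms this recovers shifts to <0.1 px and rotations to
  <0.1°.
- **Segmentation**: Otsu threshold on a σ = 2 px Gaussian-smoothed
  copy of the reference frame, largest connected component, holes
  filled.  A mask covering more than half the image is rejected rather
  than silently inverted.
- **Axis**: the mask's principal axis (PCA of pixel coordinates);
  poles are the extremal mask points within 2 px of the axis line,
  averaged over the extreme 1-px slice (robust to blunt thresholded
  tips).  A mask with axis ratio < 1.2 has no meaningful axis and is
  rejected.  The chromosome band is the half-depth extent of the
  central trough of the axial reference profile (searched in the middle
  40% of the span), or user-supplied coordinates.
- **Zones**: each half (split at the axis midpoint) is divided into
  three equal-length axial bins, pole → intermediate → chromosome.
  The source experiments never define these boundaries; equal thirds is
  parameter-free and symmetric.  The half containing the bleach
  geometry is the bleached half; a geometry overlapping both halves by
  more than 40% each is ambiguous and rejected.
- **Profiles**: intensity averaged across a band of fixed physical
  width (default 2 μm) perpendicular to the axis, sampled at 1-px steps
  pole to pole; samples outside the image are dropped and the profile
  flagged as clipped.
- **Background**: a user-supplied ROI, else the per-frame 1st-percentile
  pixel value of the reporter channel.

## FRAP kinetics

Double normalization uses the whole spindle as the reference region.
Full-scale normalization is applied to bleached ROIs only; decay fits on
unbleached ROIs use the double-normalized trace, since rescaling by
bleach depth is meaningful only where there is one.  Whether per-zone
fits should be full-scale normalized per zone or per half is not
externally constrained; it is applied per fitted ROI.

One-phase fits use `scipy.optimize.curve_fit`, parameterized in
(t − t0) so the first post-bleach frame anchors the curve.
Initialization: the rate from the time the trace crosses half its
terminal change, the plateau from the mean of the last three points;
k is bounded to (1e-5, 10) s⁻¹.  A failed optimization returns
`converged = False`, never an exception; fits with R² < 0.8 are flagged
(`quality_ok = False`) but not excluded — flagging is a reviewable
choice, silent exclusion is not.  `halflife = ln 2 / k` exactly.

## Photoactivation kinematics

Gaussian profile fits include a constant offset by default (robustness
to diffuse background); an offset-free mode reproduces the plain
single-Gaussian convention.  Tracking is windowed: each frame after the
first is fitted within ±2.5 μm of the previous center, keeping the fit
on the pulse once exchanged molecules have spread.  Non-converged
frames are dropped and counted; at least 4 usable frames are required.

The center-vs-time track, re-expressed as distance from the landmark
(increasing away from it), is fitted with a quadratic; u0 = c1 and
a = 2·c2 in μm/min and μm/min².  `velocity_at_reference` solves
x0 + u0·t + a·t²/2 = 0 with cancellation-free quadratic roots (the
small root via the Citardauq form, so a → 0 degrades smoothly to the
uniform-motion −x0/u0) and takes the real root of smallest magnitude —
the nearest extrapolation, backward in time where the pulse moves away
from the landmark.  Both roots are kept for audit.  Velocities are
reported signed, with poleward positive; cross-condition averages use
magnitudes.  The negative correlation of raw u0 with x0 that motivates
the extrapolation can be inspected with the Spearman diagnostic in
`spindleflux.stats`.

## Statistics

Mann-Whitney U is two-tailed, exact (full null distribution) for
combined n ≤ 12 without ties, normal approximation with tie correction
otherwise; the exact/asymptotic switch point is a convention, not a
measured quantity.  Spearman's rho uses midranks with the t-based
two-tailed p.  Profile averaging rescales each profile to a [0, 1]
pole-to-pole fraction, interpolates to a 100-point grid, max-normalizes
per cell, and computes a per-point t-distribution 95% CI.  Star codes:
`*` ≤ 0.05, `**` ≤ 0.01, `***` ≤ 0.001, `****` ≤ 0.0001.  No
multiple-testing correction is applied.

## Problem sizes and what the tests show

End-to-end checks run at 20,000 molecules (FRAP) and 15,000 (PA) with
cohorts of 3–14 simulated cells; these sizes give half-life recovery
within a few percent of truth while a full test run stays in minutes.
Passing them demonstrates that the pipeline is internally consistent —
it recovers the rates and velocities the generator put in, under the
generator's assumptions.  It does not demonstrate robustness to what
the generator omits: 3-D optics and defocus, acquisition photobleaching,
chromosome and spindle movement beyond rigid drift, spindle elongation,
tubulin turnover in the reference channel, spatially structured
background, or reaction–diffusion coupling in FRAP recovery (the fits
are single-exponential by design, matching the analysis convention they
implement, and will mis-state half-lives when recovery is strongly
diffusion-limited).

## Known limitations

- The simulator's supplementary role is a stated stand-in of our own
  design; it is a minimal transport model, not a fitted mechanistic
  model of any particular protein.
- The 2-D closed-field unbound pool exaggerates rebinding background in
  long photoactivation runs (see the preset rationale above).
- Zone boundaries (equal thirds) and the half-split at the axis
  midpoint are conventions; results for spatial kinetics depend on
  them.
- The equatorward-motor stop rule (stall at the chromosome-band edge)
  compresses pulses that reach the band; kinematic fits should use
  tracking windows that end before pile-up dominates.
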