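# spindleflux

Quantitative kinetics of spindle-bound fluorescent reporters from
two-channel live-cell time-lapse microscopy.

Microtubule-associated proteins such as HURP exchange rapidly on the
metaphase spindle and are also transported along it — by poleward
microtubule flux and, for some proteins, by motor complexes moving
poleward or back toward the chromosomes.  Two classic experiments probe
this: **FRAP** (bleach half the spindle, watch fluorescence return as
molecules exchange) measures binding turnover, and **photoactivation**
(switch on a 2-μm stripe of PA-GFP, track the marked pool) measures
directed transport.  `spindleflux` implements the complete analysis for
both, together with a ground-truthed stochastic simulator that stands in
for live-cell data, so every stage of the pipeline can be validated
against known rates and velocities.

The package is aimed at cell-biology labs analyzing spindle FRAP /
photoactivation stacks, and at anyone who wants a tested, reusable
implementation of this analysis with a simulator to calibrate it.

## The models

**FRAP normalization and turnover.**  After background subtraction,
each ROI trace is double-normalized against the whole spindle to cancel
acquisition fade,

$$I_{norm}(t) = \frac{I_{ref}(t_{pre})}{I_{ref}(t)}\cdot\frac{I_{roi}(t)}{I_{roi}(t_{pre})},$$

and bleached ROIs are additionally full-scale normalized so the first
post-bleach frame ($t_0$) is 0 and the pre-bleach level is 1:

$$I_{fs}(t) = \frac{I_{norm}(t) - I_{norm}(t_0)}{1 - I_{norm}(t_0)}.$$

Recovery is fitted with a one-phase association
$y = P\,(1-e^{-k(t-t_0)})$ and the unbleached half's decay with
$y = P + A\,e^{-k(t-t_0)}$; the half-life is $t_{1/2} = \ln 2 / k$.
The spindle is compartmentalized into six zones (pole / intermediate /
chromosome × bleached / unbleached half) for spatially resolved
kinetics.

**Photoactivation kinematics.**  Each frame's pole-to-pole intensity
profile (2 μm band width) is fitted with a Gaussian
$I(x) = c + A\,e^{-(x-\mu)^2/2\sigma^2}$ and the center $\mu(t)$ tracked.
Because the raw fitted velocity depends on where the stripe was placed,
the track is fitted with a second-order polynomial and extrapolated with
the constant-acceleration equations of motion

$$x = x_0 + u_0 t + \tfrac12 a t^2, \qquad u_c = u_0 + a t,$$

to the time $t^\*$ at which the pulse center would cross a common
landmark ($x = 0$: the chromosome edge, or the pole), giving the
reference-point velocity $u_c$ that can be averaged across cells.

**The simulator.**  A discrete-time Monte-Carlo of independent
molecules on the spindle axis: diffusion when unbound, binding with a
chromosome-proximal on-rate boost (the Ran-GTP pattern), unbinding at a
(optionally per-zone) off-rate, poleward advection of the bound lattice
at the flux velocity, and optional poleward/equatorward motor states.
Photobleach/photoactivation events and a two-channel camera render
(Poisson + read noise) produce calibrated TIFF stacks with the true
rates recorded alongside.

## Worked example

```python
from spindleflux.experiments import bleach_mask_for, run_pa_cohort
from spindleflux.frap import frap_experiment
from spindleflux.synthetic import frap_preset, pa_flux_preset, simulate

# one simulated FRAP cell: bleach the left half-spindle, 5-s frames to 120 s
cfg = frap_preset(seed=1)
stack, truth = simulate(cfg)
fits = frap_experiment(stack, bleach_mask_for(cfg), bleach_frame_index=1)
print(fits[["roi", "kind", "halflife_s", "plateau", "r2"]].round(2).to_string(index=False))
print(f"configured half-life: {truth.expected_recovery_halflife:.1f} s")

# a 7-cell photoactivation cohort measuring poleward microtubule flux
flux = run_pa_cohort(pa_flux_preset, seeds=range(1, 8))
print(f"flux = {flux.uc_poleward_um_min.abs().mean():.2f} "
      f"+/- {flux.uc_poleward_um_min.abs().std():.2f} um/min (n = 7)")
```

prints

```
                    roi        kind  halflife_s  plateau   r2
    bleached_chromosome association       24.19     0.99 0.99
          bleached_half association       26.28     0.97 1.00
  bleached_intermediate association       29.44     0.98 0.99
          bleached_pole association       25.41     0.94 0.99
  unbleached_chromosome       decay       23.95     1.01 0.99
        unbleached_half       decay       26.87     1.02 1.00
unbleached_intermediate       decay       30.07     1.03 1.00
        unbleached_pole       decay       27.57     1.00 0.99
configured half-life: 25.0 s
flux = 0.72 +/- 0.08 um/min (n = 7)
```

The bleached-half recovery half-life (26.3 s) recovers the configured
turnover (ln 2 / k_off = 25 s); the photoactivated-pulse analysis
recovers the configured 0.69 μm/min poleward flux.

## Command line

```sh
spindleflux simulate --config sim.yaml --out stack.tif --truth truth.json
spindleflux frap     --stack stack.tif --config frap.yaml --out fits.csv
spindleflux pa       --stack stack.tif --event event.yaml --landmark chrom_edge --out kinematics.csv
spindleflux report   --in measurements.csv --out report/
```

`fits.csv` columns: `roi, kind, k_per_s, halflife_s, plateau, amplitude,
r2, n_points, converged, quality_ok`.  `kinematics.csv` columns:
`cell_id, x0_um, u0_um_min, a_um_min2, t_star_min, uc_um_min,
uc_poleward_um_min, r2_quadratic, n_frames_used`.  `report/` contains
`summary.csv` (per-condition mean ± sd, n), `comparisons.csv` (pairwise
two-tailed Mann-Whitney with star codes `*` ≤ 0.05 … `****` ≤ 0.0001)
and a dot/bar plot.

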