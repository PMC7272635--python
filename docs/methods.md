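# Methods

This document describes the physical model, the numerical methods, the
synthetic-experiment design, and the verification strategy implemented in
`spheropore`.

## Physical model

### Electric field

The cell is a prolate spheroid (long semi-axis `a`, short semi-axes
`b = a / aspect_ratio`) centred in a cubic simulation box. A trapezoidal
voltage pulse (rise and fall each 1% of the duration by default) is applied
between two opposite box faces; the nominal field `E` is the applied
voltage divided by the box edge. The intra- and extracellular media are
homogeneous conductors with permittivity, governed by the transient
quasi-static continuity equation

    div( (sigma + eps0 epsr d/dt) grad V ) = 0

with sigma_i = 0.3 S/m, sigma_e = 1.0 S/m, epsr_i = epsr_e = 80 by
default.

### Membrane

The membrane (thickness d_m = 10 nm) is not meshed as a volume; it enters
as a **contact-impedance boundary condition** on the spheroid surface: the
normal current density through the membrane equals

    n . J = (1 / d_m) * ( sigma_m + eps0 eps_m d/dt ) * (V_i - V_e)

where `V_i - V_e = Um` is the transmembrane voltage, eps_m = 5, and
sigma_m is the (pore-dependent) membrane conductivity. The membrane
surface carries duplicated mesh nodes (an intracellular and an
extracellular copy at identical coordinates) so `Um` is a nodal degree of
freedom difference.

### Pore dynamics

The areal pore density N(t) on each membrane patch follows the asymptotic
pore equation

    dN/dt = alpha * exp(x) * (1 - (N / N0) * exp(-q x)),   x = (Um / Vep)^2

with alpha = 1e9 m^-2 s^-1, N0 = 1.5e9 m^-2, Vep = 0.258 V, q = 1.46.
Pores make the membrane conductive:

    sigma_m = sigma_m0 + N * (2 pi r_p^2 sigma_p d_m) / (pi r_p + 2 d_m)

with sigma_m0 = 3e-7 S/m, pore radius r_p = 0.76 nm, and sigma_p the
logarithmic mean of the intra/extracellular conductivities,
`(sigma_e - sigma_i) / ln(sigma_e / sigma_i)` (= 0.581 S/m for the
defaults). This closes the two-way coupling: the field charges the
membrane, Um creates pores, pores raise sigma_m, which discharges Um.

### Dose scaling

Across pulse durations, amplitudes are taken from a strength-duration
(iso-effect) curve. The built-in hyperbolic curve is

    E(t) = 520.9 + 1.43 / t_ms   [V/cm]

optionally multiplied by a scale factor (0.5 for the rounder-cell study
configuration); tabulated curves can be loaded from CSV and are
interpolated log-log without extrapolation.

## Discretisation

### Mesh

A structured, conforming tetrahedral mesh of one octant of the domain
(symmetry: the field axis and the two transverse mid-planes). Radial
construction: angular directions are generated by barycentric subdivision
of the coordinate octant; inside the cell, scaled copies of the spheroid
surface form shells graded toward the membrane (finest layer at the
membrane); outside, shells blend from the spheroid to the box surface with
geometric grading (ratio 1.7). Each prism between consecutive shells is
split into tetrahedra with diagonal choices keyed to global vertex indices
(consistent across neighbouring prisms, so the mesh is conforming). The
membrane carries duplicated node pairs; every membrane facet borders
exactly one intra- and one extracellular tetrahedron.

The `resolution` parameter sets both the angular spacing (via the
quarter-meridian arc length) and the radial layer thickness near the
membrane. The production default is 5 µm; see Verification for the
convergence measurement behind it.

Boundary conditions on the octant: driven box face at +V/2, field-axis
mid-plane at 0 (antisymmetry), all other faces natural (zero flux).

### Field solver

P1 (linear) elements, with the bulk sigma- and eps-weighted stiffness
matrices assembled per region. The membrane condition is lumped per node
pair with dual-patch areas (one third of each adjacent facet). Backward
Euler in time gives, per step,

    [K_sigma + K_eps/dt + M_mem(sigma_m/d_m + C_m/dt)] V = rhs(V_old, drive)

solved with a sparse LU factorisation (refactorised when dt or sigma_m
changes). Waveform breakpoints (pulse edges) are never stepped across:
steps are clamped and subdivided at them.

### Pore integrator

Over a step with frozen Um, the pore equation is linear in N with rate
`b = (alpha/N0) exp((1-q) x)` and equilibrium `N_eq = N0 exp(q x)`; it is
advanced exactly by the exponential integrator

    N_new = N_eq * (1 - exp(-b dt)) + N * exp(-b dt)

implemented with `expm1` and clamped exponents so arbitrarily large Um
excursions remain finite and positive.

### Coupling and adaptive stepping

Each time step iterates field-solve and pore-update to self-consistency in
sigma_m (geometric damping on sigma_m, relative Um tolerance 0.5%). Step
size starts at `min(rise_time/5, tau_charge/20, t_end/20)` and adapts to
keep the per-step change below 0.1 V in Um and 0.5 in log10 N, growing by
1.6x when comfortably below target.

## Analyses

### Pore counts, ratios, crossover, onset

The whole-cell pore count integrates the nodal density over dual patches,
multiplied by 8 (octant symmetry) and rescaled from the polyhedral to the
analytic spheroid area (so a uniform resting density integrates exactly to
N0 x surface area at any resolution). A membrane patch counts as
electroporated above 1e13 pores/m^2.

For each duration, the parallel/perpendicular pore-count ratio is formed;
the crossover is located by linear interpolation of log(ratio) in
log(duration) between the first sign-changing pair. Onset fields scan an
ascending field grid and report the first field whose end-of-pulse count
exceeds the resting count by 10%.

The named study configurations (`protocols.py`): A = aspect 1:4 with the
hyperbolic curve, B = aspect 1:2 with the 0.5-scaled curve, C = aspect 1:2
with the unscaled curve (twice the relative dose; shows no crossover).

### Synthetic ratiometric imaging experiment

Stands in for the wet-lab stage with known ground truth. Scenes are
two-channel (340/380 nm excitation) 15-frame stacks, one frame per 5 s,
pulse at 7 s, calcium peak 8 s later; cells are non-overlapping ellipses
with uniformly random elongation (1.4-5x) and orientation (0-90 deg to the
field axis), sampled away from the classification decision boundaries and
guaranteed to include at least one parallel and one perpendicular cell.
Each cell's peak 340/380 ratio rise is drawn from an effect model
(orientation-class x duration x field) plus Gaussian cell-to-cell
variability; pixel noise is additive Gaussian.

The analysis pipeline mirrors a real one: threshold the time-averaged
380 nm channel, label components, fit an ellipse from second-order image
moments, classify orientation (parallel: a > 2b and angle <= 20 deg;
perpendicular: a > 2b and angle >= 70 deg; otherwise unclassified), extract
the background-corrected ratio trace (x100), and report the
baseline-subtracted value at the peak frame. The per-experiment readout is
the mean parallel peak minus the mean perpendicular peak.

### Statistics

Treatment groups are compared to a control with the Kruskal-Wallis test
(tie-corrected) followed by Dunn's comparisons versus control: rank-sum z
with tie correction, two-sided p multiplied by the number of comparisons,
and flagged significant only when the omnibus test is significant at
alpha = 0.05. Measured calibration: single-comparison type-I error 0.050
(n = 10 per group, 3000 null simulations); with three treatment groups the
familywise rate is 0.028 (conservative, as Bonferroni-style control
intends).

## Verification

- **Uniform conductor**: with equal conductivities and a transparent
  membrane the potential is linear in the field direction (< 2% of the
  drive away from the chamfered box edges on a coarse mesh).
- **Steady-state membrane charging**: on a 45 µm sphere in a wide box the
  simulated |Um| matches the analytic 1.5 E R cos(theta) profile within 3%
  at the production resolution, and the charging time constant
  `R C_m (sigma_i + 2 sigma_e) / (2 sigma_i sigma_e)` (0.76 µs) within 3%.
- **Linearity and conservation**: with frozen sigma_m, doubling the drive
  doubles Um to machine precision; driven-face and mid-plane reaction
  currents balance at every step.
- **Pore ODE**: the exponential integrator under a prescribed
  charging-like Um(t) matches an LSODA reference solve to ~1e-8 relative.
- **Mesh convergence**: at (aspect 1:2, 3 µs, parallel, half-scaled curve)
  the end-of-pulse pore count changes by 1.5% under a 4 µm -> 2 µm
  resolution doubling (< 2%); the 5 µm production mesh sits 2.5% from the
  finest tested level, and crossover locations move only ~4% per
  refinement level.
- **Pipeline identity**: noiseless rendered scenes are recovered exactly
  (cell count, class; shape within pixel-discretisation error; peak equal
  to the ground-truth amplitude).

## Problem sizes and runtimes (one CPU)

| Task | Size | Time |
| --- | --- | --- |
| Octant mesh, 5 µm, aspect 1:4 | ~1.3k vertices | < 1 s |
| One coupled pulse, 1-10 µs | 30-80 steps | 2-12 s |
| Full crossover sweep (8 durations x 2 orientations) | 16 runs | 40-100 s |
| Onset scan, 100 µs, one orientation | 2-7 runs | 3-7 s |
| Synthetic scene render + analysis | 192x192x15x2 | ~0.3 s |

## Known limitations

- Pore radius is fixed (no pore-radius dynamics or resealing kinetics);
  post-pulse resealing is therefore not modelled.
- The membrane condition is lumped per node pair rather than assembled as
  a consistent surface mass matrix; the difference vanishes under
  refinement and is part of the measured convergence.
- At extreme durations (nanoseconds/milliseconds) the orientation ratios
  are exponentially sensitive to how close the disfavoured orientation is
  to its poration threshold, so their absolute magnitudes carry much
  larger uncertainty than the crossover locations.
- The synthetic experiment is a stand-in with a parametric effect model;
  it validates the analysis pipeline and statistics, not the biology.
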