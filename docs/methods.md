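# Methods

## Field model

The electric potential in the tissue is modelled by the Laplace equation
∇²Φ = 0 with uniform conductivity. This is the standard quasi-static IRE
planning model when conductivity changes are not fed back into the PDE: with
σ constant, σ cancels and the potential — hence the field distribution — is
conductivity-free. Measured conductivity changes (pre/post impedance
readings) are treated as cohort data and analysed statistically, not coupled
into the field solve. Nonlinear (field-dependent) conductivity, Joule
heating and pore dynamics are out of scope.

**Geometry.** Tissue cylinder of height 80 mm and diameter 20 mm, axis along
z. Two needle electrodes (1 mm diameter) run parallel to the axis at
x = ±s/2, with s = 5 mm read as **center-to-center** spacing (the common
clinical convention; an edge-to-edge mode is provided, giving s = 6 mm).
The 15 mm exposed segments are centered at the cylinder's axial midpoint;
insertion depth and orientation are not otherwise constrained by the study
description, and the symmetric axial arrangement was chosen as the maximal
symmetry reading of the published renderings. The energized electrode
carries Φ = V, the grounded one Φ = 0, and all remaining surfaces are
insulated (homogeneous Neumann).

**Discretization.** Voxel grid with staircase (voxel-center membership)
geometry; 7-point finite-difference Laplacian; Dirichlet values imposed on
electrode voxels; Neumann boundaries by ghost-cell mirroring (equivalent to
dropping the stencil connection). The assembled system is symmetric positive
definite; grids up to 40k unknowns are solved by sparse LU, larger grids by
Jacobi-preconditioned conjugate gradients run to an internal relative
residual of `tol × 1e-2` (default contract tol = 1e-8). Both routes are
deterministic. A connectivity pre-check raises a singular-system error for
floating tissue regions or a source/sink pair not joined through tissue.

**Verification.** Three closed forms back the solver: (i) the plane slab
(linear potential; reproduced to ~1e-15 relative with the direct solve and
< 1e-6·V with CG); (ii) the coaxial annulus Φ(r) = V·ln(R_out/r)/ln(R_out/R_in),
against which the staircased constant-voltage problem converges at first
order (the staircase boundary-location error is O(h)); and (iii) the same
annulus with the exact solution imposed as Dirichlet data on the staircase
voxels, which isolates the interior stencil and exhibits the expected
second-order convergence (observed order ≈ 2.1). Discrete current balance
(source flux + sink flux ≈ 0) and the maximum principle (0 ≤ Φ ≤ V) are
asserted on every converged solve in the suite.

## Field magnitude and ablation areas

|E| = |∇Φ| is computed with central differences (one-sided at grid edges)
after filling exterior voxels with their nearest interior value, which
approximates the insulated-boundary mirror and avoids spurious jumps at the
cylinder wall; the result is converted to V/cm. Planes are sampled by
trilinear interpolation at the grid's native spacing: the *coronal* plane
contains both electrode axes (the plane of maximal ablation cross-section);
the *axial* plane is perpendicular at the exposed midpoint.

The ablation area at threshold T is the area of {|E| ≥ T} measured by a
marching-squares-style rule: each sampling cell is split into four triangles
about its center average and the linear-interpolant superlevel area of each
triangle is accumulated exactly. Electrode cross-sections (where Φ is
boundary data and |E| undefined) are counted as ablated whenever any tissue
reaches the threshold; a threshold above the tissue maximum yields area 0.
scikit-image's contour finder provides an independent polyline route used
for export and cross-checks. The measured coronal area at 500 V/cm changes
by ~1.3% when the default 0.5 mm voxel is halved, and the linear-scaling
identity area(V, T) = area(V′, T·V′/V) holds across independent solves to
well below 0.1%.

**Relation to image-based planimetry.** With the geometry above, the model
yields 500 V/cm coronal areas of ≈ 132 / 152 / 169 mm² at 500 / 700 / 900 V.
Published planimetry of rendered field maps for this geometry reports
substantially larger absolute areas; notably, those published values are
mutually consistent with this model at a *single* effective threshold of
≈ 110 V/cm, i.e. they differ from the 500 V/cm superlevel sets by an
approximately constant field-calibration factor (≈ 4.5) rather than by a
geometric discrepancy, a pattern consistent with tracing the outer edge of
a rescaled color map rather than a specific isoline. The package therefore
reports the areas its model actually computes; the voltage ordering and the
linear-scaling identity — the calibration-free content — are reproduced
exactly. No internal threshold was adjusted to match published planimetry.

## Pulse protocol

Grouped schedules are generated from (pulse width, intra-group interval,
pulses/group, group count, group interval). "Pulse interval" is read as the
gap between pulse end and next onset (generator convention); an
onset-to-onset mode is provided since datasheets are ambiguous. The group
interval is the gap between a group's last pulse end and the next group's
first onset (onset-to-onset mode available). The study protocol gives 180
pulses and 18 ms on-time; the dose surrogate is V/d (900 V, 5 mm → 1800
V/cm). Delivered energy sums V·I·duration over pulses with per-pulse or
constant currents.

## Cohort statistics

The screening formula V = W²L/2 is used only for the enrollment filter
(strict exclusion above 1000 mm³) and the follow-up formula
V = π/6·f·(L·W)^{3/2}, f = 1.69, only for trajectories; the two are
deliberately not harmonized, mirroring their separate uses in the emulated
design. Both are exposed for either purpose.

Paired t, one-way ANOVA and Tukey HSD are implemented from the textbook
formulas (Tukey-Kramer form for unequal n) with p-values from scipy's t, F
and studentized-range distributions; degenerate inputs (zero variance)
return defined results with a warning flag rather than NaNs. Agreement with
scipy's independent implementations is asserted to ≥ 6 significant digits on
random fixtures, and a vectorized null Monte-Carlo (10,000 replicates)
verifies 5% type-I error for all three procedures (Tukey as family-wise
error, which the studentized-range construction controls exactly at equal n).

The fold change "relative to control" is ambiguous in common usage; the
default definition is the ratio of ratios
(treated_b/treated_a)/(control_b/control_a), with a treated-only alternative
selectable and the definition recorded in every output.

## Synthetic cohorts

The generator emulates the study design: 4 arms × 6 animals, measurement
days 0, 1, 3, 7, 12, 14, 21, 28. Choices, made once:

| parameter | default | rationale |
|---|---|---|
| baseline volume | lognormal, median 500 mm³, log-sd 0.65, truncated at 1000 | reproduces ≈ 14% oversize rate at the screening stage |
| control growth | exp(0.05/day) | ≈ 4-fold over 28 days, typical xenograft growth |
| 500 V profile | knots (0,1,7,28) → (1, 1.05, 0.68, 0.68) | early partial regression vs control, then constant |
| 700 V profile | knots (0,1,7,14,28) → (1, 1.05, 0.80, 0.39, 0.60) | deeper mid-study regression with late regrowth |
| 900 V profile | knots (0,1,28) → (1, 0.90, 0.17) | transient day-1 blip then continuous regression |
| measurement noise | lognormal, log-sd 0.15 | multiplicative caliper error, volumes stay positive |
| aspect ratio W/L | normal(0.75, 0.10) clipped to [0.3, 1] | typical subcutaneous tumor eccentricity |
| terminal weight (g) | control 1.31±0.22, 500 V 0.95±0.30, 700 V 0.70±0.30, 900 V 0.37±0.35 | end-point means/SDs; the middle arms interpolate between the two anchored arms |
| conductivity (mS/mm) | pre 0.30±0.05; increments 0.00±0.02 / 0.25±0.06 / 0.39±0.15 / 0.42±0.19 | post-treatment conductivity rise grows with voltage |

Profiles are piecewise linear in log-multiplier; caliper pairs are
back-solved from volumes through the follow-up formula (exact round trip).
All randomness flows from one master seed through named child streams
(baselines, noise, aspect, weights, body, conductivity, currents), recorded
in the table metadata. Current traces model I = V·G₀·(1 + drift·p/n)·noise
with upward conductance drift during the train.

What the generator does **not** emulate: any mechanistic link between
simulated field coverage and cell kill (none is available at this scale),
inter-animal correlation beyond the baseline, missing data/dropout, or
digit-preference in caliper readings. Passing pipeline tests therefore
demonstrate correctness of the analysis machinery under the emulated
statistical structure, not biological fidelity.

Generator validation: on noise-free data the log-linear fixed-effects fit
recovers the configured growth rate to 4 significant digits; with noise the
configured rate lies within ±2 SE in ≥ 93% of 500 replicates; over 200
default cohorts the analysis reports regression (final < initial) for the
900 V arm and growth for control in ≥ 95% of runs.

## Problem sizes and determinism

Default production grid 0.5 mm (≈ 2×10⁵ unknowns; a solve takes a few
seconds), refinement study at 0.25 mm (≈ 1.6×10⁶ unknowns); verification
problems run at a few thousand unknowns. Statistical calibration uses
10,000 null replicates; synthetic-pipeline properties use 200 cohorts.
Every pipeline stage is deterministic given its inputs and seed; analysis
reports are byte-identical across repeated runs.

## Known limitations

* Staircase electrodes limit near-electrode field accuracy to first order;
  areas at thresholds that hug the electrode surface need finer grids than
  the defaults.
* The uniform-conductivity model cannot capture the measured conductivity
  rise during treatment; dynamic-conductivity planning would change the
  field shape between electrodes.
* Absolute ablation areas depend on the field-threshold calibration
  discussed above; cross-study comparisons should rely on the
  calibration-free quantities (ordering, scaling identity) or state the
  threshold convention explicitly.
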