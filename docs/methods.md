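# Methods

## Physical model and assumptions

The sample is a homogeneous, isotropic solid cylinder in perfect contact with
two end electrodes; a rigid lateral wall is not modelled explicitly — its
thermal resistance is lumped into the overall surface coefficient U. Because
geometry, electrical loading and boundary conditions are all rotationally
symmetric, the fields are solved in the (r, z) half-plane (axisymmetric
formulation) rather than in 3D; this is exact for the continuous problem, not
an approximation.

Three processes are coupled:

1. **Quasistatic potential.** The thermal transient (minutes) is far slower
   than any electrical relaxation, so at each instant the potential satisfies
   ∇·(σ(T)∇V) = 0 with Dirichlet values on the electrodes (ΔV = 100 V by
   default, interpreted as the effective/RMS value) and zero normal current on
   the lateral surface and the axis. Electrode electrochemistry, contact
   impedance and frequency effects are out of scope.
2. **Heat transfer.** VHC(T)·∂T/∂t = ∇·(λ(T)∇T) + σ(T)|∇V|². The volumetric
   heat capacity VHC = ρ·C_p is used as a single measured product; ρ and C_p
   are never needed separately. Exterior faces are either insulated or lose
   heat by Newton cooling q = U(T − T_inf). By default the Robin loss acts on
   **all** exterior faces (both electrode ends and the lateral surface, each
   switchable): the cold regions observed in lossy runs concentrate at the
   electrode/lateral-surface junctions, which requires losses through both
   face families. No evaporation, moisture migration, phase change or
   radiation.
3. **Inactivation kinetics.** First-order log-linear decay with the classical
   D/z model: dN/dt = −(ln10/D(T))·N, D(T) = D_ref·10^((T_ref−T)/z). The
   decay-rate form follows directly from requiring that one D-value at
   constant temperature removes exactly one log cycle, and integrates in
   closed form to log₁₀(N₀/N) = F/D_ref with the sterility factor
   F = ∫10^((T−T_ref)/z)dt. Only thermal inactivation is modelled (no
   electroporation-like effects, no Weibull tails).

The **cold spot** is defined by accumulated lethality — the argmin-F cell —
not by instantaneous temperature: pasteurization credit is a time integral,
so the governing location is the least-*treated* one. The instantaneous
minimum temperature is traced as well.

## Discretization and numerics

Cell-centered finite volumes on a uniform (nr × nz) grid of annular cells
(volume 2πrΔrΔz). Face coefficients (σ, λ) use the harmonic mean of the
adjacent cells, preserving flux continuity across property jumps; the
symmetric positive-definite systems are solved by a direct sparse method.
Verified consequences (enforced by tests): discrete maximum principle for
both equations, equal electrode currents to 1e−8 relative, and exact
agreement with the series-resistor closed form for layered conductivity.

The Joule source is assembled from per-face dissipations G_f(ΔV_f)², split
evenly between the two adjacent cells (boundary faces assign fully to their
cell). This reduces to σ(V/L)² exactly for uniform conductivity and makes the
global identity Σ Q·vol = V·I hold to solver precision for arbitrary σ
fields, so energy audits close to round-off.

Time stepping is backward Euler (unconditionally stable) with properties
lagged one step; at the default dt = 0.5 s the per-step temperature change is
a fraction of a kelvin, so the lagged linearization is first-order consistent
with the scheme itself. An optional within-step fixed-point iteration
(tolerance 1e−3 K) exists for convergence studies and changes the default
runs by well under 0.05 K. The Robin closure combines U in series with the
half-cell conduction resistance, h = 1/(1/U + d/(2λ)), evaluating the loss at
the face rather than the cell center (a sub-percent correction at the U
values of interest).

Lethality accumulates per cell by the trapezoid rule on the step's endpoint
temperatures — consistent in order with the thermal scheme and exactly
additive over subintervals. The time to the 12D target is interpolated
linearly within the bracketing step of the minimum-over-cells log reduction.

A **boiling guard** aborts any run in which a cell exceeds 373.15 K
(configurable): the measured property tables stop at 85 °C and the
single-phase model is invalid past boiling. Property evaluation outside the
measured 5–85 °C range clamps to the nearest tabulated value — the tables
give no functional form to extrapolate, and clamping keeps properties
bounded and positive.

## Parameters, defaults and provenance

| parameter | default | units | provenance |
|---|---|---|---|
| applied voltage | 100 | V | stated process condition |
| initial temperature T₀ | 279.15 | K | stated process condition |
| base duration | 150 | s | stated process condition |
| properties λ, VHC, σ | measured table, 5–85 °C | SI | packaged mashed-potato measurements |
| z-value (E. coli O157:H7) | 10 | °C | stated organism datum |
| D_ref, T_ref | 60 s at 333.15 K | s, K | **assumption** (see below) |
| target log reduction | 12 | — | 12D pasteurization convention |
| U (lossy cases) | 5–15 | W m⁻² K⁻¹ | stated typical range; 5 is the validated value |
| cylinder R × L | 0.025 × 0.18 | m | **assumption** (see below) |
| grid (nr × nz) | 24 × 48 | — | grid study (below) |
| dt | 0.5 | s | time-step study; convergence knob |

**Kinetics reference point.** Only the z-value of the target organism is
tightly constrained; D_ref/T_ref are a calibration assumption, set to 60 s at
60 °C — inside the range of published heat-resistance data for *E. coli*
O157:H7 — and config-overridable. Absolute 12D times scale directly with this
choice; all *relative* scenario comparisons (±10 % conductivity, case
orderings) are insensitive to it.

**Cell geometry.** The physical cell dimensions are not part of the packaged
data and are likewise a documented assumption. They were calibrated once,
before the test suite was frozen, against three qualitative requirements the
physics must meet simultaneously at 100 V: the insulated 150-s process ends
below boiling; all seven scenario 12D times are of the observed order
(minutes, not seconds or hours); and the strong-loss case C6 is the worst
case overall, ahead of the −10 % conductivity case C3. The third requirement
is the discriminating one: the cold-corner time penalty grows with electrode
gap (the surface deficit scales like U(T−T_inf)√(αt)/λ while the heating rate
falls as 1/L²), and short cells can never rank C6 above C3's rescaling-fixed
+10.6 %. R = 0.025 m, L = 0.18 m satisfies all three with ~8 K of boiling
margin. Users simulating a specific cell should set their own geometry.

**Grid.** The C6 corner penalty converges from below under axial refinement
(+9.5 % at 16×16, +12.1 % at 24×48, +12.8 % at 32×64): coarse axial layers
average the corner boundary layer away. The default 24×48 resolves the
ranking with margin at ~25 s for the full seven-case suite on one CPU.
Quantities that are spatially trivial (insulated-run temperatures, ±10 %
conductivity shifts) are grid-insensitive at 16×16 already.

## Drive modes

In constant-voltage drive the drawn power rises during the run because σ(T)
grows (roughly 3.5× over 5–85 °C). In constant-power drive the Joule field is
rescaled every step to a set point and the equivalent voltage scales with the
square root of the power ratio. `rescale_for_constant_power` takes an
explicit set point; `run_simulation` defaults it to the first step's power.
The `compare_drive_modes` experiment instead matches the set point to the
*time-averaged* constant-voltage power, i.e. equal delivered energy: for an
insulated sample the final temperature then depends only on total energy, so
both drives end at the same temperature (observed gap ~2×10⁻⁵ K) while the
constant-power trajectory runs hotter in between (up to ~1.5 K at
mid-process) — the physically meaningful statement of "same endpoint,
different history, hence different accumulated lethality".

## Cold-spot classification

A completed run's F field is classified as: `uniform` when the relative
spread (F_max − F_min)/F_max is below 1 % (an insulated run is uniform to
round-off — no cold area is identifiable, matching the stated behaviour of an
ideally insulated cell); otherwise `exterior-corner` when the argmin-F cell
lies in the outermost radial ring *and* an outermost axial layer (the
electrode/lateral junction); `on-axis` when it lies at r = 0; `interior`
otherwise.

## What the built-in conditions do and do not represent

The packaged defaults emulate the study conditions: a uniform mashed-potato
cylinder with measured temperature-dependent properties, fixed 100 V drive,
uniform 279.15 K start and steady surroundings. They do not include property
heterogeneity or anisotropy, contact resistance at the electrodes, wall
capacitance, moisture loss, or non-thermal inactivation — so passing tests
demonstrate the coupled solver and kinetics are correct under the model's
assumptions, not that a specific physical cell will match to the degree the
tests enforce. Absolute 12D times inherit the D_ref/T_ref and geometry
assumptions above and should be read as a plausibility band (the tests bound
them to 50–600 s), whereas orderings and percent changes are robust.

## Verification strategy

Independent oracles back every layer: closed forms (linear potential,
series-resistor two-layer profile, lumped source-only steps, exponential
small-Biot cooling), brute-force solvers written in the tests (dense 1D
finite differences for the potential, stiff ODE integration for survivor
curves), and a high-accuracy adaptive 0D ODE for the insulated coupled run
(the PDE pipeline tracks it within 0.03 K over 150 s at the default
resolution; the 0.2 K acceptance bound is conservative). Conservation is
audited per step — stored-energy change equals source minus boundary losses
to solver precision for constant properties. Property-based tests (seeded
hypothesis) cover the maximum principles, current conservation, the V·I
power identity and lethality additivity/monotonicity.

## Known limitations

- Uniform structured grids only; no local refinement at corners (the grid
  study quantifies the cost: ~0.7 pp of C6 penalty between 24×48 and 32×64).
- Lagged (Picard-free) property coupling is first-order in dt; halving dt
  moves the insulated 150-s endpoint by <0.05 K.
- The Robin coefficient U is a lumped constant per run: no natural-convection
  temperature dependence, no per-face distinct U values (only on/off flags).
- Survivor arithmetic is done in log space (F), so populations below ~1e−300
  of N₀ would underflow only at absurd targets; the 12D range is untouched.
- The boiling guard makes near-boiling processes abort rather than degrade
  gracefully; that is intentional model-validity policing.
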