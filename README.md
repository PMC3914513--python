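# ohmicpast

Coupled electro–thermal–microbial simulation of **ohmic (Joule) pasteurization**
of a homogeneous solid cylindrical food held between two end electrodes.

Ohmic heating passes electric current directly through a conductive food, so
heat is generated volumetrically instead of diffusing in from the surface. For
process safety the key question is *where the least-treated spot is and how long
the process must run* to deliver the target microbial reduction there. This
package is a virtual laboratory for that question, aimed at food-process
engineers and predictive-microbiology researchers: it resolves how exterior
heat losses, ambient temperature and the sample's electrical conductivity move
the cold spot and stretch the pasteurization time.

## Model

On an axisymmetric cylinder (radius *R*, electrode gap *L*) the simulator
solves, with all properties functions of the local temperature:

- **Electrical potential** (quasistatic): ∇·(σ∇V) = 0, with V fixed on the two
  electrodes and insulation on the lateral surface;
- **Joule source**: Q = σ|∇V|²;
- **Heat transfer**: ρC_p ∂T/∂t = ∇·(λ∇T) + Q, with either insulated surfaces
  or Newton cooling q = U(T − T_inf) through an overall coefficient U;
- **Inactivation kinetics**: dN/dt = −(ln10/D(T))·N with
  D(T) = D_ref·10^((T_ref−T)/z), so the log reduction is
  log₁₀(N₀/N) = F/D_ref with the accumulated lethality
  F(t) = ∫ 10^((T−T_ref)/z) dτ. A *12D process* is complete when the
  **minimum-over-the-product** log reduction reaches 12.

σ rises steeply with temperature, so the potential and heat equations are
two-way coupled and solved together on a cell-centered finite-volume (r, z)
grid. Packaged default properties are measured mashed-potato tables
(λ, volumetric heat capacity, σ at 5–85 °C); the default target organism is
*E. coli* O157:H7 (z = 10 °C).

## Worked example

Run the built-in sensitivity suite — seven cases varying the surface heat
exchange (U, T_inf) and the electrical conductivity (±10 %) around an
insulated control, all at 100 V from 279.15 K:

```bash
ohmicpast suite --out suite_out
```

```
C1: t12D = 333.3 s (+0.0% vs control), cold spot uniform
C2: t12D = 304.1 s (-8.7% vs control), cold spot uniform
C3: t12D = 368.7 s (+10.6% vs control), cold spot uniform
C4: t12D = 346.2 s (+3.9% vs control), cold spot exterior-corner
C5: t12D = 333.1 s (-0.0% vs control), cold spot on-axis
C6: t12D = 373.5 s (+12.1% vs control), cold spot exterior-corner
C7: t12D = 333.0 s (-0.1% vs control), cold spot on-axis
```

Reading the numbers: a perfectly insulated cell (C1) heats uniformly — no
identifiable cold spot. Raising σ by 10 % (C2) shortens the 12D time by ≈10 %
(heating rate scales with σ); lowering it (C3) lengthens it by the same logic —
accurate conductivity measurement matters more than any other property here.
With heat losses into cold air (C4, C6) the least-treated cells sit at the
junction of the electrodes with the lateral surface, so the *outer shell*, not
the geometric center, is the critical region to monitor; the strong-loss case
C6 is the worst case overall. Warm surroundings (C5, C7) suppress the surface
deficit and push the coldest region back onto the axis, at almost no time
penalty.

`ohmicpast run --config examples/validated_case.yaml --out out/` runs a single
process (low-loss baseline, U = 5 W m⁻² K⁻¹) and writes `trace.csv` plus
VTK snapshots of T, V, Q and F; `ohmicpast lethality --profile profile.csv`
integrates F and the survivor curve along any measured time–temperature
profile.

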