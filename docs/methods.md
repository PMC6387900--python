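# Methods

## Model and assumptions

The chamber is modelled as a 2D longitudinal section through the inlet and
outlet ports: a rectangle of width 2R (R = chamber radius) and depth H,
with z = 0 at the base. A solid, impermeable pedestal of height h and width
2·r_ped stands centred on the base; its top face carries the cell
monolayer on a coverslip of radius r_cs = 6.5 mm (r_ped = r_cs by
default). The working assumptions:

- **Steady laminar flow.** Perfusion at Q = 150 μl/min through a 1 mm-radius
  port gives a mean inlet velocity U = Q/(πr²) ≈ 0.8 mm/s and an inlet
  Reynolds number ≈ 2.3. The Stokes equations are solved by default; a
  Picard-linearised convective term is available (`numerics.inertia`).
  In this creeping regime the flow scales linearly with Q, which the test
  suite checks numerically.
- **2D section.** The outputs of interest (disc-centreline profiles and
  means) are section quantities, and a planar model keeps every solve on a
  desk scale. The 2D per-unit-width inlet flux is U·2r. The cost is that
  three-dimensional lateral spreading is absent, so absolute velocities
  near the cell disc are section estimates rather than full-3D values;
  the shear predictions should be read at order-of-magnitude accuracy
  (the design criterion uses a factor-of-5 band), while the oxygen means
  are anchored by calibration (below).
- **One-way coupling.** Oxygen is a dilute solute: flow drives transport,
  transport does not alter the flow.
- **Uptake only at the cell disc.** Walls, lid and pedestal sides are
  impermeable and consume nothing; there is no exchange through tubing or
  reservoir and no CO₂/pH coupling. The uptake flux is Michaelis–Menten,
  −D ∂c/∂n = σ·V_max·c_s/(K_m + c_s), with σ = cell count / coverslip area.

## Parameters

| parameter | default | units | provenance |
| --- | --- | --- | --- |
| flow_rate | 2.5e-9 (150 μl/min) | m³/s | operating protocol |
| inlet_oxygen | 0.21 (21 %) | mol/m³ | air-equilibrated medium; 1 mol/m³ ≡ 100 % |
| chamber_radius | 10e-3 | m | commercial chamber scale |
| chamber_depth | 24.6e-3 | m | **calibrated** (see below) |
| port_center_height | 22.9e-3 | m | **calibrated** (see below) |
| port_radius | 1e-3 | m | commercial chamber scale |
| coverslip_radius | 6.5e-3 | m | 13 mm coverslip |
| density / viscosity | 993 / 0.7e-3 | kg/m³ / Pa·s | aqueous medium, 37 °C |
| oxygen_diffusivity | 3.0e-9 | m²/s | O₂ in water, 37 °C |
| cell_count | 1e6 | cells | seeding protocol |
| vmax_per_cell | 1.25e-17 | mol/(cell·s) | **external/calibrated** (see below) |
| km | 5e-3 | mol/m³ | low relative to operating c (≈3.8 mmHg) |

**Calibration.** The internal chamber depth, the port height and the
hepatocyte kinetic constants are not available to this implementation: the
published kinetics literature spans orders of magnitude, and headline
hepatocyte consumption rates (10⁻¹⁷–10⁻¹⁵ mol/cell/s) would drive this
chamber fully anoxic at every height, which contradicts the observed
6–15 % operating window. These three quantities were therefore fixed
**once**, by a coarse numeric sweep, so that the simulator's operating
point reproduces the documented design outputs (mean surface O₂ ≈ 6/12/15 %
at inserts of 0/4/7 mm, minimum ≈ 4 % at the base, shear ≈ 10⁻⁸–10⁻⁶ Pa),
and are shipped as config defaults clearly marked as external. They are
degrees of freedom of the model, not measurements; every one is overridable
from the YAML config.

## Discretisation

- **Mesh.** Boundary-fitted tensor-product grid; faces coincide exactly
  with the pedestal edges, the cell-disc plane and the port — so fluid
  area, boundary measure and the disc span are exact at every refinement
  level. Vertical spacing is geometrically graded (ratio 1.2) towards the
  cell-surface plane with smallest spacing `surface_layer_fraction ×
  surface_layer_scale / 2^level` (default 25 μm at level 0), resolving the
  uptake boundary layer. Level ℓ targets `32·2^ℓ` cells across each
  dimension: level 2 (the working resolution) has ≈18k cells and solves in
  a few seconds; level 3 (≈69k cells) is used for convergence checks
  (oxygen mean moves < 0.5 %, shear < 0.1 % between levels 2 and 3).
- **Flow.** Staggered (MAC) finite volumes: u on vertical faces, w on
  horizontal faces, p at cell centres — an inf-sup stable pairing with
  continuity enforced exactly per cell (divergence at solver precision,
  inlet flux = outlet flux to 1e-14). Inflow is an exactly flux-normalised
  parabolic profile over the port; the outlet is traction-free, implemented
  as a half-control-volume momentum balance with zero boundary traction,
  which also pins the pressure level (the reported pressure is re-gauged to
  zero mean; for all-Dirichlet meshes such as the stagnant column the gauge
  is a zero-mean Lagrange multiplier). Walls are no-slip via half-cell
  ghosts. One sparse direct solve for Stokes; with inertia enabled, Picard
  iterations with first-order upwinding to relative tolerance 1e-8 (cap 50,
  failure raises with the residual history).
- **Wall shear.** μ·∂u/∂z at the disc, extracted by a one-sided quadratic
  fit through the no-slip surface value and the two cell-centre velocities
  above — exact for locally parabolic flow, which makes the plane-Poiseuille
  benchmark essentially exact.
- **Oxygen.** Cell-centred finite volumes on the same grid, sharing the
  discretely divergence-free face fluxes. Convection–diffusion face fluxes
  use Patankar's power-law scheme, which blends central differencing into
  upwinding as the face Péclet number grows: the matrix stays an M-matrix,
  so the discrete maximum principle 0 ≤ c ≤ c_in holds by construction and
  is asserted after every solve (violation raises rather than returning an
  unphysical field). The price of power-law upwinding is extra numerical
  diffusion in strongly convective cells; the level-2/3 convergence check
  bounds its effect on the reported means below 1 %.
- **Nonlinear uptake.** The Michaelis–Menten surface concentration is
  Picard-lagged into a series-resistance Robin coefficient (half-cell
  diffusion in series with linearised uptake — keeps the M-matrix), then
  updated from the exact local quadratic balance through the half cell
  (numerically stable root form), with Aitken-accelerated relaxation.
  Tolerance 1e-8 relative to the inlet concentration, cap 50 iterations;
  typical solves converge in 5–10.

## Design procedure

`height_sweep` evaluates insert heights 0, 1 mm, 2 mm, … and stops at the
first height whose **mean** cell-surface oxygen reaches the target
(default 15 %) — "approximately 15 %" is operationalised as
`mean ≥ target_pct` at the first qualifying height, with the target a
parameter. If the target is unreachable inside the chamber (clearance of
1 mm below the lid), the sweep returns all evaluated heights, no stopping
height, and a warning. Non-monotone means would also emit a diagnostic
warning rather than silently stopping. `select_zones` labels base →
perivenous, 4 mm → central, stop → periportal, and `table1_report` emits
the per-zone design table. The 4–15 % physiological window is surfaced as
a validation check (`ZoneSummary.in_physiological_window`), not a hard
constraint.

## Verification fixtures and synthetic data

All test inputs are generated internally:

- **Plane Poiseuille** (closed-form wall shear 6μQ/(w·gap²)) exercises the
  momentum discretisation and the shear extraction; agreement contract 2 %
  at level 2.
- **Stagnant Michaelis–Menten column** (top concentration held, uptake at
  the base) has the closed-form surface concentration
  c_s² + (K_m + σV_max L/D − c₀)c_s − K_m c₀ = 0; the root is verified
  against a dense, independently coded 10⁴-node finite-difference solve,
  and the 2D solver must match within 1 %. Each case self-checks its own
  flux balance before being used as an oracle.
- **Synthetic profiles** sample the column's surface concentration with
  additive Gaussian noise under an explicit seed (no global random state);
  `recover_vmax` inverts the flux balance by least squares with a
  delta-method standard error. Noiseless recovery is exact; at 5 % noise
  and n = 50 single replicates land within 10 % and the 100-replicate
  ensemble bias is below 2 %.

The oracles are deliberately simple flows. What passing proves: the
discretisations converge to the right continuum operators, conservation is
exact, and the uptake nonlinearity is solved correctly. What it does not
prove: that the 2D section with calibrated dimensions reproduces the true
3D chamber hydrodynamics — the shear outputs in particular inherit the
section approximation and the calibration, and real chambers add menisci,
tubing compliance and reservoir depletion that are out of scope.

## Known limitations

- 2D planar section; no 3D mode yet (the geometry/config layer is
  dimension-agnostic by design).
- Shear at the base of a deep chamber is a quasi-exponentially decaying
  (Moffatt-eddy) quantity and is therefore sensitive to geometry and to the
  inertia setting: enabling the convective term moves base shear by a
  factor ≈ 3 while oxygen means move by well under a percentage point.
- Power-law convection is first-order accurate in strongly convective
  regions; refine beyond level 2 if sub-percent transport accuracy matters.
- The kinetics defaults are calibration anchors, not measured hepatocyte
  constants; conclusions about absolute oxygen levels in a real chamber
  require measured V_max and K_m.
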