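# Methods

`veinflow` simulates passive, steady-state water and sucrose transport
through the coupled xylem–phloem vasculature of a dicot leaf and asks
how leaf proportion and second-order vein orientation shape whole-leaf
transport efficiency.

## Model

The leaf lamina is a 2-D network of nodes on a rectangular lattice.  Two
parallel networks share the node set: a xylem network carrying water and
a phloem network carrying sucrose solution, joined at every node by a
cross conduit.  Three unknowns live at each node: xylem hydraulic
pressure `p_xyl` (MPa), phloem total pressure `p_ph` (MPa), and phloem
sucrose concentration `C` (mol m⁻³).

Per interior node, steady state imposes three conservation laws:

* **Xylem water.**  `Σ_d K_xyl (p_d − p) + E a + F_c = 0`.  Darcy flux
  along each of up to eight conduit directions (four axial, four
  diagonal), a fixed transpiration efflux `E a` proportional to the
  node's tributary lamina area `a`, and the cross-conduit flux.
* **Phloem water.**  `Σ_d K_ph (p_d − p) − F_c = 0`.  The lateral
  reflection coefficient is zero (solute moves freely along sieve
  tubes), so lateral phloem flow is plain Darcy flow; the osmotic
  physics lives entirely in the cross conduit.
* **Cross conduit (Münch coupling).**
  `F_c = K_c ((p_ph − σ_c R T C) − p_xyl)` with `σ_c = 1`: an ideally
  semipermeable membrane path, so dissolved sucrose pulls water from
  the xylem into the phloem even at equal hydraulic pressures.
* **Sucrose.**  `Σ_d S_d + Λ a = 0` with
  `S_d = v_μ F_ph C_from + G (C_d − C)`: convection by the phloem water
  stream plus Fickian diffusion with conductance
  `G = D_su A_ph / l`.  Loading `Λ a` is a fixed areal source; there is
  no unloading or metabolic consumption.

Boundary conditions: at the single petiole node the two pressures are
Dirichlet (`0.00` and `0.20` MPa by default) and the sucrose condition
is zero-Neumann — the petiole concentration is pinned to its interior
neighbor, so sucrose leaves only convectively.  Gravity is neglected at
leaf scale.  All node-centric fluxes are signed positive into the node,
so a transpiring leaf has `E < 0`.

Units are fixed internally to MPa, m, s, mmol (water) and mol
(sucrose); with `R = 8.31e-6 MPa m³ mol⁻¹ K⁻¹`, `R·T·C` is an osmotic
pressure in MPa directly.

### The two sucrose convection schemes

The `literal` scheme multiplies the convective term by the from-node
concentration for both flow directions.  Pairwise sucrose fluxes are
then *not* antisymmetric, so whole-leaf sucrose export does not exactly
match total loading; the gap is computed and reported in every balance
report (roughly 45% of the load under core conditions — a property of
the discretization, not a solver error).  The `upwind` (donor-cell)
scheme uses the concentration of the node the water flows from, is
exactly mass-conserving, and is offered as the alternative.  `literal`
is the default: under core conditions at a 45° vein angle it reproduces
the published area-average concentrations to ~1%, whereas the upwind
variant runs ~7% high, which strongly suggests the original results
used the literal form.

## Venation generation

The leaf outline is a lanceolate half-width profile
`w(z) = (W/2) sin(π z/L)^q`, mirror-symmetric about the main vein, with
the exponent `q` solved per shape so the lamina area is exactly
73.35 cm².  Three proportions share that area: wide (12.8 × 8.09 cm),
reference (16.0 × 6.47 cm), narrow (19.2 × 5.39 cm).  The profile is the
simplest smooth family satisfying every documented constraint (length,
max width, area); it is replaceable via `LeafShape`.

Nodes sit on a square lattice (default spacing 2.0 mm) clipped to the
outline, with the first interior node 5 mm up the symmetry axis and an
external petiole node joined to it by a 5 mm order-1 conduit.  Nodal
areas are lattice cells clipped to the outline (exact in the lateral
direction, Simpson quadrature longitudinally); slivers whose cell center
falls outside are folded into the nearest interior node, so the nodal
areas sum to the lamina area and total transpiration is exactly
`E × 73.35 cm²`.  Areas are mirror-symmetrized so solved fields are
symmetric to solver precision.

Vein orders and conductivities (order: conductivity in
m mmol s⁻¹ MPa⁻¹ / diameter in μm): 1: 1.00e-2 / 15.50, 2: 5.00e-4 /
11.30, 3: 6.00e-5 / 7.50, 4: 4.00e-5 / 7.20, 5: 4.00e-6 / 4.34.  Edge
conductance is conductivity over edge length; phloem conductances are a
uniform 3/100 of the xylem values; diameters only enter the diffusive
conductance `G`.  The main vein (order 1) runs the symmetry axis; order
3 occupies every 6th lattice row and column; orders 4 and 5 fill the
remaining lattice lines alternating by index parity (even lines order 4
by default; the parity is a config switch), so every interior lattice
edge carries an order.  Where orders overlap, the lowest order (widest
vein) wins.

Second-order veins leave the main vein as mirrored left/right pairs and
are rasterized as staircases of axial and diagonal steps whose period
realizes `tan θ = p/q` exactly; the 13 supported sweep angles
(0.00°–75.96°) are the small-integer lattice ratios from 0/1 to 4/1.
Mirrored pairs (rather than single alternating-side veins) are forced by
two facts: the mirror symmetry of the solved fields, and the 0.74 m
total-length budget, which equals lamina area / 10 mm spacing only if
both half-leaves are serviced at the stated 10 mm axial spacing.

**Constant total length.**  The angle experiments hold the total
second-order vein length at 0.74 ± 0.01 m so the flow-resistance budget
of the second-order system is angle-invariant.  Station placement is a
two-stage search: an integer scan over alternating intervals
(L_v1, L_v2) minimizing the deviation (ties toward equal intervals),
then a deterministic greedy refinement that shifts, inserts, or removes
individual stations one lattice row at a time.  The refinement is
needed because on a 2 mm lattice the two-interval family's achievable
totals are quantized by whole veins (~0.06 m near 10 mm spacing) and
margin truncation leaves the θ=0 reference construction at ~0.71 m; the
per-station adjustment closes the gap for all 39 shape × angle cells
(worst residual 0.0096 m).  On this outline, staircase length to the
margin grows like 1/cos θ once tan θ exceeds the local taper, so steep
angles carry the budget with *fewer, longer* veins — the adjustment
direction is an emergent property of the outline, and a different
outline or termination rule could reverse it.

In `constant_spacing` mode the intervals are fixed (10 mm default,
15 mm alternative) and the total floats.

## Solver

The system is polynomial of degree 2 in the unknowns (only the
`F_ph · C` convective product is nonlinear), so a damped Newton
iteration with the exact, analytically assembled sparse Jacobian
converges in ~5 iterations from the constant initial guess
(petiole pressures, `C = 100 mol m⁻³`, inside the expected 150–190
steady-state range).  Convergence is declared when the max-norm
residual of each equation class falls below `tol = 1e-10` relative to
its forcing scale (median `|E a|` or current cross-flux magnitude for
water; median `|Λ a|` for sucrose).  On failure the solver ramps
`(K_c, Λ)` from the always-solvable linear decoupled problem in five
homotopy steps, then retries from seeded perturbed starts; the seed is
the only randomness and defaults make every solve bit-deterministic.
The degenerate input `K_c = 0` with `Λ ≡ 0` leaves the concentration
field defined only up to a constant; it is special-cased as the two
linear water solves with `C` returned uniform at the initial guess.

Verification is double-tracked: a loop-coded residual solved densely by
MINPACK's hybrid method with finite-difference Jacobians (homotopy
continuation from the linear xylem-only solution) must agree with the
main path to 1e-8 relative on randomized toy networks, and uniform
chains admit a telescoping closed form.  Whole-leaf balance closures
(petiole inflow vs transpiration plus cross transfer; phloem outflow vs
cross transfer; sucrose export vs loading) are computed after every
solve and asserted in tests.

At float64, the scaled residual floor sits near `5e-11 × (n/2000)`; on
lattices finer than ~1.5 mm the default tolerance approaches that floor
and should be relaxed (e.g. `3e-9`), which is far below any physically
meaningful scale.

## Indices and experiments

The headline index is the leaf area-average of a field — the arithmetic
mean over interior nodes (the petiole is a boundary reservoir and is
excluded).  Angle sweeps rebuild the venation per angle on a shared
lattice and tabulate averages; peaks are grid-argmax over the sampled
angles with ties toward the smaller angle (no interpolation, matching
how the published peaks are reported).  The "degree of variation" of a
response curve has no published definition; the metric is pluggable
(`range/|mean|` default, `range/|max|`, `range/|min|`), and because the
percent normalizations reorder shapes, cross-shape comparisons in the
tests use the dimensional range (max − min of the average pressure),
which reproduces the published orderings in both the reduced- and
enhanced-conductance experiments.  The circulation diagnostic map is
`p_xyl − (p_ph − R T C)` per node, i.e. `−F_c / K_c`: positive where
the xylem feeds the phloem.

Default problem sizes: the 2.0 mm lattice gives ≈1836 interior nodes
(≈5500 unknowns) per leaf; a build-plus-solve takes ~0.25 s and the full
3-shape × 13-angle campaign ~8 s on one core.

## Known limitations

* The original outline ("Laurel leaf shape") and lattice spacing are
  not documented; only length, width, and area are honored.  Area
  averages reproduce to a few percent, but peak angles can shift by one
  sampled-angle step with spacing.  In the enhanced-conductance
  experiment (5× order-2 conductivity) the wide-leaf peak sits at
  59.06° on the 2 mm default versus 53.13° on a 1 mm lattice (published:
  49°); the reference and narrow peaks land within one angle step at
  either spacing.  The minor-vein network density — and with it the
  second-order/minor conductance balance that governs angle
  sensitivity — scales with lattice spacing, which is the likely
  mechanism.
* Straight, margin-terminated second-order veins lengthen with angle on
  a lanceolate outline; published remarks imply the opposite adjustment
  direction, which would require an undocumented outline or vein
  termination rule.  The quantified 0.74 m budget is honored either
  way.
* Vein tapering and curvature, free (non-lattice) branching,
  craspedodromous/actinodromous and monocot parallel venation,
  mesophyll/bundle-sheath tissue, separate symplast/apoplast pathways,
  sucrose unloading, and time dependence are out of scope.
* The fixed-rate transpiration and loading boundary conditions are
  idealizations; with them, leaf conductance follows by dividing the
  (constant) transpiration flux by the petiole-to-leaf-average pressure
  drop.
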