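# Methods

## The physical picture

Shallow-water hydrothermal vents discharge hot, reduced, H2S-rich fluids
through permeable sandy seabeds. Bottom currents mould that sand into
ripples (crest-to-crest wavelengths of 15–20 cm at the field site this
package emulates), and the interaction of the benthic boundary layer with
the ripple topography re-organises both the flow and the chemistry the
surface-attached microbial mats experience: flow accelerates over the
crest (a surface-pressure minimum), the boundary layer separates on the
steep lee flank and rolls up into a weak recirculation eddy in the
trough, a positive pressure zone forms on the stoss flank pumping
oxygenated seawater into the sand, and the trough above the vent traps
reduced pore fluid. The mats record this as a colour zonation — white in
the reduced trough, through yellow and light brown, to Cyanobacteria-rich
brown at the oxygenated crest.

`ripplemat` reproduces this chain at desk scale: a 2-D vertical slice
along the flow direction, a lattice-Boltzmann shear flow over and through
a porous ripple, passive O2/H2S/temperature transport on the converged
velocity field, feature diagnostics, and a niche classifier whose
predicted zonation is compared against (synthetic) community tables.

## Flow model

D2Q9 single-relaxation-time (BGK) lattice Boltzmann, kinematic viscosity
`nu = (tau - 1/2)/3` in lattice units. Double precision, fixed iteration
order: runs are bit-reproducible for a given configuration.

* **Top boundary** — moving-wall halfway bounce-back (Ladd momentum
  correction) imposing the horizontal lid velocity `u_top`. Chosen over a
  Zou–He velocity inlet because it conserves mass exactly, which the
  conservation contract (drift < 1e-10 over 10^4 steps) demands.
* **Bottom boundary** — no-slip halfway bounce-back below the deepest
  sediment row.
* **Lateral boundaries** — periodic: the domain is one wavelength of an
  infinite ripple train.
* **Porous sediment (gray LBM)** — each cell carries a solid fraction
  `ns ∈ [0,1]`; after collision, outgoing populations are blended with
  their reverses by a swap fraction `θ = ns/2` before streaming. The swap
  scales the node's post-collision momentum by `(1 − ns)`: a Darcy-like
  drag, monotone over the whole range, identity in open water, and exact
  flow blockage at `ns = 1`. A full swap (`θ = ns`) would reverse the
  seepage direction for `ns > 0.5`, a documented defect of the naive
  partial-bounce-back scheme; the half-swap mapping avoids it while
  conserving node mass exactly and leaving no spurious density contrast
  across the sediment–water interface. An alternative Brinkman mode
  replaces the swap by a velocity-proportional momentum sink
  `F = −λ·ns·ρ·u` (Guo forcing, implicit in `u`), mirroring a
  finite-volume momentum-sink treatment of soil porosity.
* **Vent** — an optional bottom-row segment where the populations are
  reset to equilibrium at the local density and an imposed upward
  velocity `w`. This imposes the inflow velocity while conserving mass
  exactly; a true mass-injecting inlet has no steady state in a
  lid-driven closed domain. The vent cells also act as fixed-value
  sources for H2S and temperature.
* **Body force** — Guo forcing (second-order), used for the Poiseuille
  validation and the Brinkman mode.
* **Convergence** — windowed residual: the run is steady when the maximum
  per-cell velocity change over a 100-step window, relative to the
  current maximum speed, falls below `tol`. Non-convergence is flagged in
  the result metadata, never silently accepted.

The inner loop is compiled with numba (`_kernels.py`); the readable numpy
implementation in `lbm_flow.collide_stream` is the reference, and the two
are held to agreement at round-off by the test suite.

## Reference run

No lattice parameters for the original simulations are on record, so the
packaged reference configuration declares its own desk-scale conditions:
one ripple of wavelength 0.175 m (the midpoint of the observed 15–20 cm
range) and height 0.02 m on an 88×60 lattice (dx ≈ 2 mm), asymmetry 0.5
(gentle stoss, steep lee), bed depth 0.02 m, sediment solid fraction
`ns = 0.6`, lid velocity 0.05 lattice units (Mach 0.087), `tau = 0.515`.
The Reynolds number on the ripple height — the obstacle scale that
controls separation — is `U·h/nu = 0.05·10/0.005 = 100`. The run starts
from the linear Couette profile (so the transient is only the
ripple-induced perturbation) and converges at `tol = 1e-6` in roughly
2×10^5 steps, about one minute on one core. The vent occupies the four
bottom columns beneath the lee trough with `w = 0.002`.

## Scalar transport

Temperature, O2 and H2S are passive: nothing ever feeds back on the
velocity field (asserted by test). All scalars are normalized — solutes
in units of their source boundary value, temperature as
`(T − T_top)/(T_bottom − T_top)`. Default chemistry: O2 fixed at 1 on the
top boundary and 0 at the vent/deep bed; H2S and temperature fixed at 1
at the vent/deep bed and 0 at the top. Inside the sediment the advecting
velocity is the resolved seepage velocity and the diffusivity is reduced
to `D·(1 − ns)` as a minimal tortuosity proxy. The default lattice
diffusivity 0.01 puts the wavelength Péclet number `U·λ/D` near 440.

Two numerical paths share the same finite-volume discretisation:

* **Explicit stepper** (`scalar_step`) — conservative flux form;
  advection either first-order upwind or van-Leer MUSCL (default). The
  MUSCL branch adds the Lax–Wendroff modified flux `u²·dt/2` to the face
  diffusivity, cancelling the forward-Euler antidiffusion so that an
  advected Gaussian reproduces the analytic centroid speed and `2Dt`
  variance growth to ~1%. With zero-flux walls the total is conserved to
  round-off.
* **Direct steady solve** (`solve_steady`, default for the pipeline) —
  the steady first-order-upwind operator assembled as a sparse linear
  system and solved exactly. The advective part is written in
  non-conservative (advective) form — zero row sum — because the LBM
  velocity field is divergence-free only to O(Ma²) and the vent row is a
  velocity source; this makes the operator an M-matrix, so the discrete
  maximum principle holds by construction. Explicit marching to steady
  state at the reference Péclet would need O(H²/D) ≈ 10^6 steps; the
  direct solve takes a fraction of a second and is the package's own
  design choice for steady fields. The explicit path remains available
  (`method="explicit"`) with the same windowed-residual rule as the flow.

**Convection guard** — the thermal scalar is advection-only by
assumption, so before running it the pipeline computes a Darcy (porous
medium) Rayleigh number `Ra = g·alpha·dT·K·H/(nu·kappa)` for the heated
sand layer. The porous form is used because the heated layer is sand, not
clear fluid: with field-typical defaults (dT = 2 K over a 5 cm bed,
permeability 4e-11 m², seawater properties) Ra ≈ 0.05, orders of
magnitude below the conservative critical value of 1708 (the classical
clear-layer threshold, kept as the default guard). A clear-layer Rayleigh
number with the same inputs would exceed the threshold and wrongly block
the run. The guard can be overridden explicitly in the configuration.

## Diagnostics

All diagnostics are pure functions of the fields.

* **Streamfunction** — column-wise midpoint integration of `u_x` upward
  from the bottom, with a bottom-row baseline `−∫u_y dx`; gauged to 0 at
  the bottom-left cell.
* **Separation / reattachment** — sign changes of the one-sided wall
  shear estimate (`u_x` at the first water cell above the bed) along the
  flow direction, with near-zero values carried through.
* **Eddies** — connected near-bed regions (within 25 % of the ripple
  height above the local interface) of `u_x` opposing the driving
  velocity, retained above a minimum area; centre at the interior
  streamfunction extremum, rotation sense from local vorticity. Reversed
  near-bed flow is used instead of closed-streamline topology because
  streamlines through the partially-penetrable bed are ambiguous.
* **Surface pressure** — `c_s²·rho` at the first water cell above the
  bed, reported as deviation from the mean; stoss/lee flank means use the
  sign of the smoothed bed slope, with crest/trough plateaus excluded.
* **Exchange flux** — advective + diffusive normal flux across the
  horizontal face between the top sediment cell and the water cell above
  it, positive into the sediment.
* **O2 penetration depth** — per column, the count of contiguous sediment
  cells below the interface where O2 stays above 10 % of its value at the
  interface cell.

## Niche mapping

Mats sit on the sediment surface, so exposure is the scalar value at the
first water cell above the bed (not a depth integral). Exposures are
split into tertiles of the run's own distribution (scale-free; no
absolute concentration cut-offs are on record), and a monotone lookup
maps (O2 tertile, H2S tertile) to the ordered classes
white < yellow < light_brown < brown via the score
`O2_tertile + (2 − H2S_tertile)`: reduced trough → white, oxygenated
crest → brown. Absolute thresholds can be supplied in the configuration.

Agreement between a predicted gradient and a community table is the
sign-adjusted mean Spearman correlation between sample position
(trough→crest ordinal) and indicator-taxon relative abundance —
Cyanobacteria expected to increase toward the crest (+), the sulfur
oxidizer *Sulfurimonas* to decrease (−). Midranks break ties. The
statistic is rank-based, hence invariant to monotone transforms of the
abundances, and equals +1/−1 for perfect agreement/reversal. On the
observed three-point mat profiles (Cyanobacteria 26.6/26.0/57.6 %,
Sulfurimonas 35.3/18.1/8.1 % from trough to crest) it evaluates to
(0.5 + 1)/2 = 0.75.

## Synthetic data

The community generator draws sample compositions from Dirichlet
distributions `Dir(concentration × mean)` around packaged per-condition
mean vectors (the storm-succession time series and the ripple mat
gradient). The field study provides one observed composition per
condition with no replication or error model, so the default
concentration of 50 is a declared stand-in giving per-taxon standard
deviations of a few percentage points — large enough to be a real noise
test, small enough that the gradient sign survives in almost all draws.
Taxa not reported for a condition receive the pooled `other` remainder
rather than invented values; taxa with zero mean are exactly zero in
every draw. All randomness flows from one integer seed through one
`numpy.random.Generator`.

What the generator does **not** emulate: sequencing depth and count
noise, compositional correlation between named taxa beyond the simplex
constraint, within-condition spatial autocorrelation, and any read-level
artifacts. Passing the agreement tests therefore shows the statistic
recovers a monotone gradient under Dirichlet noise — not that it would
survive the full error structure of amplicon data.

The ripple-geometry ensemble draws wavelengths uniformly over the
observed 0.15–0.20 m range with height a fixed fraction (default 0.115)
of wavelength.

## Numerical choices and degenerate inputs

* Relaxation time is restricted to (0.5, 2.0]; unit conversion enforces
  lattice Mach < 0.1 and raises when no admissible mapping exists.
* Ripples must be resolved by at least `height ≥ 4·dx` (raised
  otherwise); a zero-height ripple degenerates cleanly to a flat bed.
* Tertile thresholds on a laterally uniform run would collapse; the
  classifier widens degenerate cut points symbolically so a constant
  exposure yields one class everywhere.
* The agreement statistic refuses fewer than three positioned samples and
  skips constant abundance vectors (undefined rank correlation).
* Divergence of the flow solver (`|u| ≥ c_s` or `rho ≤ 0`) raises with
  the step number; non-convergence within `max_steps` is flagged, not
  raised.

## Known limitations

* 2-D vertical slice: no spanwise structure, no 3-D horseshoe vortices.
* Static geometry: no sediment transport, ripple migration or erosion.
* BGK at `tau` near 0.5 trades accuracy at high Reynolds number for cost;
  the reference run's Re ≈ 100 (on ripple height) is at the low end of
  field conditions.
* The gray-LBM solid fraction is a resistance parameter, not a measured
  porosity; no permeability calibration is attempted.
* Mat classes are a monotone re-coding of exposure tertiles, not a
  mechanistic growth model; agreement with synthetic tables tests the
  statistic, not mat ecology.
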