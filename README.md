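# ripplemat

Benthic boundary-layer flow over porous sand ripples, and the redox niche
zonation of shallow-vent microbial mats.

At shallow-water hydrothermal vents, bottom currents shape the permeable
sandy seabed into ripples (15–20 cm crest to crest), and the flow over that
microtopography re-organises the chemistry that surface-attached microbial
mats experience: accelerated flow and a pressure minimum over the crest,
boundary-layer separation and a weak recirculation eddy on the lee flank,
stoss-side overpressure pumping oxygenated seawater into the sand, and a
trough that traps reduced, H2S-rich vent fluid. Mats record this as a
colour gradient — white in the trough, yellow and light brown on the
flank, Cyanobacteria-rich brown at the crest.

`ripplemat` is a desk-scale model of that whole chain, for microbial
ecologists and benthic modellers who want the hydrodynamic side of mat
zonation without a CFD cluster:

* **geometry** — parametric asymmetric ripple + sand bed rasterised to a
  per-cell solid-fraction grid; physical ↔ lattice unit conversion under
  Reynolds matching.
* **lbm_flow** — D2Q9 BGK lattice-Boltzmann shear flow (moving lid,
  periodic in x) over and through porous sediment via a mass-conserving
  gray (partial bounce-back) scheme; optional Brinkman drag mode and a
  mass-conserving vent inflow. Numba-compiled inner loop with a pure
  numpy reference implementation held to round-off agreement in tests.
* **scalar_transport** — passive O2 / H2S / temperature on the frozen
  velocity field: explicit MUSCL finite-volume stepper plus an exact
  sparse steady solve with a discrete maximum principle; Darcy–Rayleigh
  guard enforcing the advection-only thermal regime.
* **diagnostics** — streamfunction, separation/reattachment points,
  recirculation eddies, surface-pressure profile with stoss/lee means,
  sediment–water exchange fluxes, O2 penetration depth.
* **niche_map** — tertile-based monotone classifier from surface (O2,
  H2S) exposure to the ordered mat classes white < yellow < light_brown
  < brown, and a sign-adjusted Spearman statistic quantifying agreement
  between predicted zonation and positioned community tables.
* **synthetic_data** — seeded Dirichlet community tables around the
  observed storm-succession and ripple-gradient compositions, and random
  ripple-geometry ensembles.

The model in one line: shear flow `u_top` drives a D2Q9 lattice with
viscosity `nu = (tau - 1/2)/3`; sediment cells with solid fraction `ns`
damp momentum by `(1 - ns)` per step (Darcy-like gray LBM); scalars obey
`∂C/∂t + u·∇C = ∇·(D(1-ns)∇C)` with fixed-value boundaries; zonation
agreement is `mean_t [ sign_t · SpearmanRho(position, abundance_t) ]`
over indicator taxa *t* (Cyanobacteria +, *Sulfurimonas* −).

## Worked example

```bash
ripplemat run --out out --seed 0
```

runs the packaged reference configuration — one 0.175 m × 0.02 m ripple
on an 88×60 lattice (dx ≈ 2 mm), lid velocity 0.05, Re ≈ 100 on the
ripple height, vent under the lee trough — and prints:

```json
{
  "flow": {
    "converged": true,
    "steps": 224500,
    "residual": 9.991411434281383e-07
  },
  "agreement": {
    "statistic": 0.7842762814941464,
    "scenario": "ripple_gradient"
  }
}
```

`out/` then contains the porosity, velocity, density and scalar grids
(CSV + VTK legacy), the surface-pressure and exchange-flux profiles, the
per-column zonation (`zonation.csv`), the synthetic community table, and
`report.json` with the diagnostics summary. For this run the report
shows one lee-side eddy (54 cells, centre in the trough at column 87),
boundary-layer separation at column 76 on the lee flank (reattachment at
16), the surface-pressure minimum at column 69, four columns downstream
of the crest (~5 % of a wavelength), stoss-mean relative pressure
+8.6e-6 against a lee mean of −1.0e-5 (lattice units), and a predicted
mat sequence running white (trough) → yellow → brown (crest). The
agreement statistic 0.78 is the sign-adjusted mean Spearman correlation
between sample position and indicator-taxon abundance in the synthetic
ripple-gradient table drawn for this seed: strongly positive, i.e. the
table's Cyanobacteria rise and *Sulfurimonas* fall toward the crest just
as the predicted zonation orders them; Dirichlet noise keeps it below
the perfect score of 1.

Library use mirrors the CLI: `ripplemat.reference_config()` →
`pipeline.run_pipeline(cfg, "out")`, or stage by stage
(`make_ripple` → `run_to_steady` → `run_scalars_to_steady` →
`diagnose` → `zonation_profile` → `zonation_agreement`).

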