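# Methods

## Scope and model structure

`gelget` models one well of a 3D gene-electrotransfer experiment as a 1-D
slab: depth `z` runs from the gel surface (`z = 0`) to the gel bottom
(`z = d`), with the plasmid reservoir or injection bolus, the gel, and the
embedded cells all homogeneous in the lateral directions. The pipeline is

1. **media** — transport coefficients of the gel (diffusivity `D`,
   electrophoretic mobility `μ`) and molecular-scale quantities of the
   plasmid (effective charge, Stokes mobility, pore-size sieving regime);
2. **diffusion** — the pre-pulse concentration profile `c(z, t_inc)`;
3. **electrokinetics** — pulse protocols, drift displacement `L_E`,
   drift–diffusion transport during the train, and dosimetry;
4. **transfection** — the efficiency map `%TR = K ∫ g(c) dz` and the
   calibration of `K` (and jointly `D`);
5. **synthetic** — counted-well data generation for validation;
6. **cli** — thin command wrappers with schema-checked YAML configs.

Out of scope by design: membrane-permeabilization mechanics, 2-D/3-D field
inhomogeneity, gel swelling, DNA degradation, electrode electrochemistry and
pH fronts (the coulomb dosage is reported as a proxy only), and any
mechanistic efficiency gain for HV+LV or alternating-polarity protocols
(these are representable as protocols, but their benefit is a membrane-level
effect the 1-D transport model cannot see).

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| gel thickness `d` | 0.95 | mm | the 3D collagen model's thickness |
| well cross-section `S` | 1.9 | cm² | 180 µl of gel over a 24-well area |
| `D` (0.35 % gel) | 3×10⁻⁸ | cm²/s | anchored measurement |
| `D` (3 % gel) | 0.01×10⁻⁸ | cm²/s | anchored measurement |
| `D` (free medium) | 5×10⁻⁸ | cm²/s | anchored measurement |
| `μ` (0.35 %, 200 µs…10 ms) | 0.2–2.8×10⁻⁸ | m²/Vs | anchored, duration-dependent |
| `μ` (3 %, any duration) | 0.03×10⁻⁸ | m²/Vs | anchored, duration-independent plateau |
| plasmid length | 4700 | bp | the GFP plasmid used in the reference system |
| charge per bp | 0.066 | e | screened effective charge; assumed to be in elementary charges per bp |
| `R_g` | 100 | nm | supercoiled-plasmid coil size |
| viscosity (free solution) | 1.0×10⁻³ | Pa·s | water at room temperature |
| elementary charge | 1.602176634×10⁻¹⁹ | C | exact |
| DNA molar mass | 650 | g/mol/bp | double-stranded DNA convention |
| dose-response breakpoints | 10 / 40 / 200 | µg/ml | linear top / toxicity onset / extinction |
| `K` | calibrated | %TR/(µg/ml·mm) | condition-dependent; never hard-coded |
| grid spacing | 2 | µm | resolves the erfc front for t_inc ≥ 1 min |
| solver step `dt` | 1 | s | accuracy knob only (implicit scheme) |
| injection spread | 250 | µm | no measured injection geometry; mid-gel bolus |

Interpolation of `D` and `μ` between gel-fraction anchors is piecewise
linear in `(fraction, log₁₀ value)` — transport coefficients fall roughly
exponentially with gel density — and anchors are reproduced exactly.
Outside the anchored range the nearest segment is continued and an
`ExtrapolationWarning` is raised; pulse durations outside 100 µs–100 ms are
clamped to that window with the same warning. The 3 % gel mobility is a
single duration-independent value, as its anchor series shows no duration
dependence.

The sieving relation `R_p = 118·A^(−0.74)` nm is implemented as printed.
Note it does not reproduce every pore-size figure quoted for tumor
collagen densities (at 0.252 % w/w it gives ≈ 327 nm where ~270 nm is
sometimes quoted); no reconciliation is attempted. The Ogston/reptation
boundary `R_g > R_p/2` is strict: the tie classifies as Ogston.

The generator voltage `U` is an explicit protocol field, never derived from
`E × electrode gap`: the published energy factors for the 8-pulse schedules
imply `U = 160 V` while `0.8 kV/cm × 4 mm` would give 320 V. The package
keeps the two quantities independent and raises a `ConfigurationError` if an
energy factor is requested without `U`.

## Numerical choices

* **Half-space solution.** `c₀·erfc(z/2√(Dt))` interprets the applied
  plasmid solution as an undepleted constant-concentration reservoir
  (Dirichlet top). At `t = 0` the profile is `c₀` at the surface node and
  zero below.
* **Finite-difference oracle.** Crank–Nicolson on the uniform grid;
  unconditionally stable, so `dt` is an accuracy parameter. The bottom
  boundary is always no-flux; the top is Dirichlet or no-flux. With the
  mirror-ghost Neumann discretization the scheme conserves discrete mass to
  solver round-off. Against the erfc solution the max error is < 0.03 % of
  `c₀` for 1–30 min incubations. Whether a bounded-gel or half-space
  treatment better reflects long incubations is left to the caller: both are
  provided, and they agree while `2√(Dt) < d/3`.
* **Kernel convolution.** `convolve_profile` applies a sampled Gaussian
  kernel (truncated at 8σ, tail < 10⁻¹⁵). `boundary='open'` zero-pads and
  warns with the clipped-mass fraction when > 10⁻⁶ of the mass leaves the
  grid; `boundary='reflect'` is exactly the method of images for no-flux
  walls and conserves mass to machine precision. Accuracy for profiles with
  jumps is second order in `dz/σ` (an endpoint Euler–Maclaurin term), so the
  analytic-equivalence tests use finer grids.
* **Injected bolus.** A Gaussian at mid-gel (σ = 250 µm) with image sources
  at both faces, renormalized so the column holds the dose exactly. The
  1-D idealization ignores lateral spreading. During incubation the bolus
  diffuses with reflecting boundaries — the free-space convolution the
  composition could also use leaks ~10 % of the dose out of a 0.95 mm slab
  at these widths, which is unphysical for a gel in a closed well.
* **Drift–diffusion splitting.** During pulses, first-order upwind
  advection with automatic CFL sub-stepping (positivity-preserving; the
  centroid shift is exact away from boundaries, which is what the drift
  oracle checks), alternated with Crank–Nicolson diffusion during pulses,
  inter-pulse gaps and inter-segment lags. Mass advected past the gel bottom
  accumulates in an explicit `exited_mass` tally. Orthogonal-both-polarity
  segments produce zero net depth drift; their gross per-axis sweep is
  reported as metadata.
* **%TR integral.** Trapezoid rule on the standard grid (refinement changes
  the value by < 0.1 %). The dose-response correction `g` is applied inside
  the integral, and clipping of `%TR` to [0, 100] happens after integration;
  operating regimes here sit far below saturation, where the choice is
  immaterial, but it is config-visible.
* **Calibration.** The model is linear in `K` (before clipping), so the
  least-squares `K` is a closed-form projection. The joint `(K, D)` fit
  profiles `K` out and runs a bounded scalar minimization over `log₁₀ D`
  (D ∈ [10⁻¹⁰, 10⁻⁶] cm²/s). Identifiability is structural, not numeric:
  top-applied half-space profiles are self-similar (`c = c₀·f(z/√(Dt))`), so
  those wells constrain only the product `K·√D`; injected wells conserve the
  dose, so their efficiency level pins `K` alone. A recovery design needs
  both arms.

## What the synthetic generator does and does not emulate

Each well's transfected count is drawn from `Binomial(n_cells, %TR/100)`
with the true `%TR` computed by the forward model; an optional beta-binomial
layer inflates variance by a configurable factor (default 1). Per-well cell
counts default to 500 (a plausible manual-count scale across ≥ 10
microscope fields; configurable, and not a claim about any real dataset).
RNG streams are keyed per `(seed, condition, replicate)`, so datasets are
reproducible and extendable without perturbing existing draws.

The default recovery design is 10 conditions × 5 wells: top-applied
90 µg/ml and injected 18.2 µg, each at 15/30/60/120/240 min incubation.
The longer incubations extend the usual 30 min protocol to strengthen the
time-ladder; they remain within what a gel experiment can do. Routine
triplicate generation (`wells_per_condition = 3`) mirrors ordinary practice.

Passing recovery tests show that the calibration machinery inverts the
model under its own noise assumptions at realistic count depths. They do
not show that real wells are binomial (manual counting adds field-selection
and segmentation variance), that `K` transfers between plated, gel-top and
embedded conditions (it demonstrably does not — it absorbs cell density and
pulse efficacy), or that the 1-D homogeneous-slab transport picture holds in
structured tissue.

## Known limitations

* The efficiency map treats the pulse protocol's effect entirely through
  `K`; protocol comparisons beyond transport (HV+LV synergy, polarity
  effects) are outside the model, and measured efficiencies for those
  protocols enter only as fixture observations for comparison tables.
* The dose-response plateau (10–40 µg/ml) and the linear decline to
  extinction at 200 µg/ml are interpolations between two stated facts (a
  linear regime and a toxicity onset); both breakpoints and the extinction
  point are configuration parameters.
* Mobility and diffusivity anchors are treated as given constants; their
  provenance measurements are not re-derived, and extrapolation to other
  gel chemistries is log-linear faith, flagged by warnings.
* The observed-efficiency scale of a real experiment (a few percent in 3D
  gels) emerges here only after calibrating `K`; with the default `K = 1`
  the examples happen to land on that scale, but that is illustration, not
  validation.
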