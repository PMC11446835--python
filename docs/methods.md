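# Methods

## The model

`dermalkin` simulates ethanol transport from capillary blood, through the
skin, into the air immediately above it.  One square centimetre of skin is
described as four well-mixed compartments in series — capillary blood,
viable epidermis, stratum corneum, and a supradermal gas space ventilated
with fresh air — each holding ethanol mass `beta * V * P` (solubility x
volume x partial pressure).  Writing conservation of mass per compartment
gives four coupled linear ODEs in the partial pressures:

    beta_b A_c L_c dP_c/dt = Qdot beta_b (P_a - P_c) - g_ce (P_c - P_e)
    beta_e A   L_e dP_e/dt = g_ce (P_c - P_e) - k_es A (P_e - P_s)
    beta_s A   L_s dP_s/dt = k_es A (P_e - P_s) - g_sg (P_s - P_g)
    beta_g A   L_g dP_g/dt = Vdot beta_g (P_I - P_g) + g_sg (P_s - P_g)

Boundary-adjacent fluxes use half-layer conductances (`g_ce = D_e beta_e
A_c / (L_e/2)` from the capillary wall to the epidermis centre, `g_sg = D_s
beta_s A / (L_s/2)` from the stratum-corneum centre to the gas boundary).
The epidermis-stratum-corneum interface uses a mass transfer coefficient
built from the two half-layer resistances in series,

    k_es = [ L_e/(2 D_e beta_e) + L_s/(2 D_s beta_s) ]^-1 ,

which assumes a linear partial-pressure profile between the two layer
centres.  The arterial pressure `P_a(t)` is imposed from a blood alcohol
concentration (BAC) profile; the inspired air is ethanol-free (`P_I = 0`,
configurable).  Sweat transport, skin hydration and temperature dependence
of the transport coefficients are outside the model.

The system is linear in the pressures, so trajectories scale exactly with
the input (asserted to 1e-6 in tests), and the steady state under constant
input has a closed form used as a verification oracle.

### Units

Solubilities are Ostwald-style: mL ethanol vapour per 100 mL medium per
Torr.  The "per 100 mL" convention is carried by every `beta` and cancels
throughout the balance equations (each term holds exactly one solubility);
it only matters in unit conversion.  Gas-compartment pressure is reported as
the equivalent BAC that would be in equilibrium with it:

    C_g = (beta_b / beta_g) * P_g * M_etoh * 100 / (R T)   [g/dL]

`beta_b/beta_g` is the dimensionless blood:gas partition coefficient (~1758)
and `P_g M/(R T)` the gas-phase mass concentration in g/cm^3.  The molar
mass does not appear in the compact textbook statement of this relation, but
no combination of the remaining symbols yields g/dL; with it, the factor is
0.4187 g/dL per Torr (~0.19 Torr at 0.08 g/dL), consistent with ethanol
partition physiology.  The inverse map turns the imposed BAC profile into
`P_a(t)`.

Internally everything runs in seconds (the transport parameters are per
second); all public interfaces use hours, converted only at the boundary.

### Parameters

Eleven physiological parameters (three solubilities, two diffusivities,
three thicknesses, capillary area, blood flow, ventilation flow) carry
independent uniform uncertainty ranges of 10-50% about literature averages;
see `src/dermalkin/parameter_schema.json` for values and units.  Fixed
constants: `beta_g = 0.132`, `L_c = 0.0007` cm, `A = 1` cm^2, `T = 310.15` K,
`M_etoh = 46.07` g/mol, `R = 62,360` Torr cm^3/(mol K).  Validation rejects
(never clamps) out-of-range values so that sampling code cannot silently
distort the uniform distributions.

## Numerics

* **Stiffness.**  Isolated-compartment relaxation times span 0.12 s
  (capillary) to ~19 min (stratum corneum); the slowest coupled eigenmode is
  45 min.  The system is integrated with LSODA (adaptive stiff/non-stiff
  multistep) with the constant Jacobian supplied, `rtol = 1e-8`,
  `atol = 1e-12` Torr (pressures are O(0.1) Torr).
* **Input kinks.**  `P_a(t)` is evaluated analytically inside the right-hand
  side and the integration is restarted at each profile breakpoint (profile
  start, BAC peak, BAC zero), so step control never straddles a slope
  discontinuity.
* **Grid.**  Output is sampled every 0.5 min; the default horizon is the
  profile's zero time plus 8 h (the supradermal tail needs ~4 h to clear at
  average parameters; sensitivity draws use a 16 h margin because slow
  corners of the parameter box roughly double the tail time constant).
  Halving the grid changes no metric by more than 0.1%.
* **Initial condition.**  All compartments start at zero (alcohol-free
  skin), matching profiles that start at BAC = 0.
* **Mass balance.**  The residual compares compartment accumulation against
  net delivered mass, with the boundary-flux integrals computed by composite
  Simpson quadrature on the output grid split at the input kinks; it stays
  below 1e-6 (relative to gross supply) on every default run.  An
  augmented-state quadrature cross-check puts the model's intrinsic
  conservation error at ~2e-12; the grid residual is quadrature-limited.
* **Metric extraction.**  The peak is refined by a local quadratic through
  the three samples around the discrete maximum (removes grid quantisation
  from the peak delay at the ~0.1-min level; on non-smooth synthetic peaks
  the refiner can overshoot by O(grid step)).  The washout rate uses central
  differences without smoothing — the solved curve is smooth — with an
  optional moving-average window, default off.  The zero crossing is located
  on the descending limb only, by linear interpolation between bracketing
  samples (the rising limb also crosses the threshold, upward, which is not
  the quantity of interest).

### The zero threshold

The zero-delay metric `T_ZD` needs a "zero" detection threshold on `C_g`.
The package default is **1e-4 g/dL**.  A nominal threshold of 0.001 g/dL is
sometimes quoted for this quantity, but it is internally inconsistent with
the reported ~3.9 h zero-delay asymptote: the slowest system eigenmode has a
45-min time constant, and moving the threshold a decade (0.001 -> 1e-4)
lengthens the asymptotic delay by exactly `ln(10) * 0.751 h = 1.73 h` — the
difference between the 2.17 h obtained at 0.001 g/dL and the reported
3.9 h, which the 1e-4 default reproduces to better than 1%.  Every other
reference output (peak-ratio range, peak-delay range, washout asymptote) is
threshold-independent and reproduces identically under either choice.  The
threshold is a parameter of `compute_metrics` and of the config file.

## Simulation experiments

The factorial design crosses eight absorption times (0.25-2.0 h,
quarter-hour steps) with five peak concentrations (0.02-0.10 g/dL, 0.02
steps) at a fixed 0.018 g/dL/h elimination rate — 40 cells, average
parameters, ~2 s total on one CPU.  Four outputs summarise each cell: peak
equivalent concentration `C_g,max` (and its ratio to the blood peak),
maximum washout rate `WO_max`, peak delay `T_PD`, zero delay `T_ZD`.  Cells
are independent pure functions of their inputs and run sequentially; every
CLI experiment writes a JSON manifest (version, resolved config, output
checksums) sufficient to reproduce it.

## Sensitivity analysis

Parameter uncertainty is propagated by Latin hypercube sampling: each
parameter's uniform range is split into `n = 50` equal-probability
intervals, each interval used exactly once per parameter (sampling without
replacement), with the interval midpoint assigned — so sorted sample columns
are deterministic and only the per-parameter permutations are random.
Permutations are drawn from a single seeded generator in fixed parameter
order, making results platform-reproducible; a nine-profile convenience
runner (absorption 0.5/1/2 h x peak 0.02/0.05/0.10 g/dL) uses seeds
`seed+0..seed+8`.

The sensitivity index is the partial rank correlation coefficient (PRCC):
rank-transform all columns, regress the parameter's ranks and the output's
ranks each on the other ten parameters' ranks, and correlate the residuals.
Ties receive average ranks.  Significance uses a two-sided Student's t-test
with `df = n - 2 - k` (k = 10 controlled covariates) — conventions for the
degrees of freedom differ, so this one is stated explicitly.  An independent
implementation via the inverse of the full rank-correlation matrix
(`PRCC_j = -c^{jy}/sqrt(c^{jj} c^{yy})`) serves as a cross-check oracle; the
two routes agree to 1e-10 on every ensemble.

At `n = 50` the sampling standard deviation of a PRCC near zero is roughly
`1/sqrt(n - k - 3) ~ 0.16`, so single-draw PRCC values for weakly coupled
parameters (|true PRCC| < ~0.3) are sign-unstable across seeds.  Dominant
coefficients (stratum-corneum diffusivity ~ +0.97 and thickness ~ -0.95
against the peak concentration) are stable to a few hundredths; the test
suite therefore checks medians over 20 seeds for the dominant entries and
treats weak entries' signs as draw-dependent.

## What the tests do and do not show

All inputs are synthetic by construction (the study design imposes idealised
triangular BAC profiles); there is no measured-data path in the package.
Passing tests demonstrate that the implementation solves the stated
equations correctly (oracle agreement, conservation, linearity, refinement
convergence) and reproduces the reference quantitative behaviour under the
same idealised conditions.  They say nothing about how well the model
describes real skin: triangular blood profiles ignore absorption-phase
curvature, the parameter box ignores inter-parameter correlation, and the
model omits sweat, hydration and sensor effects entirely.

## Verification oracles built into the package

* `steady_state` — closed-form fixed point of the linear system; long-run
  simulations converge to it within 0.1%.
* `refine_layers` — splits each skin layer into `n` sub-layers with the same
  half-layer resistance rule (`n = 1` reproduces the base model to 1e-10);
  as `n` grows the solution is Cauchy-convergent toward the
  continuum-diffusion limit, and the refined peak is earlier and slightly
  higher than the lumped model's — quantifying the lumped model's
  under-accounting of diffusive conductance within the stratum corneum.
* `mass_balance_residual` and `prcc_matrix_inverse` — described above.

## Known limitations

* The compartmental description under-represents stratum-corneum diffusive
  conductance relative to a spatially resolved treatment (see
  `refine_layers`); delays are accordingly a few minutes long.
* Tabulated profiles are interpolated linearly; strongly curved inputs
  should be tabulated finely.
* The LHS design assumes independent parameters; correlations (e.g. between
  layer thickness and diffusivity under hydration) are not representable.
* `T_ZD` depends on the detection threshold (see above); comparisons across
  studies must fix it explicitly.
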