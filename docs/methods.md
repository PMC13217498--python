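# Methods

## Scope and model structure

`blanchsim` couples one-dimensional radial heat conduction in an infinite
cylinder to first-order enzyme-inactivation kinetics and a three-pool pectin
degradation model, and layers equivalent-time (TTI) analysis and inverse
parameter estimation on top. The intended regime is hot-water blanching of
green beans: product diameter ~9 mm, bath temperatures 35–100 °C, treatment
times up to ~20 min. Calcium–pectin crosslinking, turgor mechanics,
non-enzymatic demethoxylation, freezing kinetics and mass-transfer physics
of leaching are deliberately outside the model; leaching is handled only
through its empirical linearity in equivalent time.

## Heat transfer

Effective thermophysical properties come from the Choi–Okos component
polynomials evaluated once at a property temperature (default 25 °C) and
held constant: density by the reciprocal mixture rule, specific heat
mass-fraction-weighted, conductivity volume-fraction-weighted (parallel
model). For the default green-bean composition (water 0.90, carbohydrate
0.07, protein 0.02, ash 0.006, fat closing the balance) this gives
λ_eff ≈ 0.585 W m⁻¹ K⁻¹ and ρc_p ≈ 4.05 MJ m⁻³ K⁻¹. Holding properties
constant makes the problem linear, which is what produces the
reduced-temperature collapse of heating curves and is verified to 1e-9.

The finite-volume grid uses n equal-radial-width, cell-centered control
volumes (default n = 5). "Equal size" could also be read as equal volume;
equal width was chosen as the simplest cell-centered construction, and the
refinement tests show the choice is immaterial at the reported tolerances.
Interior face conductances are λ·2πr_face/Δr per unit length; the axis face
carries zero flux; the outer face couples the boundary node to the bath
through the film coefficient in series with the half-cell conduction
resistance. Time integration is explicit Euler with the step chosen as 0.2
times the positivity/stability bound min_i (ρc_p V_i / ΣG_i); a
user-supplied step is validated against that bound and rejected otherwise.
The discrete energy balance (stored enthalpy change vs time-integrated
boundary flux) closes to round-off by construction and is asserted at 1e-6.

Verification is against the classical Bessel eigenfunction series for a
convectively heated infinite cylinder. At n = 40 cells the volume-averaged
temperature matches the series within 0.5 % of the span at all times; at
the production n = 5 the early transient (boundary layer thinner than Δr)
deviates by up to ~1.4 % of span for a few seconds, which moves 5-min
whole-bean activity predictions by well under 2 % absolute (tested 5 vs 20
cells). Bath programs are piecewise segments, constant by default; the
"2 min come-up" of typical protocols is modelled as immersion in a
constant-temperature bath, with an optional linear ramp per segment since
no ramp shape is specified by typical protocols.

The average temperature is volume-weighted (annulus cross-sections as
weights). An unweighted node mean would be an equally defensible reading
for pure reporting, but enzyme amount scales with tissue volume, so the
volume weighting is used consistently for temperature, activity and
firmness averages.

## Inactivation kinetics

All rate constants use the reference-anchored Arrhenius form
k(T) = k_ref·exp[−ΔE/R(1/T − 1/T_ref)] with R = 8.314 J mol⁻¹ K⁻¹; exponent
arguments are clipped at ±700 so that physically "instantaneous" rates at
multi-MJ/mol energies stay finite in float64.

Residual activity along a history is the exact exponential of the
trapezoid-integrated rate, A = exp(−∫k dt) — unconditionally positive and
stable, with quadrature as the only error — rather than Euler stepping of
the ODE. Biphasic enzymes are the convex combination
f_I·exp(−∫k_I) + (1−f_I)·exp(−∫k_II); the labile-isoform share is stored as
a fraction, with a constructor accepting the ratio EnzI(0)/EnzII(0)
(converted as a/(1+a)) because both parameterizations occur in practice,
and the object records which one it came from.

### Packaged parameter sets

Fitted green-bean values shipped as defaults (rates s⁻¹, energies J/mol):

| set | parameters |
|---|---|
| LOX, biphasic | ratio 0.53; k_I 0.36e-3, ΔE_I 282e3; k_II 0.028, ΔE_II 96e3 |
| POD, biphasic | fraction 0.70; k_I 12e-5, ΔE_I 0.37e6; k_II 6.8e-4, ΔE_II 4.7e6 |
| PME, monophasic | k 91e-3, ΔE 315e3 |
| texture | k_β(373.15 K) 0.2e-3, ΔE_β 200e3; k_m(338.15 K) 0.011, ΔE_m 100e3; k_d = PME set; DM0 0.8 |
| heat transfer | h_ext 1000 W m⁻² K⁻¹, T0 25 °C |

The reference temperatures of the LOX, POD and PME inactivation rates were
not part of the published fits. The packaged defaults assume 60 °C for LOX
(mid-range of the 55–70 °C isothermal extract data) and 80 °C for POD and
PME (mid-range of the 70–100 °C whole-bean data); the rate objects carry
`assumed_t_ref=True` to flag this. The texture references are quoted as
373 K / 338 K and are read as rounded 100 °C / 65 °C. Because every
headline result in this package is a generate-then-refit closure, these
assumptions set the *conditions* of the recovery experiments rather than
their outcome. The 100 kJ/mol "PME" energy in the texture set is assigned
to the activity rate k_m (not the denaturation rate, which comes from the
monophasic inactivation fit); both assignments are overridable in config.

## Pectin system and firmness

The three-pool system
∂t[Pm] = −k_β[Pm] − k_m[Pm][PME], ∂t[Pe] = +k_m[Pm][PME],
∂t[PME] = −k_d[PME], with [PME] dimensionless (normalized to 1, so k_m is
per unit relative PME), plus Psol accumulating the β-eliminated pectin.
Firmness is (Pm+Pe)/(Pm(0)+Pe(0)); demethylation moves pectin between Pm
and Pe without changing their sum, so firmness loss is attributable to
β-elimination alone, and this is asserted as a property test.

The default integrator is a conservative exponential-splitting scheme:
[PME] is the exact exponential of the integrated k_d; Pm is the exponential
of the integrated total removal rate; the pectin removed from Pm per step
is split between Pe and Psol in proportion to the per-step integrals of the
two removal channels. Total pectin is conserved to round-off by
construction, the scheme is unconditionally stable and positive, and it is
second-order accurate (verified against closed forms and by
self-refinement, coarse vs 10× finer < 1e-8). The grid is refined
automatically so max(k)·Δt ≤ 0.2 (factor capped at 400). This scheme was
chosen over fixed-step RK4 because the PME denaturation rate implied by the
packaged parameters reaches ~30 s⁻¹ at 100 °C, which would force
impractically small fixed steps; classical RK4 remains available as
`method="rk4"` with a stiffness guard that rejects steps with k·Δt > 0.1.

## Coupling and averaging order

The conduction problem is solved once per bath program; kinetics are then
evaluated on each control volume's local history and volume-averaged.
Averaging order is fixed and load-bearing: the activity of the averaged
temperature differs measurably from the averaged activity during the
heating transient (a regression test pins the convention by asserting they
differ at mid-decay). Whole-bean observables at requested sampling times
come from linear interpolation on the solver grid; sampling outside the
solved window raises rather than extrapolating.

## Equivalent time

t_eff uses the same trapezoid quadrature as the activity integrals, which
makes the identity −ln A = k_ref·t_eff hold to better than 1e-10 for
matched activation energy — the premise that lets a first-order enzyme act
as a time–temperature integrator. t_eff is computed from the
volume-averaged product temperature by default (matching the
single-product-temperature usage of TTI practice); a per-cell option is
available through the per-cell histories. The qualitative colour test is
calibrated by OLS of assay activity on 1/τ; the activation-energy
optimization scans a uniform grid and refines the best point by
golden-section search on r² (squared Pearson correlation of the linear, or
optionally log-linear, quality-vs-t_eff regression), breaking ties toward
the smaller energy and flagging essentially flat responses (max r² < 0.05).

## Estimation

Losses: pooled RMSE with predictions interpolated to measurement times
(single N over all temperatures of a slice), and the multi-experiment L2
Σ_j (1/N_j)Σ_i r_ij² in which each experiment contributes its mean squared
error. The direction of "weighted by the number of data points" is
ambiguous; the mean-per-experiment reading was adopted so densely sampled
experiments cannot dominate, with the sum reading selectable
(`mode="sum"`). Observations are sorted by experiment and time before any
loss is computed, so row order can never change a fit. Activities are fit
on the natural scale.

Bounded quasi-Newton fitting uses L-BFGS-B on parameters mapped to [0, 1]
(log10 scale for rates) so finite-difference gradients are well scaled.
The documented convergence tolerance (default 1e-4) is a *relative*
function-value criterion; because scipy's `ftol` compares improvements
against max(|f|, 1) and therefore behaves absolutely near zero loss, the
solver is restarted from its stopping point until one restart improves the
loss by less than the tolerance relative to its value. Multistart (extra
starts drawn log-uniformly in bounds from a fixed seed) is available for
multimodal problems; the default is the single user-supplied start.

Cyclic coordinate descent minimizes one parameter at a time, in declared
order, by golden-section search within bounds (line-search tolerance 1e-4
of the normalized interval), repeating until a full cycle improves the loss
by less than 0.5 % (configurable) or 40 cycles. A non-improving first cycle
with the loss still above tolerance is flagged as a possible local trap.
This mirrors the manual practice used when five-parameter biphasic fits
defeat quasi-Newton solvers.

## Synthetic data

The generators emit every dataset shape the estimation and TTI layers
consume — isothermal extract-decay curves; whole-bean activity, firmness
and averaged-temperature records from the coupled model; qualitative colour
times τ = c/activity; leaching metrics a + b·t_eff — with the generating
parameters embedded in the dataset metadata. Noise is multiplicative
Gaussian (assay errors scale with signal), truncated at zero, from a
mandatory seed; magnitudes are not calibrated to any particular instrument
and default to zero. What the generators do *not* emulate: assay chemistry,
bean-to-bean size variability, batch effects on bath temperature, or
measurement-time jitter. Passing recovery tests therefore demonstrate
identifiability and correctness of the inverse machinery under the model,
not robustness to real-data artefacts.

## Recovery experiments (problem sizes)

The headline recovery workflows use desk-scale grids chosen to mirror the
designs the parameter sets came from: heating curves at 42/54/72/92 °C
sampled every 15 s for 7 min (112 points); LOX extract curves at
55–70 °C × 8 times ≤ 900 s (48 points); whole-bean PME at 70–90 °C ×
{60…600 s} (20 points); firmness at 80–100 °C × {120…1200 s} (25 points);
whole-bean POD at 70/80/90/100 °C × {60…900 s} (20 points). Perturbed
starts multiply every free parameter by 2.0 (film coefficient), 1.5 (LOX,
PME, texture) or 1.3 (POD). All refits recover the generating values within
1–2 % relative (the POD isoform fraction within 0.005 absolute under the
0.5 % cyclic stopping rule).

## Known limitations

* The 5-cell grid under-resolves the first seconds of the heating
  transient; quantities read during the first ~10 s of immersion carry a
  percent-level discretization error.
* The heat-stable LOX isoform's low activation energy (96 kJ/mol) leaves a
  small residual rate even in ice water (~0.4 % activity loss over 5 min),
  so cooling steps are not perfectly inert for LOX.
* Biphasic TTI behaviour is out of scope: equivalent-time analysis assumes
  monophasic first-order kinetics, and applying it to a biphasic enzyme is
  only meaningful per isoform.
* The activation-energy optimizer assumes a monotone linear (or log-linear)
  quality–t_eff relationship; strongly nonlinear quality responses need the
  full mechanistic model instead.
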