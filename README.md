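# blanchsim

Mechanistic modelling of hot-water blanching of vegetables — the brief heat
treatment given to green beans (and most other vegetables) before freezing to
inactivate the enzymes that would otherwise ruin texture, colour and flavour
in frozen storage. Blanching is a balancing act: peroxidase (POD) and
lipoxygenase (LOX) must be knocked out, but over-blanching above ~90 °C
solubilizes pectin by β-elimination and softens the product, and it leaches
nutrients into the water. `blanchsim` packages the coupled models needed to
study that trade-off quantitatively, together with the inverse-fitting and
synthetic-data machinery to estimate and validate every parameter in them.

It is aimed at food-process engineers and kinetic modellers who want a
tested, scriptable alternative to one-off spreadsheet fits.

## The model

**Heat transfer.** A bean pod is an infinite cylinder of radius R heated by a
stirred bath. With temperature-independent effective properties (Choi–Okos
correlations from the proximate composition),

```
ρ_eff c_p,eff ∂T/∂t = (λ_eff / r) ∂/∂r ( r ∂T/∂r ),   −λ_eff ∂T/∂r |_R = h_ext (T_R − T_bath)
```

solved by a cell-centered finite-volume scheme (5 equal-width control volumes
by default) with explicit Euler steps inside the stability bound. Linearity
makes heating curves collapse in the reduced temperature
θ = (T − T0)/(T_e − T0).

**Enzyme inactivation.** First-order decay with reference-anchored Arrhenius
rates k(T) = k_ref · exp[−ΔE/R (1/T − 1/T_ref)]. POD and LOX are *biphasic*
(a heat-labile and a heat-stable isoform, each first order); PME is
monophasic. Along a temperature history the residual activity is

```
A(t) = f_I exp(−∫k_I dt) + (1 − f_I) exp(−∫k_II dt)
```

computed per control volume and then volume-averaged — never from the
averaged temperature.

**Texture.** Methylated pectin Pm in the middle lamella is lost to thermal
β-elimination (rate k_β) and to PME demethylation (k_m·[PME]); demethylated
pectin Pe resists β-elimination; PME denatures first order (k_d).
Normalized firmness is F̂ = (Pm + Pe)/(Pm(0) + Pe(0)) with initial degree of
methylation DM(0) = 0.8.

**Equivalent time.** For first-order Arrhenius kinetics a dynamic history is
summarized by t_eff = ∫ exp[ΔE_a/R (1/T_ref − 1/T)] dt, the holding time at
T_ref with the same effect; −ln A = k_ref·t_eff exactly. The package
calibrates the qualitative guaiacol POD test (colour time τ ∝ 1/activity)
and optimizes ΔE_a so that a quality attribute (firmness, leaching metrics)
becomes linear in t_eff.

**Estimation.** Predictions are interpolated to measurement times; the loss
is either pooled RMSE or a per-experiment-mean L2; fitting is bounded
quasi-Newton (L-BFGS-B, rates on a log scale, optional multistart) or cyclic
coordinate descent with golden-section line searches and a 0.5 %
relative-improvement stopping rule for ill-conditioned five-parameter
biphasic problems.

## Worked example

Five minutes in a 92 °C bath for a 9 mm green bean, packaged parameter sets:

```python
import blanchsim as bs
from blanchsim import params as P

geometry = P.default_geometry()          # 9 mm diameter pod, 5 control volumes
composition = P.default_composition()    # 90 % water, 7 % carbs, 2 % protein
bath = P.default_bath(92.0, 300.0)       # 5 min at 92 C, h_ext = 1000 W/m2K

result = bs.simulate_blanching(
    geometry, composition, bath,
    enzymes={"pod": P.pod_biphasic(), "lox": P.lox_biphasic(),
             "pme": P.pme_monophasic()},
    pectin=P.texture_parameters(),
    tti={"quality": bs.TTIParameters(110e3, 363.15)},
)
for t in (60.0, 180.0, 300.0):
    acts = [result.at_times(result.average_activities[e], [t])[0]
            for e in ("pod", "lox", "pme")]
    firm = result.at_times(result.average_firmness, [t])[0]
    teff = result.at_times(result.teff["quality"], [t])[0]
    print(f"t={t:5.0f} s  POD={acts[0]:.3f}  LOX={acts[1]:.3f}  "
          f"PME={acts[2]:.3f}  firmness={firm:.3f}  teff={teff:5.1f} s")
```

prints

```
t=   60 s  POD=0.800  LOX=0.074  PME=0.221  firmness=1.000  teff= 10.6 s
t=  180 s  POD=0.399  LOX=0.000  PME=0.000  firmness=0.998  teff=131.7 s
t=  300 s  POD=0.164  LOX=0.000  PME=0.000  firmness=0.996  teff=277.5 s
```

LOX and PME are gone within three minutes while the heat-stable POD fraction
survives the whole treatment — which is why POD works as a conservative
blanching-intensity indicator — and firmness is barely touched at 92 °C.
The equivalent time lags wall-clock time while the bean interior is still
heating up.

A CLI covers the same ground from config files:
`blanchsim simulate`, `generate`, `fit`, `tti`, `tti-fit`, `calibrate-pod`,
`validate-config` (see `blanchsim --help`).

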