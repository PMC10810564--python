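# brainco2

Does hypercapnia change brain oxygen metabolism? Raised arterial CO₂
reliably increases cerebral blood flow (CBF), but multimodal monitoring in
volunteers shows something a pure flow effect cannot explain: a large, slow
oxidation of cytochrome-c-oxidase (a rise in the NIRS [oxCCO] signal of
~0.58 µM) together with a small *fall* in the cerebral metabolic rate for
oxygen (CMRO₂) when the same data are pushed through a Fick-style
calculation. `brainco2` is a compact dynamic-systems implementation of
that analysis for physiologists and NIRS researchers: a forward model of
CO₂-driven circulation coupled to mitochondrial electron transport, two
candidate CO₂→metabolism pathways, a modified-Fick ΔCMRO₂ estimator, a
synthetic hypercapnia-challenge generator, and a genetic-algorithm fitting
pipeline that asks which pathway reconciles measured ΔCBF%, TOI and
[oxCCO] simultaneously.

The two competing mechanisms are expressed as single parameters acting on
the filtered CO₂ stimulus c₂(t) (first-order filter, time constant τ_c2):

- **substrate supply** — NADH production is scaled by `(1 − supps·c2)`;
  positive `supps` raises the NAD/NADH ratio, oxidises the Cu_A centre
  ([oxCCO] ↑) and lowers oxygen consumption;
- **ATP demand** — the ATP-synthase proton re-entry flux
  `L_CV = r_CV·u_eff·(e^θ − 1)`, θ = (Δp − Δp_CV0)/Z, is scaled through
  `u_eff = u·(1 + uf·c2)`; lowering demand raises the proton motive force
  Δp, *reduces* Cu_A ([oxCCO] ↓) and lowers consumption.

Because the two mechanisms move [oxCCO] in opposite directions for the same
CMRO₂ fall, the [oxCCO] signal discriminates them. Fitting both regimes
(six free parameters each: the metabolic gain plus R_autc, τ_c, τ_c2, P_an,
CBF_n) against {[oxCCO]}, {TOI, ΔCBF%} and all three channels reproduces
the study's asymmetry: only the supply mechanism matches the [oxCCO] rise
*and* the Fick-estimated CMRO₂ fall at once.

## Worked example

```python
import numpy as np
from brainco2 import (ChallengeSpec, make_inputs, make_observations,
                      default_parameters, simulate, fick_delta_cmro2,
                      FickConfig, FitConfig, fit_parameters)

spec = ChallengeSpec(seed=1)          # 600 s record, CO2 on at 100 s, off at 400 s
inputs = make_inputs(spec)            # MABP, SpO2, PaCO2 drivers (+2 kPa step)
obs = make_observations("descriptive", spec, inputs)

win = spec.plateau_mask(inputs.t)     # last 100 s of the challenge

# 1. unoptimised model: flow rises, [oxCCO] and CMRO2 barely move
sim = simulate(default_parameters(), inputs)
print(f"model dCBF  {sim.dCBF_pct[win].mean():+.1f} %")
print(f"model oxCCO {sim.oxCCO[win].mean():+.4f} uM")

# 2. Fick inversion of the observations: CMRO2 falls
fick = fick_delta_cmro2(obs.t, obs.dCBF_pct, inputs.SpO2, obs.TOI, FickConfig())
print(f"Fick dCMRO2 {fick[win].mean():+.1f} %")

# 3. supply-regime fit against all three channels
cfg = FitConfig(regime="supply", target_set="all", seed=1,
                population=16, generations=8)
fit = fit_parameters(obs, inputs, cfg)
fitted = simulate(fit.model_parameters(), inputs)
print(f"fitted supps {fit.parameters['supps']:+.3f}")
print(f"fitted oxCCO {fitted.oxCCO[win].mean():+.2f} uM (observed +0.58)")
base = fitted.CMRO2[inputs.t <= 100].mean()
print(f"fitted dCMRO2 {100*(fitted.CMRO2[win].mean()/base - 1):+.1f} %")
```

prints (the fit takes a few minutes):

```
model dCBF  +66.3 %
model oxCCO +0.0002 uM
Fick dCMRO2 -5.5 %
fitted supps +0.244
fitted oxCCO +0.51 uM (observed +0.58)
fitted dCMRO2 -20.6 %
```

Reading: the unmodified CO₂→flow model moves [oxCCO] four orders of
magnitude less than observed, and the Fick estimate says metabolism *falls*
while the plain model says it rises slightly. A fitted CO₂→substrate-supply
restriction (supps > 0, delayed by τ_c2 ≫ τ_c) reproduces the [oxCCO]
plateau to within 15% with a negative ΔCMRO₂ — the demand regime cannot do
both (run it with `regime="demand"` and compare signs).

There is also a CLI mirroring the library
(`brainco2 synth | preprocess | fick | fit | run`); `brainco2 run --config
analysis.yaml --out results/` executes the whole pipeline — unoptimised
run, supps/uf sweeps, Fick comparison, both regimes × three target sets
with repeats — and writes tables, plots and a verdict.

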