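# Methods

## The scientific question

Hypercapnia (raised arterial CO₂) reliably increases cerebral blood flow
(CBF), but its effect on the cerebral metabolic rate for oxygen (CMRO₂) has
been contested for decades. Non-invasive multimodal monitoring — transcranial
Doppler for CBF velocity, broadband NIRS for the tissue oxygenation index
(TOI) and the cytochrome-c-oxidase redox signal ([oxCCO]) — shows that a
~2 kPa end-tidal CO₂ rise produces a large, slow oxidation of the Cu_A
centre of cytochrome oxidase alongside the expected CBF and TOI rises, while
a Fick-style inversion of the same data indicates a small *fall* in CMRO₂.
A plain CO₂→flow model predicts neither. This package implements a forward
dynamic-systems model with two candidate CO₂→metabolism pathways and asks
which one reconciles all three signals:

- **substrate supply** (`supps` > 0): CO₂ throttles delivery of reducing
  equivalents (NADH) to the electron-transport chain, raising the NAD/NADH
  ratio, oxidising Cu_A and lowering oxygen consumption;
- **ATP demand** (`uf`): CO₂ scales the proton re-entry flux through ATP
  synthesis, moving the proton motive force Δp and, through it, both flux
  and Cu_A redox state.

## The forward model

Nine states: filtered arterial pressure `P_filt`; two first-order-filtered
CO₂ stimuli `c1` (vascular, time constant τ_c) and `c2` (metabolic, τ_c2),
each the PaCO₂ excursion normalised by a 15 mmHg (≈2 kPa) reference so that
the standard challenge drives c ≈ 1; vessel radius `r`; NADH fraction;
reduced Cu_A and haem-a3 fractions; mitochondrial O₂; and Δp.

Circulation. The radius relaxes (t_r = 5 s) to
`r_n · (1 + k_r · tanh(R_autc·c1 − R_autp·(P_filt/P_an − 1)))`, a saturating
combination of CO₂ vasodilation and pressure autoregulation. Flow is
`CBF = K_flow · r⁴ · (MABP − P_v)` (Poiseuille radius dependence), TOI is
the arterial/venous saturation mix with an arterial weight that follows the
arterial volume (∝ r²) around its baseline fraction AVR_n = 0.25, and venous
saturation comes from the quasi-steady extraction identity
`SvO2 = SaO2 − CMRO2/(CBF·H_b)`.

Mitochondria. Three electron-transfer steps carry flux f1 (NADH → Cu_A,
lumping complexes I–III), f2 (Cu_A → a3) and f3 (a3 + O₂), each mass-action
in its donor/acceptor with an exponential Δp back-pressure
`exp(−γᵢ·(Δp−Δp_n)/Z)`. Proton pumping p1·f1 + p2·f2 + p3·f3 (p = 4, 1, 1
per electron) charges Δp through a buffering capacitance chosen so Δp
settles with a ~5 s time constant; it discharges through ATP synthesis
`L_CV = r_CV · u_eff · (e^θ − 1)`, θ = (Δp−Δp_CV0)/Z, clamped at zero below
Δp_CV0 (no synthase reversal), and a linear leak `k_leak·Δp`. NADH is a
dynamic pool: production `k_prod · u^(2·D_NADH) · (1 − supps·c2) ·
NAD/(NAD + K_N)` against consumption f1/2. The two CO₂ pathways enter
exactly once each: `supps` multiplies NADH production, `uf` scales demand
as `u_eff = u·(1 + uf·c2)`. Functional activation itself is held at u = 1
and its direct flow coupling is disabled (R_u = 0), so CBF responds to CO₂
and pressure only.

A dynamic NADH pool (rather than a fixed NAD:NADH ratio) is what lets a
supply restriction simultaneously raise NAD/NADH, oxidise Cu_A and lower
steady-state flux; an algebraic ratio cannot reduce flux on its own.
The ordering γ2 > γ1 (defaults 6 > 2, with γ3 = 0.5) is a hard invariant:
it makes a demand *reduction* (Δp rise) choke the Cu_A→a3 step harder than
the NADH→Cu_A step, so electrons back up on Cu_A and [oxCCO] falls — the
behaviour that separates the two mechanisms observationally.

## Calibration

Users state the operating point, not rate constants. At nominal inputs
(MABP = P_an = 90 mmHg, SpO₂ = 0.98, PaCO₂ = 37.5 mmHg) the calibration
solves k1, k2, k3, k_prod, D_O2, K_flow, r_CV and k_leak so the model sits
exactly at: CBF_n = 0.0083 s⁻¹ (~50 ml·100 g⁻¹·min⁻¹), CMRO2_n = 0.024
mM O₂ s⁻¹, Δp_n = 145 mV, Cu_A 67% oxidised, a3 10% reduced, NAD/NADH = 9,
O₂_mito = 0.024 mM, and a baseline proton-leak fraction of 25%. The
resulting baseline TOI is 73.6%. Calibration fails loudly (naming the
violated target) if the targets are inconsistent, e.g. a CMRO2_n that
exceeds what CBF_n·H_b can deliver. The vasoreactivity gain default
R_autc = 0.3 follows in closed form from requiring a 4 %CBF/mmHg
small-signal steady-state CO₂ reactivity
(R_autc = 0.04·dPaCO2_ref/(4·k_r)); the tanh saturation brings the
large-excursion response below the linear extrapolation.

## Numerics

Simulation uses LSODA (default rtol 1e-8/atol 1e-10; fits use 1e-6/1e-9).
The system is stiff: the a3 redox pool relaxes at ~500 s⁻¹ against a 600 s
record. A fixed-step RK4 integrator (`simulate_rk4`) is the brute-force
cross-check; its step must sit inside the RK4 stability region for the
fastest pool, so equivalence tests run at dt = 2 ms and agree with the
adaptive solver to better than 1e-4 relative. Steady states are found by
root-finding from the nominal point with a long-relaxation fallback, and
must satisfy max|dy/dt| < 1e-9; at any converged steady state the proton
budget (Σpᵢfᵢ = L_CV + L_leak) and oxygen budget (J_O2 = CMRO₂) close to
1e-8. Driver signals are linearly interpolated between samples, so a
"step" recorded on a 1 s grid acts at the half-sample point — filter
time-constant tests account for this.

## Synthetic data

The generator emulates the study protocol: 600 s record at 1 Hz, CO₂ on at
100 s and off at 400 s, end-tidal rise targeting +2 kPa with a 20 s
saturating ramp, MABP +5 mmHg, SpO₂ constant. *Plateau* statistics are
means over the last 100 s of the challenge window throughout the package.

Descriptive mode emulates the group-mean monitoring responses with
saturating-ramp curves: ΔCBF +45% and ΔTOI with a fast (30 s) time
constant, Δ[oxCCO] +0.58 µM with a slow (180 s) one — the delayed metabolic
response. Only the 0.58 µM plateau is anchored to a reported value; the
group-mean CBF/TOI traces are not published as numbers, so those plateaus
are package defaults chosen for physiological consistency: +45% ΔCBF
matches ~4 %/mmHg reactivity over a ~11–15 mmHg excursion, and ΔTOI =
+8.5 %-points is chosen so that the Fick inversion of the descriptive data
yields ≈ −5% ΔCMRO₂, the direction and magnitude the Fick comparator is
expected to report. (A smaller ΔTOI of +3 points would flip the Fick sign
positive and make the dataset internally inconsistent with the
extraction-based CMRO₂ fall.) All plateaus are config fields, not
constants. Default observation noise is i.i.d. Gaussian at ~2% of each
channel's dynamic range; driver noise defaults to zero (group-mean inputs).
What descriptive mode does *not* emulate: subject-level variability,
drifts, motion artefacts, or arterial/venous ratio changes during the
challenge — passing tests say the pipeline discriminates mechanisms under
clean group-mean-like conditions, not that it would on any individual
recording.

Forward mode generates observations from known parameters via the model
itself (plus optional noise) and exists for parameter-recovery and
regime-discrimination experiments where ground truth is required.

## Fitting

Cost: mean absolute difference per channel, weighted by the inverse SD of
the observed channel over the full record (including baseline, which
anchors absolute TOI/CBF levels), summed over the chosen target set —
{oxCCO}, {TOI, ΔCBF%} or all three. Each regime frees exactly six
parameters: its metabolic gain plus [R_autc, τ_c, τ_c2, P_an, CBF_n], with
bounds supps/uf ∈ [−0.5, 0.5], τ_c ∈ [1, 60] s, τ_c2 ∈ [1, 600] s, R_autc
∈ [0.25×, 4×] nominal, P_an ∈ [70, 110] mmHg, CBF_n ∈ [0.6×, 1.4×] nominal.

The optimiser is a seeded real-coded GA in normalised [0,1]⁶ coordinates:
tournament selection (k = 3), SBX crossover (η = 15, rate 0.9), per-gene
Gaussian mutation (rate 0.1, σ = 0.1 span), one elite. The GA best is then
polished by restarted bounded Powell searches; restarts matter because the
cost surface has a curved, weakly identified ridge along the
R_autc/P_an/CBF_n trio (several circulatory settings produce nearly the
same CBF curve — the same trade-off shows up as the baseline-anchoring
behaviour of the fitted CBF_n). The mechanism parameters (supps/uf, τ_c2)
converge tightly regardless; on noiseless forward data the generating
supps and τ_c2 are recovered to well under 1%. Failed simulations inside
the search are penalised with +∞ and the run continues. `repeat_fits` runs
the whole fit at seeds seed+i and reports per-parameter means and SDs
across repeats — the spread is the reported measure of identifiability.
The production default is 200 repeats; tests and the acceptance script run
2–3 repeats with small populations, which is enough because repeats
converge to the same optimum on well-identified data.

## Known limitations

- The mitochondrial sub-model is a minimal reduction: its functional forms
  (tanh radius target, exponential Δp inhibition, linear leak, Michaelis O₂
  term, NAD-dependent production) are this package's choices, constrained
  by steady-state targets and sign behaviour rather than by enzyme-level
  data. Quantitative couplings inherit that freedom: in this calibration a
  fitted supply restriction reproducing a 0.58 µM oxCCO plateau implies a
  ~20% CMRO₂ fall, steeper than the ~5% the Fick comparator reports — the
  sign structure, not this ratio, is the robust output.
- The demand pathway moves steady-state flux only weakly (it mostly moves
  Δp), so on {TOI, CBF}-only targets `uf` is poorly identified here.
- The Fick estimator assumes a static arterial/venous ratio; the model's
  own optics let the arterial weight track r², and the residual
  disagreement between the two conventions is at the ~1 %-point TOI level
  for a 45% CBF rise. The estimator's ratio form is exactly
  baseline-offset invariant only to first order.
- Absolute [oxCCO] scale rests on cytox_tot = 2.2 µM of NIRS-visible Cu_A
  and its 67% baseline oxidation; both are approximate in vivo.
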