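# Example pipeline configuration for `brainco2 run --config ... --out results/`.
# Every key shown here is optional; omitted keys take these same defaults
# (see brainco2.pipeline.DEFAULT_CONFIG).

seed: 1

data:
  source: descriptive          # descriptive | forward | csv
  challenge: {}                # ChallengeSpec field overrides, e.g. {dETCO2: 2.0}
  true_parameters: {}          # forward source: generating model parameters
  inputs_csv: null             # csv source: path to t,MABP,SpO2,ETCO2 file
  observations_csv: null       # csv source: path to t,Vmca|dCBF_pct,TOI,oxCCO file

stages: [unoptimized, sweeps, fick, fits, report]

challenge_window: null         # [onset, offset] s; defaults to the spec's window
sweep_values: [-0.05, 0.0, 0.05]

fick:
  avr: 0.25                    # arterial fraction used to invert TOI
  baseline_window: [0.0, 100.0]

fit:
  repeats: 20                  # desk scale; the full protocol uses 200
  population: 24
  generations: 20
  polish: true
  polish_maxfev: 1600
  regimes: [supply, demand]
  target_sets: [oxcco, toi_cbf, all]
  bounds: {}                   # per-parameter [lo, hi] overrides

plots: true
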