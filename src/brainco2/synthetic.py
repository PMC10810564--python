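"""Synthetic hypercapnia-challenge data.

Emulates the study protocol — 300 s of CO2 added to the inspired gas,
targeting a ~2 kPa end-tidal rise inside a 600 s record — in two modes:

``descriptive``
    smooth saturating-ramp observation curves hitting configured plateau
    changes (fast vascular CBF/TOI response, slow delayed oxCCO rise),
    emulating the group-mean monitoring data;
``forward``
    observations produced by the forward model from known parameters, for
    parameter-recovery and regime-discrimination experiments.

Plateau changes are defined as the mean over the last 100 s of the
challenge window, the same statistic the analysis pipeline reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import InputTrace, ObservedTrace, kpa_to_mmhg
from .model import simulate
from .parameters import ModelParameters

__all__ = ["ChallengeSpec", "make_inputs", "make_observations", "PLATEAU_WINDOW_S"]

#: Plateau statistics are means over the last this-many seconds of the challenge.
PLATEAU_WINDOW_S = 100.0


@dataclass
class ChallengeSpec:
    """Protocol and (descriptive-mode) response-shape definition."""

    duration: float = 600.0        # s
    fs: float = 1.0                # Hz
    onset: float = 100.0           # s, CO2 on
    offset: float = 400.0          # s, CO2 off (300 s challenge)
    ramp_tau: float = 20.0         # s, stimulus saturating-ramp time constant

    # baselines
    MABP0: float = 90.0            # mmHg
    SpO2_0: float = 0.98           # fraction
    ETCO2_0: float = 5.0           # kPa

    # stimulus amplitudes
    dETCO2: float = 2.0            # kPa
    dMABP: float = 5.0             # mmHg

    # descriptive-mode observation plateaus (changes over baseline)
    dVmca_pct: float = 45.0        # %  (≈4 %/mmHg reactivity over a 2 kPa step)
    dTOI: float = 8.5              # %-points; with dVmca above, Fick gives ≈ -5% CMRO2
    doxCCO: float = 0.58           # uM
    TOI0: float = 73.6             # % baseline (matches the calibrated model's TOI_n)
    resp_tau: float = 30.0         # s, vascular response time constant
    oxcco_tau: float = 180.0       # s, delayed metabolic response time constant

    # i.i.d. Gaussian noise SDs (defaults ~2% of each channel's dynamic range)
    noise_dCBF: float = 0.9        # %
    noise_TOI: float = 0.17        # %-points
    noise_oxCCO: float = 0.012     # uM
    noise_MABP: float = 0.0        # mmHg (inputs are group means; default clean)
    noise_SpO2: float = 0.0
    noise_ETCO2: float = 0.0       # kPa

    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.onset < self.offset < self.duration:
            raise ValueError("require 0 <= onset < offset < duration")
        for name in ("noise_dCBF", "noise_TOI", "noise_oxCCO", "noise_MABP",
                     "noise_SpO2", "noise_ETCO2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dVmca_pct", "dTOI", "doxCCO"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def t(self) -> np.ndarray:
        return np.arange(0.0, self.duration, 1.0 / self.fs)

    def plateau_mask(self, t) -> np.ndarray:
        return (t >= self.offset - PLATEAU_WINDOW_S) & (t <= self.offset)


def _ramp(t: np.ndarray, onset: float, offset: float, tau: float) -> np.ndarray:
    """Saturating rise after onset, exponential return after offset; max ~1."""
    y = np.zeros_like(t)
    on = (t >= onset) & (t < offset)
    y[on] = 1.0 - np.exp(-(t[on] - onset) / tau)
    level = 1.0 - np.exp(-(offset - onset) / tau)
    post = t >= offset
    y[post] = level * np.exp(-(t[post] - offset) / tau)
    return y


def _plateau_shape(spec: ChallengeSpec, tau: float, t: np.ndarray) -> np.ndarray:
    """Ramp on grid ``t``, normalised so its plateau-window mean equals 1."""
    shape = _ramp(t, spec.onset, spec.offset, tau)
    mask = spec.plateau_mask(t)
    if not mask.any():
        raise ValueError("input grid does not cover the plateau window")
    return shape / float(shape[mask].mean())


def make_inputs(spec: ChallengeSpec | None = None) -> InputTrace:
    """Driver signals for the challenge (MABP, SpO2, PaCO2), seeded noise."""
    spec = spec or ChallengeSpec()
    t = spec.t
    rng = np.random.default_rng(spec.seed)
    s = _ramp(t, spec.onset, spec.offset, spec.ramp_tau)
    etco2 = spec.ETCO2_0 + spec.dETCO2 * s + rng.normal(0, spec.noise_ETCO2, t.size)
    mabp = spec.MABP0 + spec.dMABP * s + rng.normal(0, spec.noise_MABP, t.size)
    spo2 = np.clip(spec.SpO2_0 + rng.normal(0, spec.noise_SpO2, t.size), 0.0, 1.0)
    return InputTrace(t=t, MABP=mabp, SpO2=spo2, PaCO2=kpa_to_mmhg(etco2))


def make_observations(mode: str, params_or_spec, inputs: InputTrace,
                      noise: dict | None = None, seed: int | None = None
                      ) -> ObservedTrace:
    """Observation traces, either simulated from parameters or descriptive.

    ``mode='forward'`` needs a :class:`ModelParameters`; ``mode='descriptive'``
    needs a :class:`ChallengeSpec` (its plateau fields define the curves).
    ``noise`` overrides the per-channel SDs ``{'dCBF_pct':…, 'TOI':…,
    'oxCCO':…}``; ``seed`` overrides the spec seed (forward mode requires it
    for nonzero noise).
    """
    t = inputs.t
    if mode == "forward":
        if not isinstance(params_or_spec, ModelParameters):
            raise TypeError("forward mode requires ModelParameters")
        sim = simulate(params_or_spec, inputs)
        clean = {"dCBF_pct": sim.dCBF_pct, "TOI": sim.TOI, "oxCCO": sim.oxCCO}
        sd = {"dCBF_pct": 0.0, "TOI": 0.0, "oxCCO": 0.0}
        rng = np.random.default_rng(0 if seed is None else seed)
    elif mode == "descriptive":
        spec = params_or_spec
        if not isinstance(spec, ChallengeSpec):
            raise TypeError("descriptive mode requires a ChallengeSpec")
        fast = _plateau_shape(spec, spec.resp_tau, t)
        slow = _plateau_shape(spec, spec.oxcco_tau, t)
        clean = {
            "dCBF_pct": spec.dVmca_pct * fast,
            "TOI": spec.TOI0 + spec.dTOI * fast,
            "oxCCO": spec.doxCCO * slow,
        }
        sd = {"dCBF_pct": spec.noise_dCBF, "TOI": spec.noise_TOI,
              "oxCCO": spec.noise_oxCCO}
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'forward' or 'descriptive'")

    if noise:
        sd.update(noise)
    data = {k: np.asarray(v, float) + rng.normal(0.0, sd[k], t.size)
            for k, v in clean.items()}
    return ObservedTrace(t=t, **data)
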