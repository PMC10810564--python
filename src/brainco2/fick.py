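"""Modified-Fick estimation of relative CMRO2 change.

The Fick principle gives CMRO2 = CBF * Hb_capacity * (SaO2 - SvO2).  With
NIRS, SvO2 is not measured directly; it is inferred from the tissue
oxygenation index by treating TOI as a static arterial/venous volume mix:

    TOI/100 = AVR * SaO2 + (1 - AVR) * SvO2

Relative CMRO2 then needs only the relative CBF change and the
arterio-venous saturation difference, normalised by its pre-challenge
baseline — no absolute flow or haemoglobin values.  This is the
model-independent comparator for the dynamic-systems fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FickConfig", "FickError", "svo2_from_toi", "fick_delta_cmro2"]


class FickError(ValueError):
    pass


@dataclass
class FickConfig:
    AVR: float = 0.25                 # arterial volume fraction of the NIRS-sampled bed
    baseline_window: tuple = (0.0, 100.0)  # s from record start

    def __post_init__(self):
        if not 0.0 < self.AVR < 1.0:
            raise ValueError("AVR must lie in (0, 1)")


def svo2_from_toi(TOI, SaO2, AVR: float = 0.25):
    """Invert the TOI volume mix for venous saturation (fractions).

    ``TOI`` in percent, ``SaO2`` as a fraction.  Raises if the static-AVR
    assumption puts SvO2 outside [0, SaO2].
    """
    TOI = np.asarray(TOI, dtype=float)
    SaO2 = np.asarray(SaO2, dtype=float)
    if np.any((TOI <= 0) | (TOI >= 100)):
        raise FickError("TOI must lie in (0, 100) percent")
    svo2 = (TOI / 100.0 - AVR * SaO2) / (1.0 - AVR)
    if np.any(svo2 < -1e-12) or np.any(svo2 > SaO2 + 1e-12):
        raise FickError("inferred SvO2 outside [0, SaO2]; the static-AVR "
                        "assumption is violated for these TOI/SaO2 values")
    if svo2.ndim == 0:
        return float(svo2)
    return svo2


def fick_delta_cmro2(t, dCBF_pct, SaO2, TOI, cfg: FickConfig | None = None):
    """Percent CMRO2 change from aligned dCBF%, SaO2 and TOI traces.

    CMRO2_rel(t) = (1 + dCBF%(t)/100) * (SaO2(t) - SvO2(t)) / (SaO2_0 - SvO2_0)
    with the denominator taken as baseline-window means.  Returned in percent.
    """
    cfg = cfg or FickConfig()
    t = np.asarray(t, dtype=float)
    dCBF_pct = np.asarray(dCBF_pct, dtype=float)
    SaO2 = np.asarray(SaO2, dtype=float)
    TOI = np.asarray(TOI, dtype=float)
    if not (t.shape == dCBF_pct.shape == SaO2.shape == TOI.shape):
        raise FickError("traces must be aligned on the same grid")

    lo, hi = cfg.baseline_window
    mask = (t - t[0] >= lo) & (t - t[0] <= hi)
    if not mask.any():
        raise FickError("baseline window lies outside the record")

    svo2 = svo2_from_toi(TOI, SaO2, cfg.AVR)
    extraction = SaO2 - svo2
    ext0 = float(np.mean(extraction[mask]))
    if ext0 <= 0:
        raise FickError("zero baseline oxygen extraction (SaO2_0 == SvO2_0)")
    rel = (1.0 + dCBF_pct / 100.0) * extraction / ext0
    return 100.0 * (rel - 1.0)
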