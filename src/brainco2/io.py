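"""Trace containers, CSV ingest/egress, unit conversion and signal conditioning.

Conventions: time in seconds on a strictly uniform grid (1 Hz after
preprocessing), MABP in mmHg, SpO2 as a fraction in [0, 1] (percent inputs
are detected and rescaled), CO2 as arterial partial pressure in mmHg
(end-tidal kPa is converted at ingest), CBF change in percent relative to
the pre-challenge baseline, TOI in percent, oxCCO in uM change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "InputTrace", "ObservedTrace", "TraceError",
    "read_trace", "write_trace", "lowpass_resample",
    "kpa_to_mmhg", "mmhg_to_kpa", "KPA_TO_MMHG",
]

KPA_TO_MMHG = 7.50062

#: Maximum NaN gap (seconds) bridged by linear interpolation at ingest.
MAX_NAN_GAP_S = 5.0

#: Baseline window (seconds from record start) for Vmca -> dCBF% conversion.
BASELINE_WINDOW_S = 100.0


class TraceError(ValueError):
    pass


def kpa_to_mmhg(x):
    """Convert a pressure from kPa to mmHg (1 kPa = 7.50062 mmHg)."""
    return np.asarray(x, dtype=float) * KPA_TO_MMHG if np.ndim(x) else float(x) * KPA_TO_MMHG


def mmhg_to_kpa(x):
    return np.asarray(x, dtype=float) / KPA_TO_MMHG if np.ndim(x) else float(x) / KPA_TO_MMHG


def _check_grid(t: np.ndarray, what: str) -> None:
    if t.size < 2:
        raise TraceError(f"{what}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TraceError(f"{what}: time must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise TraceError(f"{what}: non-uniform sampling grid")


@dataclass
class InputTrace:
    """Driver signals for the forward model."""

    t: np.ndarray       # s, uniform grid
    MABP: np.ndarray    # mmHg
    SpO2: np.ndarray    # fraction
    PaCO2: np.ndarray   # mmHg

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("MABP", "SpO2", "PaCO2"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != self.t.shape:
                raise TraceError(f"InputTrace: channel {name} length mismatch")
            if not np.all(np.isfinite(v)):
                raise TraceError(f"InputTrace: non-finite values in {name}")
        _check_grid(self.t, "InputTrace")
        if np.any(self.MABP <= 0):
            raise TraceError("InputTrace: MABP must be positive")
        if np.any(self.PaCO2 <= 0):
            raise TraceError("InputTrace: PaCO2 must be positive")
        if np.any((self.SpO2 < 0) | (self.SpO2 > 1)):
            raise TraceError("InputTrace: SpO2 must lie in [0, 1]")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "MABP": self.MABP,
                             "SpO2": self.SpO2, "PaCO2": self.PaCO2})


@dataclass
class ObservedTrace:
    """Monitoring signals used for fitting and the Fick comparison."""

    t: np.ndarray         # s, uniform grid
    dCBF_pct: np.ndarray  # % change from pre-challenge baseline
    TOI: np.ndarray       # %
    oxCCO: np.ndarray     # uM change

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("dCBF_pct", "TOI", "oxCCO"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != self.t.shape:
                raise TraceError(f"ObservedTrace: channel {name} length mismatch")
            if not np.all(np.isfinite(v)):
                raise TraceError(f"ObservedTrace: non-finite values in {name}")
        _check_grid(self.t, "ObservedTrace")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "dCBF_pct": self.dCBF_pct,
                             "TOI": self.TOI, "oxCCO": self.oxCCO})


def _fill_nans(t: np.ndarray, v: np.ndarray, name: str) -> np.ndarray:
    bad = ~np.isfinite(v)
    if not bad.any():
        return v
    dt = float(t[1] - t[0])
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    longest = max(len(s) for s in splits)
    if longest * dt > MAX_NAN_GAP_S:
        raise TraceError(f"channel {name}: NaN gap of {longest * dt:.1f} s "
                         f"exceeds {MAX_NAN_GAP_S:.0f} s")
    if bad[0] or bad[-1]:
        raise TraceError(f"channel {name}: record starts or ends with NaN")
    out = v.copy()
    out[bad] = np.interp(t[bad], t[~bad], v[~bad])
    return out


def read_trace(path, role: str):
    """Read a CSV trace; ``role`` is ``'inputs'`` or ``'observations'``.

    Inputs require columns ``t, MABP, SpO2`` and one of ``ETCO2`` (kPa) or
    ``PaCO2`` (mmHg).  Observations require ``t, TOI, oxCCO`` and one of
    ``Vmca`` (converted to dCBF% against the first-100-s baseline mean) or
    ``dCBF_pct``.
    """
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise TraceError("missing required column 't'")
    t = df["t"].to_numpy(dtype=float)
    _check_grid(t, str(path))

    def col(name):
        return _fill_nans(t, df[name].to_numpy(dtype=float), name)

    if role == "inputs":
        for name in ("MABP", "SpO2"):
            if name not in df.columns:
                raise TraceError(f"inputs file missing channel {name!r}")
        spo2 = col("SpO2")
        if np.nanmax(spo2) > 1.5:  # recorded in percent
            spo2 = spo2 / 100.0
        if "PaCO2" in df.columns:
            paco2 = col("PaCO2")
        elif "ETCO2" in df.columns:
            paco2 = kpa_to_mmhg(col("ETCO2"))
        else:
            raise TraceError("inputs file missing channel 'ETCO2' (or 'PaCO2')")
        return InputTrace(t=t, MABP=col("MABP"), SpO2=spo2, PaCO2=paco2)

    if role == "observations":
        for name in ("TOI", "oxCCO"):
            if name not in df.columns:
                raise TraceError(f"observations file missing channel {name!r}")
        if "dCBF_pct" in df.columns:
            dcbf = col("dCBF_pct")
        elif "Vmca" in df.columns:
            vmca = col("Vmca")
            base = vmca[t - t[0] <= BASELINE_WINDOW_S].mean()
            if base == 0:
                raise TraceError("Vmca baseline mean is zero")
            dcbf = 100.0 * (vmca / base - 1.0)
        else:
            raise TraceError("observations file missing channel 'Vmca' (or 'dCBF_pct')")
        return ObservedTrace(t=t, dCBF_pct=dcbf, TOI=col("TOI"), oxCCO=col("oxCCO"))

    raise ValueError(f"unknown role {role!r}; expected 'inputs' or 'observations'")


def write_trace(trace, path) -> None:
    """Write a trace as CSV with a deterministic column order, full precision."""
    frame = trace.to_frame()
    if len(frame) == 0:
        raise TraceError("refusing to write an empty trace")
    frame.to_csv(path, index=False, float_format="%.17g")


def lowpass_resample(t, values, fc: float = 0.25, order: int = 5,
                     fs_out: float = 1.0):
    """Zero-phase Butterworth low-pass then decimation to ``fs_out``.

    Offline conditioning of raw recordings: a fifth-order 0.25 Hz Butterworth
    applied forward-backward (no phase lag, so filtering cannot masquerade as
    a physiological delay), then sampling on a grid aligned to the record
    start.  Returns ``(t_out, values_out)``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(values, dtype=float)
    _check_grid(t, "lowpass_resample")
    fs_in = 1.0 / float(t[1] - t[0])
    if fs_in < 2.0 * fc:
        raise TraceError(f"input rate {fs_in:.3g} Hz below Nyquist for fc={fc} Hz")
    sos = signal.butter(order, fc, btype="low", fs=fs_in, output="sos")
    # filtfilt needs a record several filter lengths long
    pad = 3 * (2 * order + 1)
    if x.size <= 3 * pad:
        raise TraceError("trace too short for zero-phase filtering")
    y = signal.sosfiltfilt(sos, x)
    step = 1.0 / fs_out
    n_out = int(np.floor((t[-1] - t[0]) / step)) + 1
    t_out = t[0] + step * np.arange(n_out)
    y_out = np.interp(t_out, t, y)
    return t_out, y_out
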