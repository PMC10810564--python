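"""Forward simulation of the circulation + mitochondria model.

State vector (order fixed, see :data:`STATE_NAMES`):

``P_filt``
    first-order-filtered arterial pressure (mmHg) driving autoregulation;
``c1``, ``c2``
    the vascular and metabolic CO2 stimuli — the arterial PaCO2 excursion,
    normalised by ``dPaCO2_ref`` and passed through independent first-order
    filters with time constants ``tau_c`` and ``tau_c2``;
``r``
    lumped resistance-vessel radius, relaxing towards a tanh-saturated target
    set by CO2 reactivity and pressure autoregulation;
``NADH_frac``, ``CuA_red``, ``a3_red``
    mitochondrial redox pools as fractions (their complements are NAD, the
    oxidised CuA centre and oxidised haem a3);
``O2_mito``
    mitochondrial oxygen (mM), fed from capillary blood;
``Dp``
    proton motive force (mV), charged by electron-transport proton pumping
    and discharged through ATP synthesis (L_CV) and leak.

Flow is a fourth-power function of radius times the perfusion pressure.  The
two CO2-metabolism pathways enter exactly once each: ``supps`` scales NADH
production (substrate supply) and ``uf`` scales effective demand inside the
ATP-synthase flux.  With both zero the model is the plain CO2->CBF system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import ModelParameters

__all__ = [
    "STATE_NAMES", "OUTPUT_COLUMNS", "ModelState", "SimOutput",
    "SimulationError", "derivatives", "steady_state", "observables",
    "simulate", "simulate_rk4",
]

STATE_NAMES = ("P_filt", "c1", "c2", "r", "NADH_frac", "CuA_red",
               "a3_red", "O2_mito", "Dp")

OUTPUT_COLUMNS = ("t", "CBF", "dCBF_pct", "Vmca_pct", "TOI", "oxCCO",
                  "CMRO2", "SvO2", "Dp", "NADNADHrat", "O2_mito",
                  "f1", "f2", "f3", "J_O2", "L_CV", "L_leak")


class SimulationError(RuntimeError):
    pass


@dataclass
class ModelState:
    P_filt: float
    c1: float
    c2: float
    r: float
    NADH_frac: float
    CuA_red: float
    a3_red: float
    O2_mito: float
    Dp: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "ModelState":
        return cls(*(float(v) for v in y))

    def validate(self) -> None:
        for n in ("NADH_frac", "CuA_red", "a3_red"):
            v = getattr(self, n)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"state {n}={v} outside [0, 1]")
        if self.O2_mito < 0.0:
            raise ValueError(f"state O2_mito={self.O2_mito} negative")
        if self.Dp < 0.0:
            raise ValueError(f"state Dp={self.Dp} negative")
        if self.r <= 0.0:
            raise ValueError(f"state r={self.r} non-positive")


@dataclass
class SimOutput:
    """Observable time courses on the input grid (arrays, one row per sample)."""

    t: np.ndarray
    CBF: np.ndarray
    dCBF_pct: np.ndarray
    Vmca_pct: np.ndarray
    TOI: np.ndarray
    oxCCO: np.ndarray
    CMRO2: np.ndarray
    SvO2: np.ndarray
    Dp: np.ndarray
    NADNADHrat: np.ndarray
    O2_mito: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    f3: np.ndarray
    J_O2: np.ndarray
    L_CV: np.ndarray
    L_leak: np.ndarray
    states: np.ndarray | None = None  # (n, 9) raw trajectory

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in OUTPUT_COLUMNS})

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _make_rhs(p: ModelParameters, mabp_of_t, sao2_of_t, paco2_of_t):
    """Build a fast scalar RHS closure over plain-float parameters."""
    tau_c, tau_c2, tau_P, t_r = p.tau_c, p.tau_c2, p.tau_P, p.t_r
    dref, PaCO2_n, P_an = p.dPaCO2_ref, p.PaCO2_n, p.P_an
    r_n, k_r, R_autc, R_autp = p.r_n, p.k_r, p.R_autc, p.R_autp
    K_flow, P_v, H_b, K_O2cap, D_O2 = p.K_flow, p.P_v, p.H_b, p.K_O2cap, p.D_O2
    k1, k2, k3, Km_O2 = p.k1, p.k2, p.k3, p.Km_O2
    g1, g2, g3, Z, Dp_n = p.gamma1, p.gamma2, p.gamma3, p.Z, p.Dp_n
    k_prod, K_N, supps, u, D_NADH = p.k_prod, p.K_N, p.supps, p.u, p.D_NADH
    uf, r_CV, Dp_CV0, k_leak = p.uf, p.r_CV, p.Dp_CV0, p.k_leak
    p1, p2, p3, C_buf = p.p1, p.p2, p.p3, p.C_buf
    NAD_pool, cytox_pool = p.NAD_pool, p.cytox_pool
    u_supply = u ** (2.0 * D_NADH)
    exp, tanh = math.exp, math.tanh

    def rhs(t, y):
        (P_filt, c1, c2, r, NADH_frac, CuA_red, a3_red, O2_mito, Dp) = y
        MABP = mabp_of_t(t)
        SaO2 = sao2_of_t(t)
        s = (paco2_of_t(t) - PaCO2_n) / dref

        dc1 = (s - c1) / tau_c
        dc2 = (s - c2) / tau_c2
        dP = (MABP - P_filt) / tau_P
        r_inf = r_n * (1.0 + k_r * tanh(R_autc * c1 - R_autp * (P_filt / P_an - 1.0)))
        dr = (r_inf - r) / t_r

        CBF = K_flow * r ** 4 * (MABP - P_v)
        edp = (Dp - Dp_n) / Z
        f1 = k1 * (1.0 - CuA_red) * NADH_frac * exp(-g1 * edp)
        f2 = k2 * CuA_red * (1.0 - a3_red) * exp(-g2 * edp)
        o2 = O2_mito if O2_mito > 0.0 else 0.0
        f3 = k3 * a3_red * (o2 / (o2 + Km_O2)) * exp(-g3 * edp)

        SvO2 = SaO2 - 0.25 * f3 / (CBF * H_b)
        O2_cap = K_O2cap * 0.5 * (SaO2 + SvO2)
        J_O2 = D_O2 * (O2_cap - O2_mito)

        NADfrac = 1.0 - NADH_frac
        J_prod = k_prod * u_supply * (1.0 - supps * c2) * NADfrac / (NADfrac + K_N)
        u_eff = u * (1.0 + uf * c2)
        theta = (Dp - Dp_CV0) / Z
        L_CV = r_CV * u_eff * (exp(theta) - 1.0) if theta > 0.0 else 0.0
        if L_CV < 0.0:
            L_CV = 0.0
        L_leak = k_leak * Dp

        return (
            dP, dc1, dc2, dr,
            J_prod - f1 / (2.0 * NAD_pool),
            (f1 - f2) / cytox_pool,
            (f2 - f3) / cytox_pool,
            J_O2 - 0.25 * f3,
            (p1 * f1 + p2 * f2 + p3 * f3 - L_CV - L_leak) / C_buf,
        )

    return rhs


def derivatives(state: ModelState, inputs_t, params: ModelParameters) -> np.ndarray:
    """Instantaneous state derivative for constant instantaneous inputs.

    ``inputs_t`` is ``(MABP, SpO2, PaCO2)`` in mmHg / fraction / mmHg.
    """
    y = state.to_array()
    for name, v in zip(STATE_NAMES, y):
        if not math.isfinite(v):
            raise ValueError(f"non-finite state variable {name}={v}")
    MABP, SaO2, PaCO2 = (float(v) for v in inputs_t)
    rhs = _make_rhs(params, lambda t: MABP, lambda t: SaO2, lambda t: PaCO2)
    return np.asarray(rhs(0.0, y), dtype=float)


def _fluxes(params: ModelParameters, y, MABP, SaO2):
    """Vectorised algebraic outputs for state array ``y`` of shape (n, 9)."""
    p = params
    y = np.atleast_2d(np.asarray(y, dtype=float))
    MABP = np.broadcast_to(np.asarray(MABP, dtype=float), y.shape[:1])
    SaO2 = np.broadcast_to(np.asarray(SaO2, dtype=float), y.shape[:1])
    c2 = y[:, 2]
    r = y[:, 3]
    NADH_frac, CuA_red, a3_red, O2_mito, Dp = (y[:, i] for i in range(4, 9))

    CBF = p.K_flow * r ** 4 * (MABP - p.P_v)
    edp = (Dp - p.Dp_n) / p.Z
    f1 = p.k1 * (1.0 - CuA_red) * NADH_frac * np.exp(-p.gamma1 * edp)
    f2 = p.k2 * CuA_red * (1.0 - a3_red) * np.exp(-p.gamma2 * edp)
    o2 = np.clip(O2_mito, 0.0, None)
    f3 = p.k3 * a3_red * (o2 / (o2 + p.Km_O2)) * np.exp(-p.gamma3 * edp)
    CMRO2 = 0.25 * f3
    SvO2 = SaO2 - CMRO2 / (CBF * p.H_b)
    O2_cap = p.K_O2cap * 0.5 * (SaO2 + SvO2)
    J_O2 = p.D_O2 * (O2_cap - O2_mito)

    u_eff = p.u * (1.0 + p.uf * c2)
    theta = (Dp - p.Dp_CV0) / p.Z
    L_CV = np.where(theta > 0.0, p.r_CV * u_eff * (np.exp(theta) - 1.0), 0.0)
    L_CV = np.clip(L_CV, 0.0, None)
    L_leak = p.k_leak * Dp
    return dict(CBF=CBF, f1=f1, f2=f2, f3=f3, CMRO2=CMRO2, SvO2=SvO2,
                J_O2=J_O2, L_CV=L_CV, L_leak=L_leak, CuA_red=CuA_red,
                NADH_frac=NADH_frac, O2_mito=O2_mito, Dp=Dp, r=r)


def observables(state: ModelState, inputs_t, params: ModelParameters) -> dict:
    """Instantaneous observable row for a single state."""
    p = params
    MABP, SaO2, _ = (float(v) for v in inputs_t)
    fx = _fluxes(p, state.to_array()[None, :], [MABP], [SaO2])
    CBF = float(fx["CBF"][0])
    SvO2 = float(fx["SvO2"][0])
    if not -1e-9 <= SvO2 <= SaO2 + 1e-9:
        raise SimulationError(
            f"unphysical oxygen extraction: SvO2={SvO2:.4f} outside [0, SaO2]")
    ratio = (state.r / p.r_n) ** 2
    w_a = p.AVR_n * ratio / (p.AVR_n * ratio + (1.0 - p.AVR_n))
    TOI = 100.0 * (w_a * SaO2 + (1.0 - w_a) * SvO2)
    dCBF_pct = 100.0 * (CBF / p.CBF_n - 1.0)
    return {
        "CBF": CBF,
        "dCBF_pct": dCBF_pct,
        "Vmca_pct": dCBF_pct,
        "TOI": TOI,
        "oxCCO": p.cytox_tot * ((1.0 - state.CuA_red) - p.CuA_ox_n),
        "CMRO2": float(fx["CMRO2"][0]),
        "SvO2": SvO2,
        "Dp": state.Dp,
        "NADNADHrat": (1.0 - state.NADH_frac) / state.NADH_frac,
        "O2_mito": state.O2_mito,
        "f1": float(fx["f1"][0]),
        "f2": float(fx["f2"][0]),
        "f3": float(fx["f3"][0]),
        "J_O2": float(fx["J_O2"][0]),
        "L_CV": float(fx["L_CV"][0]),
        "L_leak": float(fx["L_leak"][0]),
    }


def _nominal_state(p: ModelParameters, MABP, SaO2, PaCO2) -> np.ndarray:
    s = (PaCO2 - p.PaCO2_n) / p.dPaCO2_ref
    r_inf = p.r_n * (1.0 + p.k_r * math.tanh(
        p.R_autc * s - p.R_autp * (MABP / p.P_an - 1.0)))
    return np.array([MABP, s, s, r_inf, p.NADH_frac_n, 1.0 - p.CuA_ox_n,
                     p.a3_red_n, p.O2_mito_n, p.Dp_n])


def steady_state(params: ModelParameters, inputs0, guess: ModelState | None = None,
                 tol: float = 1e-9) -> ModelState:
    """Steady state of the model under constant inputs.

    Root-finding from the nominal baseline (or ``guess``); if the root search
    stalls, the system is relaxed by long integration and the search retried.
    Deterministic.
    """
    MABP, SaO2, PaCO2 = (float(v) for v in inputs0)
    rhs = _make_rhs(params, lambda t: MABP, lambda t: SaO2, lambda t: PaCO2)
    fun = lambda y: np.asarray(rhs(0.0, y))
    y0 = guess.to_array() if guess is not None else _nominal_state(
        params, MABP, SaO2, PaCO2)

    sol = root(fun, y0, method="hybr", tol=1e-13)
    y = sol.x
    if np.max(np.abs(fun(y))) > tol or np.any(~np.isfinite(y)):
        ivp = solve_ivp(rhs, (0.0, 5000.0), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not ivp.success:
            raise SimulationError(f"steady-state relaxation failed: {ivp.message}")
        sol = root(fun, ivp.y[:, -1], method="hybr", tol=1e-13)
        y = sol.x
    resid = float(np.max(np.abs(fun(y))))
    if resid > tol:
        raise SimulationError(
            f"steady state did not converge: max |dy/dt| = {resid:.3e}")
    st = ModelState.from_array(y)
    st.validate()
    return st


def _interp1(t_grid: np.ndarray, v: np.ndarray):
    def f(t):
        return float(np.interp(t, t_grid, v))

    return f


def simulate(params: ModelParameters, inputs, rtol: float = 1e-8,
             atol: float = 1e-10, method: str = "LSODA") -> SimOutput:
    """Integrate the model over an :class:`~brainco2.io.InputTrace`.

    The initial condition is the steady state at the first sample's inputs;
    outputs are sampled on the input grid.  ``rtol``/``atol`` default well
    below the level at which solver choice affects the outputs.
    """
    t = np.asarray(inputs.t, dtype=float)
    mabp = _interp1(t, np.asarray(inputs.MABP, dtype=float))
    sao2 = _interp1(t, np.asarray(inputs.SpO2, dtype=float))
    paco2 = _interp1(t, np.asarray(inputs.PaCO2, dtype=float))

    st0 = steady_state(params, (inputs.MABP[0], inputs.SpO2[0], inputs.PaCO2[0]))
    rhs = _make_rhs(params, mabp, sao2, paco2)
    sol = solve_ivp(rhs, (t[0], t[-1]), st0.to_array(), method=method,
                    t_eval=t, rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t[0]
        raise SimulationError(f"integration failed at t={t_fail:.1f} s: {sol.message}")
    return _outputs_from_trajectory(params, t, sol.y.T,
                                    np.asarray(inputs.MABP, float),
                                    np.asarray(inputs.SpO2, float))


def _outputs_from_trajectory(p: ModelParameters, t, Y, MABP, SaO2) -> SimOutput:
    fx = _fluxes(p, Y, MABP, SaO2)
    SvO2 = fx["SvO2"]
    if np.any(SvO2 < -1e-9) or np.any(SvO2 > SaO2 + 1e-9):
        i = int(np.argmax((SvO2 < -1e-9) | (SvO2 > SaO2 + 1e-9)))
        raise SimulationError(
            f"unphysical oxygen extraction at t={t[i]:.1f} s: SvO2={SvO2[i]:.4f}")
    ratio = (fx["r"] / p.r_n) ** 2
    w_a = p.AVR_n * ratio / (p.AVR_n * ratio + (1.0 - p.AVR_n))
    TOI = 100.0 * (w_a * SaO2 + (1.0 - w_a) * SvO2)
    dCBF = 100.0 * (fx["CBF"] / p.CBF_n - 1.0)
    return SimOutput(
        t=np.asarray(t, float),
        CBF=fx["CBF"], dCBF_pct=dCBF, Vmca_pct=dCBF.copy(), TOI=TOI,
        oxCCO=p.cytox_tot * ((1.0 - fx["CuA_red"]) - p.CuA_ox_n),
        CMRO2=fx["CMRO2"], SvO2=SvO2, Dp=fx["Dp"],
        NADNADHrat=(1.0 - fx["NADH_frac"]) / fx["NADH_frac"],
        O2_mito=fx["O2_mito"], f1=fx["f1"], f2=fx["f2"], f3=fx["f3"],
        J_O2=fx["J_O2"], L_CV=fx["L_CV"], L_leak=fx["L_leak"], states=Y)


def simulate_rk4(params: ModelParameters, inputs, dt: float = 0.002) -> SimOutput:
    """Brute-force fixed-step RK4 integration, sampled on the input grid.

    Cross-check for the adaptive solver.  The step must resolve the fastest
    redox pool (~2 ms at the default calibration).
    """
    t = np.asarray(inputs.t, dtype=float)
    mabp = _interp1(t, np.asarray(inputs.MABP, dtype=float))
    sao2 = _interp1(t, np.asarray(inputs.SpO2, dtype=float))
    paco2 = _interp1(t, np.asarray(inputs.PaCO2, dtype=float))
    st0 = steady_state(params, (inputs.MABP[0], inputs.SpO2[0], inputs.PaCO2[0]))
    rhs = _make_rhs(params, mabp, sao2, paco2)

    y = st0.to_array()
    out = np.empty((t.size, y.size))
    out[0] = y
    h = float(dt)
    for i in range(t.size - 1):
        ti, tnext = t[i], t[i + 1]
        n = max(1, int(round((tnext - ti) / h)))
        hh = (tnext - ti) / n
        tc = ti
        for _ in range(n):
            k1 = np.asarray(rhs(tc, y))
            k2 = np.asarray(rhs(tc + 0.5 * hh, y + 0.5 * hh * k1))
            k3 = np.asarray(rhs(tc + 0.5 * hh, y + 0.5 * hh * k2))
            k4 = np.asarray(rhs(tc + hh, y + hh * k3))
            y = y + (hh / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            tc += hh
        out[i + 1] = y
    return _outputs_from_trajectory(params, t, out,
                                    np.asarray(inputs.MABP, float),
                                    np.asarray(inputs.SpO2, float))
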