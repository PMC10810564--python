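"""Model parameters and baseline calibration.

The forward model couples a lumped cerebral-circulation compartment (CO2 and
pressure reactive vessel radius, flow, oxygen delivery) to a reduced
mitochondrial electron-transport-chain compartment (NADH pool, cytochrome-c
oxidase CuA and haem a3 redox states, matrix oxygen, proton motive force).
Rather than asking users to supply mutually consistent rate constants, the
rate constants ``k1, k2, k3, k_prod, D_O2, K_flow`` and the proton-cycle scale
``r_CV, k_leak`` are *calibrated*: they are solved so that, at the nominal
operating point (MABP = P_an, SpO2 = SaO2_n, PaCO2 = PaCO2_n), the model sits
exactly at the stated physiological baseline (CBF_n, CMRO2_n, Dp_n, the
nominal redox fractions and mitochondrial O2).  Everything downstream —
steady states, simulations, fitting — starts from this self-consistent point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import yaml

__all__ = [
    "ModelParameters",
    "CalibrationError",
    "default_parameters",
    "load_parameters",
    "save_parameters",
    "DERIVED_PARAMETERS",
]


class CalibrationError(ValueError):
    """Raised when no positive-rate solution satisfies a baseline target."""


#: Names filled in by :func:`default_parameters`; they may not be overridden.
DERIVED_PARAMETERS = (
    "k1", "k2", "k3", "k_prod", "D_O2", "K_flow", "r_CV", "k_leak",
    "SvO2_n", "TOI_n",
)


@dataclass
class ModelParameters:
    """All constants of the circulatory + mitochondrial model.

    The first block holds the six fit-able parameters used by the two
    CO2-metabolism regimes (``supps`` for the supply regime, ``uf`` for the
    demand regime, plus the four shared circulatory parameters).
    """

    # --- fit-able set -----------------------------------------------------
    supps: float = 0.0        # CO2 -> substrate-supply gain (positive = supply falls)
    uf: float = 0.0           # CO2 -> ATP-demand gain (negative = demand falls)
    R_autc: float = 0.3       # CO2 vasoreactivity gain (0.3 = 4 %CBF/mmHg small-signal)
    tau_c: float = 30.0       # s, vascular CO2 filter
    tau_c2: float = 30.0      # s, metabolic CO2 filter
    P_an: float = 90.0        # mmHg, normal MABP
    CBF_n: float = 0.0083     # s^-1 (ml blood / ml tissue / s, ~50 ml/100g/min)

    # --- circulation ------------------------------------------------------
    R_autp: float = 1.0       # pressure autoregulation gain
    R_u: float = 0.0          # demand->CBF coupling, disabled
    k_r: float = 0.5          # max fractional radius change
    t_r: float = 5.0          # s, radius relaxation
    tau_P: float = 5.0        # s, pressure filter
    r_n: float = 1.0          # normal vessel radius (arbitrary units)
    P_v: float = 4.0          # mmHg, venous pressure
    dPaCO2_ref: float = 15.0  # mmHg, reference CO2 excursion (~2 kPa) normalising c1/c2
    PaCO2_n: float = 37.5     # mmHg (5 kPa)

    # --- oxygen transport & saturation ------------------------------------
    SaO2_n: float = 0.98      # baseline arterial saturation (fraction)
    H_b: float = 8.9          # mM O2 carried per unit blood at full saturation
    AVR_n: float = 0.25       # baseline arterial fraction of the optically sampled blood
    K_O2cap: float = 0.06     # mM, capillary dissolved-O2 at full saturation
    Km_O2: float = 5.0e-4     # mM, oxygen affinity of the f3 step
    O2_mito_n: float = 0.024  # mM, baseline mitochondrial O2

    # --- mitochondria -----------------------------------------------------
    u: float = 1.0            # baseline metabolic demand (not varied)
    D_NADH: float = 1.0       # exponent of u in substrate production
    NAD_pool: float = 0.3     # mM, total NAD + NADH pool
    NADH_frac_n: float = 0.10  # baseline NADH fraction (NAD/NADH = 9)
    K_N: float = 0.1          # NAD-dependence of substrate production
    cytox_tot: float = 2.2    # uM, NIRS-visible CuA pool
    CuA_ox_n: float = 0.67    # baseline oxidised CuA fraction
    a3_red_n: float = 0.10    # baseline reduced haem a3 fraction
    Dp_n: float = 145.0       # mV, baseline proton motive force
    Dp_CV0: float = 90.0      # mV, Dp at which ATP-synthase flux vanishes
    Z: float = 59.0           # mV, thermodynamic scale
    p1: float = 4.0           # H+ pumped per electron at f1 (complexes I+III)
    p2: float = 1.0           # H+ pumped per electron at f2
    p3: float = 1.0           # H+ pumped per electron at f3
    C_buf: float = 0.18       # proton buffering capacitance (flux units per mV/s)
    gamma1: float = 2.0       # Dp-sensitivity of f1
    gamma2: float = 6.0       # Dp-sensitivity of f2 (> gamma1, see invariants)
    gamma3: float = 0.5       # Dp-sensitivity of f3
    CMRO2_n: float = 0.024    # mM O2 / s, baseline oxygen consumption
    leak_frac_n: float = 0.25  # baseline fraction of pumped protons returning via leak

    # --- derived by calibration (default_parameters) ----------------------
    k1: float = field(default=math.nan)      # f1 rate constant
    k2: float = field(default=math.nan)      # f2 rate constant
    k3: float = field(default=math.nan)      # f3 rate constant
    k_prod: float = field(default=math.nan)  # NADH production rate (fraction/s)
    D_O2: float = field(default=math.nan)    # blood->mitochondria O2 conductance (1/s)
    K_flow: float = field(default=math.nan)  # flow conductance scale
    r_CV: float = field(default=math.nan)    # ATP-synthase proton flux scale
    k_leak: float = field(default=math.nan)  # proton leak conductance (flux/mV)
    SvO2_n: float = field(default=math.nan)  # baseline venous saturation
    TOI_n: float = field(default=math.nan)   # baseline tissue oxygenation index (%)

    # Convenience ----------------------------------------------------------
    @property
    def NADNADHrat_n(self) -> float:
        return (1.0 - self.NADH_frac_n) / self.NADH_frac_n

    @property
    def cytox_pool(self) -> float:
        """CuA pool in mM (cytox_tot is quoted in uM)."""
        return self.cytox_tot * 1e-3

    def validate(self) -> None:
        pos = ("R_autc", "tau_c", "tau_c2", "P_an", "CBF_n", "k_r", "t_r",
               "tau_P", "r_n", "dPaCO2_ref", "PaCO2_n", "H_b", "K_O2cap",
               "Km_O2", "O2_mito_n", "u", "NAD_pool", "K_N", "cytox_tot",
               "Dp_n", "Dp_CV0", "Z", "C_buf", "CMRO2_n")
        for name in pos:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be positive")
        frac = ("SaO2_n", "AVR_n", "NADH_frac_n", "CuA_ox_n", "a3_red_n",
                "leak_frac_n")
        for name in frac:
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"parameter {name} must lie in (0, 1)")
        if not (self.gamma2 > self.gamma1 >= 0.0):
            raise ValueError("gamma2 > gamma1 >= 0 is required (demand reduction "
                             "must reduce CuA oxidation)")
        if self.R_u != 0.0:
            raise ValueError("R_u must be 0 (demand->CBF coupling is disabled)")
        if self.P_an <= self.P_v:
            raise ValueError("P_an must exceed venous pressure P_v")


_FIELD_NAMES = frozenset(f.name for f in fields(ModelParameters))


def default_parameters(overrides: dict | None = None) -> ModelParameters:
    """Build a fully calibrated parameter set.

    ``overrides`` maps parameter names to values; derived names (see
    :data:`DERIVED_PARAMETERS`) are rejected, since they are solved here so
    that the nominal operating point is an exact steady state.
    """
    overrides = dict(overrides or {})
    for name in overrides:
        if name not in _FIELD_NAMES:
            raise ValueError(f"unknown parameter: {name!r}")
        if name in DERIVED_PARAMETERS:
            raise ValueError(
                f"parameter {name!r} is derived by calibration and cannot be "
                f"overridden; adjust its baseline targets instead")
    p = ModelParameters(**overrides)
    p.validate()
    _calibrate(p)
    return p


def _calibrate(p: ModelParameters) -> None:
    """Solve the derived rate constants against the nominal baseline targets."""
    f_n = 4.0 * p.CMRO2_n                      # mM electrons / s through the chain
    CuA_red_n = 1.0 - p.CuA_ox_n
    a3_ox_n = 1.0 - p.a3_red_n
    NADfrac_n = 1.0 - p.NADH_frac_n

    p.k1 = f_n / (p.CuA_ox_n * p.NADH_frac_n)
    p.k2 = f_n / (CuA_red_n * a3_ox_n)
    sat_n = p.O2_mito_n / (p.O2_mito_n + p.Km_O2)
    p.k3 = f_n / (p.a3_red_n * sat_n)

    # NADH production balances complex-I consumption (2 electrons per NADH).
    u_term = p.u ** (2.0 * p.D_NADH)
    p.k_prod = (f_n / (2.0 * p.NAD_pool)) * (NADfrac_n + p.K_N) / (NADfrac_n * u_term)

    # Oxygen delivery: baseline capillary O2 must exceed mitochondrial O2.
    p.SvO2_n = p.SaO2_n - p.CMRO2_n / (p.CBF_n * p.H_b)
    if not 0.0 < p.SvO2_n < p.SaO2_n:
        raise CalibrationError(
            "baseline venous saturation target SvO2_n out of (0, SaO2_n): "
            f"{p.SvO2_n:.4f} — CMRO2_n incompatible with CBF_n*H_b")
    O2_cap_n = p.K_O2cap * 0.5 * (p.SaO2_n + p.SvO2_n)
    if O2_cap_n <= p.O2_mito_n:
        raise CalibrationError(
            f"baseline capillary O2 ({O2_cap_n:.4g} mM) does not exceed the "
            f"O2_mito_n target ({p.O2_mito_n:.4g} mM); no positive D_O2 exists")
    p.D_O2 = p.CMRO2_n / (O2_cap_n - p.O2_mito_n)

    p.K_flow = p.CBF_n / (p.r_n ** 4 * (p.P_an - p.P_v))

    # Proton cycle: split baseline pumping between ATP synthesis and leak.
    pump_n = (p.p1 + p.p2 + p.p3) * f_n
    theta_n = (p.Dp_n - p.Dp_CV0) / p.Z
    if theta_n <= 0.0:
        raise CalibrationError("Dp_n must exceed Dp_CV0 for a forward ATP-synthase flux")
    L_CV_n = (1.0 - p.leak_frac_n) * pump_n
    p.r_CV = L_CV_n / (p.u * (math.exp(theta_n) - 1.0))
    p.k_leak = p.leak_frac_n * pump_n / p.Dp_n

    w_a = p.AVR_n  # r = r_n at baseline
    p.TOI_n = 100.0 * (w_a * p.SaO2_n + (1.0 - w_a) * p.SvO2_n)


def save_parameters(p: ModelParameters, path) -> None:
    """Write parameters as flat YAML (name: value)."""
    data = {f.name: float(getattr(p, f.name)) for f in fields(ModelParameters)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_parameters(path) -> ModelParameters:
    """Read a flat YAML mapping and recalibrate the derived constants."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    overrides = {k: v for k, v in data.items() if k not in DERIVED_PARAMETERS}
    return default_parameters(overrides)
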