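import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainco2.io import InputTrace
from brainco2.model import (ModelState, SimulationError, _fluxes, derivatives,
                            observables, simulate, simulate_rk4, steady_state)
from brainco2.parameters import default_parameters
from brainco2.synthetic import ChallengeSpec, make_inputs


# ---------------------------------------------------------------- derivatives

def test_co2_filter_derivative_after_step(params, baseline_inputs):
    """Immediately after a PaCO2 step the filter slews at (dP/ref)/tau."""
    st0 = steady_state(params, baseline_inputs)
    dP = 7.5
    stepped = (params.P_an, params.SaO2_n, params.PaCO2_n + dP)
    d = derivatives(st0, stepped, params)
    expected = (dP / params.dPaCO2_ref) / params.tau_c
    assert d[1] == pytest.approx(expected, rel=1e-12)
    assert d[2] == pytest.approx((dP / params.dPaCO2_ref) / params.tau_c2, rel=1e-12)


def test_demand_gain_scales_atp_synthase_flux(params, baseline_inputs):
    """u_eff = u*(1 + uf*c2): uf=-0.05 at c2=1 gives 0.95x the L_CV flux."""
    st0 = steady_state(params, baseline_inputs)
    state = ModelState.from_array(st0.to_array())
    state.c2 = 1.0
    p_off = default_parameters()
    p_on = default_parameters({"uf": -0.05})
    lcv_off = observables(state, baseline_inputs, p_off)["L_CV"]
    lcv_on = observables(state, baseline_inputs, p_on)["L_CV"]
    assert lcv_on == pytest.approx(0.95 * lcv_off, rel=1e-12)


def test_non_finite_state_is_named(params, baseline_inputs):
    st0 = steady_state(params, baseline_inputs)
    st0.Dp = float("nan")
    with pytest.raises(ValueError, match="Dp"):
        derivatives(st0, baseline_inputs, params)


@given(
    c2=st.floats(-1.0, 1.5),
    nadh=st.floats(0.01, 0.99),
    cua=st.floats(0.01, 0.99),
    a3=st.floats(0.01, 0.99),
    o2=st.floats(1e-4, 0.05),
    dp=st.floats(100.0, 190.0),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_scalar_rhs_and_vectorised_fluxes_agree(params, c2, nadh, cua, a3, o2, dp):
    """The fast scalar RHS and the vectorised output path share the algebra."""
    state = ModelState(P_filt=90.0, c1=0.3, c2=c2, r=1.05, NADH_frac=nadh,
                       CuA_red=cua, a3_red=a3, O2_mito=o2, Dp=dp)
    d = derivatives(state, (90.0, 0.98, 45.0), params)
    fx = _fluxes(params, state.to_array()[None, :], [90.0], [0.98])
    p = params
    assert d[5] == pytest.approx(
        float(fx["f1"][0] - fx["f2"][0]) / p.cytox_pool, rel=1e-12, abs=1e-12)
    assert d[6] == pytest.approx(
        float(fx["f2"][0] - fx["f3"][0]) / p.cytox_pool, rel=1e-12, abs=1e-12)
    assert d[7] == pytest.approx(
        float(fx["J_O2"][0] - 0.25 * fx["f3"][0]), rel=1e-12, abs=1e-15)
    pump = p.p1 * fx["f1"][0] + p.p2 * fx["f2"][0] + p.p3 * fx["f3"][0]
    assert d[8] == pytest.approx(
        float(pump - fx["L_CV"][0] - fx["L_leak"][0]) / p.C_buf,
        rel=1e-12, abs=1e-12)


# --------------------------------------------------------------- steady state

def test_steady_state_flux_balance(params, baseline_inputs):
    """At any converged steady state J_O2 = CMRO2 and pumping balances re-entry."""
    for dP in (0.0, 5.0, -5.0):
        inp = (params.P_an, params.SaO2_n, params.PaCO2_n + dP)
        stt = steady_state(params, inp)
        ob = observables(stt, inp, params)
        pump = params.p1 * ob["f1"] + params.p2 * ob["f2"] + params.p3 * ob["f3"]
        assert abs(pump - ob["L_CV"] - ob["L_leak"]) < 1e-8
        assert abs(ob["J_O2"] - ob["CMRO2"]) < 1e-8


def test_hypercapnic_steady_state_raises_cbf_and_toi(params, baseline_inputs):
    inp = (params.P_an, params.SaO2_n, params.PaCO2_n + 3.75)
    stt = steady_state(params, inp)
    ob = observables(stt, inp, params)
    assert ob["CBF"] > params.CBF_n
    assert ob["TOI"] > params.TOI_n


# ---------------------------------------------------------------- observables

def test_observables_closed_forms(params, baseline_inputs):
    stt = steady_state(params, baseline_inputs)
    # fully oxidised CuA pool
    stt.CuA_red = 0.0
    ob = observables(stt, baseline_inputs, params)
    assert ob["oxCCO"] == pytest.approx(
        params.cytox_tot * (1.0 - params.CuA_ox_n), rel=1e-12)
    # vanishing arterial weighting: TOI -> venous saturation
    p0 = default_parameters({"AVR_n": 1e-9})
    st0 = steady_state(p0, baseline_inputs)
    ob0 = observables(st0, baseline_inputs, p0)
    assert ob0["TOI"] == pytest.approx(100.0 * ob0["SvO2"], abs=1e-5)


def test_unphysical_extraction_is_an_error(params, baseline_inputs):
    stt = steady_state(params, baseline_inputs)
    stt.r = 0.3  # collapse flow so extraction exceeds arterial supply
    with pytest.raises(SimulationError, match="SvO2"):
        observables(stt, baseline_inputs, params)


# ------------------------------------------------------------------- simulate

def test_constant_inputs_stay_flat(params, make_constant_inputs):
    sim = simulate(params, make_constant_inputs(params, duration=600.0))
    assert np.max(np.abs(sim.CBF / params.CBF_n - 1.0)) < 1e-6
    assert np.max(np.abs(sim.oxCCO)) < 1e-6
    assert np.max(np.abs(sim.Dp / params.Dp_n - 1.0)) < 1e-6


def test_redox_pools_stay_in_bounds_along_trajectory(challenge_inputs):
    sim = simulate(default_parameters({"supps": 0.2}), challenge_inputs)
    states = sim.states
    for idx in (4, 5, 6):  # NADH_frac, CuA_red, a3_red
        assert np.all(states[:, idx] >= -1e-12)
        assert np.all(states[:, idx] <= 1.0 + 1e-12)
    assert np.all(states[:, 7] >= 0.0)   # O2_mito
    assert np.all(states[:, 8] >= 0.0)   # Dp


def test_co2_filter_reaches_1_minus_1_over_e_at_tau(params):
    """A PaCO2 step drives c1 through (1-1/e) of its plateau at t = tau_c."""
    t = np.arange(0.0, 300.0, 1.0)
    paco2 = np.where(t < 50.0, params.PaCO2_n, params.PaCO2_n + 7.5)
    inputs = InputTrace(t=t, MABP=np.full_like(t, params.P_an),
                        SpO2=np.full_like(t, params.SaO2_n), PaCO2=paco2)
    sim = simulate(params, inputs, rtol=1e-10, atol=1e-12)
    c1 = sim.states[:, 1]
    plateau = c1[-1]
    target = (1.0 - np.exp(-1.0)) * plateau
    i = int(np.argmax(c1 >= target))
    # linear interpolation of the crossing time
    t_cross = t[i - 1] + (target - c1[i - 1]) / (c1[i] - c1[i - 1]) * (t[i] - t[i - 1])
    # the sampled step is linearly interpolated, so it acts at t = 49.5
    assert t_cross - 49.5 == pytest.approx(params.tau_c, rel=0.02)


def test_adaptive_solver_matches_rk4_oracle():
    """Adaptive stiff integration agrees with brute-force fixed-step RK4."""
    spec = ChallengeSpec(duration=120.0, onset=30.0, offset=90.0, seed=0)
    inputs = make_inputs(spec)
    p = default_parameters({"supps": 0.08, "uf": 0.0, "tau_c2": 40.0})
    a = simulate(p, inputs)
    b = simulate_rk4(p, inputs, dt=0.002)
    for ch in ("CBF", "TOI", "oxCCO", "CMRO2", "Dp", "NADNADHrat"):
        xa, xb = a.channel(ch), b.channel(ch)
        scale = np.max(np.abs(xb))
        assert np.max(np.abs(xa - xb)) / scale < 1e-4


def test_output_frame_has_contracted_columns(params, challenge_inputs):
    frame = simulate(params, challenge_inputs).to_frame()
    assert list(frame.columns) == [
        "t", "CBF", "dCBF_pct", "Vmca_pct", "TOI", "oxCCO", "CMRO2", "SvO2",
        "Dp", "NADNADHrat", "O2_mito", "f1", "f2", "f3", "J_O2", "L_CV", "L_leak"]
    assert np.allclose(frame["Vmca_pct"], frame["dCBF_pct"])


# -------------------------------------------------- mechanism sign structure

@pytest.fixture(scope="module")
def plateau_stats(challenge_spec, challenge_inputs):
    mask = challenge_spec.plateau_mask(challenge_inputs.t)

    def stats(overrides):
        sim = simulate(default_parameters(overrides), challenge_inputs)
        return {ch: float(sim.channel(ch)[mask].mean())
                for ch in ("oxCCO", "CMRO2", "Dp", "NADNADHrat", "dCBF_pct", "TOI")}

    return {
        "base": stats({}),
        "supply_down": stats({"supps": +0.05}),
        "demand_down": stats({"uf": -0.05}),
        "demand_up": stats({"uf": +0.05}),
    }


def test_reduced_substrate_supply_oxidises_cua_and_lowers_cmro2(plateau_stats, params):
    b, s = plateau_stats["base"], plateau_stats["supply_down"]
    assert s["oxCCO"] > b["oxCCO"]
    assert s["NADNADHrat"] > b["NADNADHrat"]
    assert s["CMRO2"] < params.CMRO2_n


def test_reduced_demand_raises_dp_and_reduces_cua(plateau_stats, params):
    b, d = plateau_stats["base"], plateau_stats["demand_down"]
    assert d["Dp"] > b["Dp"]
    assert d["oxCCO"] < b["oxCCO"] and d["oxCCO"] < 0.0
    assert d["CMRO2"] < params.CMRO2_n


def test_increased_demand_lowers_dp_and_oxidises_cua(plateau_stats):
    b, d = plateau_stats["base"], plateau_stats["demand_up"]
    assert d["Dp"] < b["Dp"]
    assert d["oxCCO"] > b["oxCCO"]
    assert d["CMRO2"] > b["CMRO2"]


def test_pure_flow_increase_gives_small_positive_oxcco(plateau_stats, params):
    """With mitochondrial O2 near-saturating, extra flow oxidises CuA only
    slightly: CBF and TOI rise strongly, oxCCO and CMRO2 barely."""
    b = plateau_stats["base"]
    assert b["dCBF_pct"] > 20.0
    assert b["TOI"] > params.TOI_n
    assert 0.0 < b["oxCCO"] < 0.1
    assert 0.0 < (b["CMRO2"] / params.CMRO2_n - 1.0) < 0.05
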