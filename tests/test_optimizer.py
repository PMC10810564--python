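import numpy as np
import pytest

from brainco2.model import simulate
from brainco2.optimizer import (DEFAULT_BOUNDS, FitConfig, TARGET_SETS,
                                evaluate_cost, fit_parameters, repeat_fits)
from brainco2.parameters import default_parameters
from brainco2.synthetic import ChallengeSpec, make_inputs, make_observations


@pytest.fixture(scope="module")
def descriptive_data():
    spec = ChallengeSpec(seed=4)
    inputs = make_inputs(spec)
    obs = make_observations("descriptive", spec, inputs)
    return inputs, obs


@pytest.fixture(scope="module")
def baseline_sim(descriptive_data):
    inputs, _ = descriptive_data
    return simulate(default_parameters(), inputs)


# --------------------------------------------------------------------- cost

def test_perfect_match_costs_zero(challenge_inputs):
    p = default_parameters({"supps": 0.05})
    sim = simulate(p, challenge_inputs)
    obs = make_observations("forward", p, challenge_inputs)
    cb = evaluate_cost(obs, sim, "all")
    assert cb.total == pytest.approx(0.0, abs=1e-12)
    assert all(d == pytest.approx(0.0, abs=1e-12) for d in cb.distances.values())


def test_constant_offset_costs_weight_times_delta(descriptive_data, baseline_sim):
    _, obs = descriptive_data
    import copy
    shifted = copy.deepcopy(obs)
    shifted.oxCCO = baseline_sim.oxCCO + 0.25
    cb = evaluate_cost(shifted, baseline_sim, ("oxCCO",))
    assert cb.total == pytest.approx(cb.weights["oxCCO"] * 0.25, rel=1e-9)
    assert cb.distances["oxCCO"] == pytest.approx(0.25, rel=1e-9)


def test_off_target_channels_do_not_enter_total(descriptive_data, baseline_sim):
    _, obs = descriptive_data
    cb1 = evaluate_cost(obs, baseline_sim, ("oxCCO",))
    import copy
    perturbed = copy.deepcopy(obs)
    perturbed.TOI = obs.TOI + 5.0
    perturbed.dCBF_pct = obs.dCBF_pct - 10.0
    w = cb1.weights
    cb2 = evaluate_cost(perturbed, baseline_sim, ("oxCCO",), weights=w)
    assert cb2.total == pytest.approx(cb1.total, rel=1e-12)


def test_cost_is_unit_invariant(descriptive_data, baseline_sim):
    """Scaling a channel in both data and model leaves its weighted term
    unchanged (the inverse-SD weighting makes the cost unit-free)."""
    _, obs = descriptive_data
    import copy
    obs10 = copy.deepcopy(obs)
    obs10.oxCCO = obs.oxCCO * 10.0
    sim10 = copy.deepcopy(baseline_sim)
    sim10.oxCCO = baseline_sim.oxCCO * 10.0
    a = evaluate_cost(obs, baseline_sim, ("oxCCO",))
    b = evaluate_cost(obs10, sim10, ("oxCCO",))
    assert b.total == pytest.approx(a.total, rel=1e-9)


def test_cost_contract_errors(descriptive_data, baseline_sim):
    _, obs = descriptive_data
    with pytest.raises(ValueError, match="empty"):
        evaluate_cost(obs, baseline_sim, ())
    import copy
    shifted = copy.deepcopy(obs)
    shifted.t = obs.t + 0.5
    with pytest.raises(ValueError, match="grid"):
        evaluate_cost(shifted, baseline_sim, "all")


# ------------------------------------------------------------------- config

def test_regimes_free_exactly_six_parameters():
    for regime, first in (("supply", "supps"), ("demand", "uf")):
        cfg = FitConfig(regime=regime)
        assert cfg.free_parameters == (first, "R_autc", "tau_c", "tau_c2",
                                       "P_an", "CBF_n")
        lo, hi = cfg.bounds_array()
        assert lo.size == hi.size == 6
        assert np.all(lo < hi)


def test_config_rejects_bad_inputs():
    with pytest.raises(ValueError):
        FitConfig(regime="entropy")
    with pytest.raises(ValueError):
        FitConfig(target_set=())
    with pytest.raises(ValueError):
        FitConfig(target_set=("oxCCO", "HbT"))
    with pytest.raises(ValueError):
        FitConfig(bounds={"k1": (0, 1)})


# ---------------------------------------------------------------------- GA

@pytest.fixture(scope="module")
def tiny_cfg():
    return dict(population=8, generations=3, polish=False, sim_rtol=1e-5,
                sim_atol=1e-8)


def test_fit_is_deterministic_given_seed(descriptive_data, tiny_cfg):
    inputs, obs = descriptive_data
    cfg = FitConfig(regime="supply", target_set="all", seed=9, **tiny_cfg)
    a = fit_parameters(obs, inputs, cfg)
    b = fit_parameters(obs, inputs, cfg)
    assert a.parameters == b.parameters
    assert a.cost.total == b.cost.total


def test_repeat_fits_aggregates(descriptive_data, tiny_cfg):
    inputs, obs = descriptive_data
    cfg = FitConfig(regime="supply", target_set="all", seed=2, repeats=3,
                    **tiny_cfg)
    res = repeat_fits(obs, inputs, cfg)
    assert len(res.repeats_table) == 3
    assert set(res.mean) == set(cfg.free_parameters)
    assert all(np.isfinite(v) and v >= 0.0 for v in res.sd.values())
    assert res.best.cost.total == res.repeats_table["total_cost"].min()
    # determinism of the whole repeat loop
    res2 = repeat_fits(obs, inputs, cfg)
    assert res.repeats_table.equals(res2.repeats_table)


def test_repeats_below_two_rejected(descriptive_data, tiny_cfg):
    inputs, obs = descriptive_data
    with pytest.raises(ValueError, match="repeats"):
        repeat_fits(obs, inputs, FitConfig(repeats=1, **tiny_cfg))
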