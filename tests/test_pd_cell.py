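"""Unit and property tests for the single-hepatocyte PD model."""

import numpy as np
import pytest

from apaptox import (
    CellState, ExposureProfile, PDParameters, STATE_NAMES,
    is_dead, pd_rhs, simulate_cell,
)
from apaptox.pd_cell import _ParamArrays, integrate_ensemble
from apaptox.population import PopulationSpec, sample_population, \
    simulate_invitro


def test_resting_state_is_fixed_point(params):
    traj = simulate_cell(params, ExposureProfile.constant(0.0), 120.0)
    end = traj.states[-1]
    assert np.allclose(end[2], params.gsh0, rtol=1e-9)
    assert np.allclose(end[6], params.atp0, rtol=1e-9)
    assert np.all(np.abs(end[[0, 1, 3, 4, 5]]) < 1e-9)
    assert traj.death_time is None


def test_rhs_matches_hand_computed_michaelis_menten(params):
    state = CellState(c_apap=2000.0, c_gsh=params.gsh0, c_atp=params.atp0)
    c_ext = 4000.0
    dy = pd_rhs(state, params, c_ext)
    a = state.c_apap
    uptake = params.uptake_rate * (c_ext - a)
    v_ugt = params.vmax_ugt * a / (params.km_ugt + a)
    v_sult = params.vmax_sult * a / (params.km_sult + a)
    v_cyp = (params.vmax_cyp2e1 * a / (params.km_cyp2e1 + a)
             + params.vmax_cyp1a2 * a / (params.km_cyp1a2 + a))
    assert dy["c_apap"] == pytest.approx(uptake - v_ugt - v_sult - v_cyp,
                                         rel=1e-12)
    assert dy["c_napqi"] == pytest.approx(v_cyp, rel=1e-12)
    # full GSH pool: resynthesis balances nothing, clearance/GST are zero
    assert dy["c_gsh"] == pytest.approx(0.0, abs=1e-9)


def test_rhs_rejects_bad_input(params):
    with pytest.raises(ValueError):
        pd_rhs(CellState(c_apap=-1.0), params, 0.0)
    with pytest.raises(ValueError):
        pd_rhs(CellState(), params, -5.0)
    with pytest.raises(ValueError):
        PDParameters(km_ugt=0.0).validate()
    with pytest.raises(ValueError):
        PDParameters(atp_death=6000.0).validate()


def test_single_cell_mass_balance(params):
    traj = simulate_cell(params, ExposureProfile.constant(4000.0), 240.0)
    assert traj.mass_balance_error() < 1e-6


def test_is_dead_strict_threshold(params):
    assert not is_dead(CellState(c_atp=params.atp_death), params)
    assert is_dead(CellState(c_atp=params.atp_death - 1e-9), params)
    assert not is_dead(CellState(c_atp=params.atp0), params)


def test_death_is_latched_and_monotone(params):
    pop = sample_population(PopulationSpec(n_cells=60, seed=2), params)
    curve = simulate_invitro(pop, 8.0, 1440.0, grid_dt=2.0)
    assert np.all(np.diff(curve.fraction) >= 0)
    assert curve.fraction[-1] > 0.2  # high dose does kill cells


def test_dead_fraction_monotone_in_dose(params):
    fractions = []
    for c in (0.5, 2.0, 8.0):
        pop = sample_population(PopulationSpec(n_cells=60, seed=2), params)
        curve = simulate_invitro(pop, c, 1440.0, grid_dt=2.0)
        fractions.append(curve.fraction[-1])
    assert fractions[0] <= fractions[1] <= fractions[2]
    assert fractions[2] > fractions[0]


def test_atp_death_threshold_insensitive(params):
    """Halving/doubling the ATP death threshold moves the 24 h endpoint by
    less than 5 percentage points (death is a fast ATP collapse)."""
    base = None
    out = {}
    for fac in (1.0, 0.5, 2.0):
        p = params.replace(atp_death=params.atp_death * fac)
        pop = sample_population(PopulationSpec(n_cells=80, seed=3), p)
        curve = simulate_invitro(pop, 4.0, 1440.0, grid_dt=2.0)
        out[fac] = curve.fraction[-1]
    base = out[1.0]
    assert abs(out[0.5] - base) < 0.05
    assert abs(out[2.0] - base) < 0.05


def test_rk4_agrees_with_adaptive_solver_smooth_regime(params):
    """Full-state agreement with a tight-tolerance adaptive reference while
    no cell has latched the MPT (the regime that decides death timing)."""
    pa_dict = {k: np.full(4, v) for k, v in params.to_dict().items()}
    pa = _ParamArrays(pa_dict, 4)
    exposure = ExposureProfile.constant(500.0)
    r1 = integrate_ensemble(pa, lambda t: exposure(t), 240.0, grid_dt=1.0,
                            method="rk4")
    r2 = integrate_ensemble(pa, lambda t: exposure(t), 240.0, grid_dt=1.0,
                            method="LSODA", rtol=1e-10, atol=1e-10)
    assert not r1.mpt.any() and not r2.mpt.any()
    assert np.allclose(r1.final[:7], r2.final[:7], rtol=1e-4, atol=1e-6)


def test_rk4_agrees_with_adaptive_solver_death_endpoints(params):
    """At a lethal concentration the fixed-step and adaptive solvers give
    identical death times; states of MPT-committed cells (GSH, ROS, JNK
    after the point of no return) are not compared — they no longer
    influence any reported quantity."""
    pa_dict = {k: np.full(4, v) for k, v in params.to_dict().items()}
    pa = _ParamArrays(pa_dict, 4)
    exposure = ExposureProfile.constant(4000.0)
    r1 = integrate_ensemble(pa, lambda t: exposure(t), 720.0, grid_dt=2.0,
                            method="rk4")
    r2 = integrate_ensemble(pa, lambda t: exposure(t), 720.0, grid_dt=2.0,
                            method="LSODA", rtol=1e-8, atol=1e-8)
    assert np.array_equal(r1.death_time, r2.death_time, equal_nan=True)
    assert np.allclose(r1.final[0], r2.final[0], rtol=1e-6)   # APAP
    assert np.allclose(r1.final[6], r2.final[6], rtol=1e-4)   # ATP


def test_zero_exposure_kills_nothing(params):
    pop = sample_population(PopulationSpec(n_cells=40, seed=0), params)
    curve = simulate_invitro(pop, 0.0, 720.0, grid_dt=2.0)
    assert curve.fraction[-1] == 0.0


def test_exposure_profile_validation():
    with pytest.raises(ValueError):
        ExposureProfile.constant(-1.0)
    with pytest.raises(ValueError):
        ExposureProfile.sampled([0.0, 1.0], [1.0, -1.0])
    with pytest.raises(ValueError):
        ExposureProfile.sampled([0.0, 0.0], [1.0, 1.0])
    decay = ExposureProfile.linear_decay(100.0, 0.1)
    assert decay(20.0) == 0.0           # clamped at zero
    assert decay(5.0) == pytest.approx(50.0)


def test_ensemble_cumulative_ledger(params):
    """uptake = accumulation + UGT + SULT + CYP throughput, per cell."""
    pa = _ParamArrays.from_single(params, 1)
    exposure = ExposureProfile.constant(2000.0)
    res = integrate_ensemble(pa, lambda t: exposure(t), 300.0, grid_dt=1.0)
    end = res.final[:, 0]
    taken = end[7]
    routed = end[8] + end[9] + end[10]
    assert abs(taken - routed - end[0]) / taken < 1e-9


def test_parameter_roundtrip_and_uptake_rate(params):
    d = params.to_dict()
    assert PDParameters.from_dict(d) == params
    assert params.uptake_rate == pytest.approx(
        params.permeability * params.surface / params.volume)
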