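"""Tests for scaling, likelihood, CMA-ES and the strategy drivers."""

import numpy as np
import pandas as pd
import pytest

from apaptox import (
    CMAES, FitSpec, PDParameters, PopulationSpec, ScalingFactors,
    fit_cmaes, loglik, run_strategy, sample_population, scale_to_invivo,
    sensitivity_screen, simulate_invitro,
)
from apaptox.calibration import _VitroObjective
from apaptox.fixtures import SyntheticDesign, generate_invitro_dataset, \
    generate_pk_dataset


def test_scale_to_invivo_factors(params):
    vivo = scale_to_invivo(params)
    assert vivo.vmax_cyp2e1 == pytest.approx(params.vmax_cyp2e1 * 3.3)
    assert vivo.vmax_cyp1a2 == pytest.approx(params.vmax_cyp1a2 * 1.8)
    assert vivo.gsh0 == pytest.approx(params.gsh0 * 0.5)
    # everything else untouched
    for name in ("permeability", "vmax_ugt", "k_gsh", "k_ros", "atp0"):
        assert getattr(vivo, name) == getattr(params, name)
    with pytest.warns(UserWarning, match="already scaled"):
        scale_to_invivo(vivo)
    ident = scale_to_invivo(params, ScalingFactors(1.0, 1.0, 1.0))
    assert ident.vmax_cyp2e1 == params.vmax_cyp2e1
    with pytest.raises(ValueError):
        ScalingFactors(cyp2e1_factor=0.0).validate()


def test_loglik_hand_computed():
    # perfect fit with fixed sigma: the constant term only
    assert loglik([1.0, 2.0], [1.0, 2.0], sigma=1.0) == pytest.approx(
        -np.log(2 * np.pi))
    # profiled variance: residuals (1, -1, 0), mse = 2/3
    expected = -0.5 * 3 * (np.log(2 * np.pi * 2.0 / 3.0) + 1.0)
    assert loglik([2.0, 1.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(expected)
    assert loglik([], []) == 0.0
    with pytest.raises(ValueError):
        loglik([1.0], [1.0, 2.0])
    # better fit => larger log-likelihood
    assert loglik([1.1, 2.1], [1.0, 2.0]) > loglik([2.0, 3.0], [1.0, 2.0])


def test_cmaes_sphere():
    rng_target = np.array([0.3, -0.7, 1.2, 0.0, -0.4])

    def sphere(x):
        return float(np.sum((x - rng_target) ** 2))

    res = fit_cmaes(sphere, np.zeros(5), sigma0=0.5, budget=4000, seed=0)
    assert res.fun < 1e-10
    assert np.allclose(res.x, rng_target, atol=1e-4)
    assert np.all(np.diff(res.trace) <= 0)     # best-so-far is monotone


def test_cmaes_budget_zero_and_bad_start():
    res = fit_cmaes(lambda x: float(np.sum(x ** 2)), [1.0, 2.0], budget=0)
    assert res.n_evals == 1 and np.array_equal(res.x, [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_cmaes(lambda x: np.inf, [0.0], budget=10)


def test_cmaes_respects_bounds():
    lo, hi = np.array([0.5, 0.5]), np.array([2.0, 2.0])

    def f(x):
        assert np.all((x >= lo) & (x <= hi))
        return float(np.sum(x ** 2))

    res = fit_cmaes(f, [1.5, 1.5], sigma0=0.8, bounds=(lo, hi), budget=300,
                    seed=1)
    assert np.all((res.x >= lo) & (res.x <= hi))
    assert res.fun == pytest.approx(0.5, rel=1e-6)   # corner (0.5, 0.5)
    with pytest.raises(ValueError):
        CMAES([1.0], 0.3, bounds=([2.0], [1.0]))


def test_cmaes_seed_determinism():
    def noisy_quad(x):
        return float(np.sum(x ** 2) + 0.1 * np.sin(40.0 * x).sum())

    a = fit_cmaes(noisy_quad, [1.0, -1.0], budget=200, seed=7)
    b = fit_cmaes(noisy_quad, [1.0, -1.0], budget=200, seed=7)
    assert a.fun == b.fun and np.array_equal(a.x, b.x)
    assert np.array_equal(a.trace, b.trace)


def test_sensitivity_screen_threshold_monotone(params):
    calls = {}

    def fake_endpoint(p):
        # analytic stand-in endpoint: fast and deterministic
        key = (p.vmax_cyp1a2, p.k_gsh)
        calls[key] = calls.get(key, 0) + 1
        return min(1.0, 0.3 * p.vmax_cyp1a2 / params.vmax_cyp1a2
                   + 0.001 * p.k_gsh / params.k_gsh)

    df_lo = sensitivity_screen(params, ["vmax_cyp1a2", "k_gsh", "km_sult"],
                               factor=2.0, threshold_pp=1.0,
                               endpoint=fake_endpoint)
    df_hi = sensitivity_screen(params, ["vmax_cyp1a2", "k_gsh", "km_sult"],
                               factor=2.0, threshold_pp=20.0,
                               endpoint=fake_endpoint)
    assert set(df_lo["parameter"]) == {"vmax_cyp1a2", "k_gsh", "km_sult"}
    # sensitive set shrinks as the threshold rises
    assert df_hi["sensitive"].sum() <= df_lo["sensitive"].sum()
    assert bool(df_lo.set_index("parameter")["sensitive"]["vmax_cyp1a2"])
    assert not bool(df_hi.set_index("parameter")["sensitive"]["km_sult"])
    assert df_lo.attrs["baseline"] == pytest.approx(0.301)


def test_vitro_objective_matches_direct_simulation(params):
    """The stacked multi-concentration prediction must equal independent
    per-concentration in vitro simulations."""
    spec = FitSpec(pop_spec=PopulationSpec(n_cells=40, seed=2), grid_dt=4.0)
    data = pd.DataFrame({"conc_mM": [1.0, 4.0], "dead_fraction": [0.1, 0.4]})
    obj = _VitroObjective(spec, data)
    pred = obj.predict(params)
    for i, c in enumerate((1.0, 4.0)):
        pop = sample_population(PopulationSpec(n_cells=40, seed=2), params)
        curve = simulate_invitro(pop, c, 1440.0, grid_dt=4.0)
        assert pred[i] == pytest.approx(curve.fraction[-1], abs=1e-12)


def test_fitspec_validation():
    with pytest.raises(ValueError):
        FitSpec(strategy="STR9").validate()
    with pytest.raises(ValueError):
        FitSpec(free_vitro=("nope",)).validate()
    with pytest.raises(ValueError):
        FitSpec(free_body=("nope",)).validate()
    with pytest.raises(ValueError):
        FitSpec(bounds_scale=1.0).validate()


def test_str2_reports_consistency_violation():
    """STR2's CL-1 self-consistency diagnostic must flag that hepatic
    uptake is not negligible for the default body (the strategy's known
    failure mode)."""
    design = SyntheticDesign(pop_spec=PopulationSpec(n_cells=40),
                             n_per_well=0, tox_noise_sd=0.0, pk_noise_cv=0.0)
    tox = generate_invitro_dataset(design, conc_mM=(1.0, 4.0), grid_dt=4.0)
    pkd = generate_pk_dataset(design, doses=(167.0, 300.0))
    spec = FitSpec(strategy="STR2", budget=0,
                   pop_spec=PopulationSpec(n_cells=40), grid_dt=4.0,
                   in_vivo_doses=(300.0,))
    res = run_strategy(spec, tox, pkd)
    diag = res.extras["consistency"]
    assert diag["consistency_ratio"] > 1.0
    assert "dose_response" in res.extras
    assert len(res.extras["dose_response"]) == 1
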