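"""Tests for population sampling, variability and zonation."""

import numpy as np
import pytest

from apaptox import PopulationSpec, sample_population, assign_zonation, \
    dead_fraction, simulate_invitro
from apaptox.population import F_CYP2E1_DEFAULT, F_CYP1A2_DEFAULT, \
    N_CELLS_DEFAULT


def test_zonation_fractions_pinned_to_one_cell(params):
    pop = sample_population(PopulationSpec(seed=0), params)
    n = pop.n_cells
    assert n == N_CELLS_DEFAULT == 3215
    assert pop.cyp2e1_pos.sum() == round(F_CYP2E1_DEFAULT * n)
    assert pop.cyp1a2_pos.sum() == round(F_CYP1A2_DEFAULT * n)
    assert abs(pop.cyp2e1_pos.mean() - 0.509) <= 1.0 / n
    assert abs(pop.cyp1a2_pos.mean() - 0.605) <= 1.0 / n


def test_zonation_nesting(params):
    for seed in (0, 7, 123):
        pop = sample_population(PopulationSpec(n_cells=777, seed=seed), params)
        assert not np.any(pop.cyp2e1_pos & ~pop.cyp1a2_pos)
        # positive Vmax exactly where the flag says
        assert np.array_equal(pop.params["vmax_cyp2e1"] > 0, pop.cyp2e1_pos)
        assert np.array_equal(pop.params["vmax_cyp1a2"] > 0, pop.cyp1a2_pos)


def test_zonation_linear_ramp_statistics(params):
    """The ramp decreases from the pericentral maximum to ~0 at the cutoff
    and averages ~vmax/2 over positive cells (uniform z)."""
    pop = sample_population(PopulationSpec(n_cells=2000, seed=4), params)
    v = pop.params["vmax_cyp1a2"]
    pos = pop.cyp1a2_pos
    z = pop.z
    # monotone in z among positive cells
    order = np.argsort(z[pos])
    assert np.all(np.diff(v[pos][order]) <= 1e-12)
    assert v[pos].mean() == pytest.approx(params.vmax_cyp1a2 / 2.0, rel=0.05)
    assert v[pos].max() <= params.vmax_cyp1a2


def test_zonation_flat_gradient(params):
    spec = PopulationSpec(n_cells=200, gradient="flat", seed=0)
    pop = sample_population(spec, params)
    v = pop.params["vmax_cyp2e1"]
    assert np.all(v[pop.cyp2e1_pos] == params.vmax_cyp2e1)


def test_assign_zonation_rejects_bad_input(params):
    spec = PopulationSpec(n_cells=10)
    with pytest.raises(ValueError):
        assign_zonation(spec, np.array([0.5, 1.5]), (10.0, 10.0))
    with pytest.raises(ValueError):
        PopulationSpec(f_cyp2e1=0.7, f_cyp1a2=0.5).validate()
    with pytest.raises(ValueError):
        PopulationSpec(n_cells=0).validate()
    with pytest.raises(ValueError):
        PopulationSpec(varying=("no_such_parameter",)).validate()


def test_cova_zero_is_degenerate(params):
    pop = sample_population(PopulationSpec(n_cells=50, cova=0.0, seed=0),
                            params)
    for name in ("vmax_ugt", "k_gsh", "k_ros"):
        assert np.all(pop.params[name] == getattr(params, name))


def test_lognormal_variability_is_mean_preserving(params):
    pop = sample_population(PopulationSpec(n_cells=4000, cova=0.3, seed=5),
                            params)
    for name in ("vmax_ugt", "k_gsh"):
        draws = pop.params[name]
        mean = getattr(params, name)
        assert draws.mean() == pytest.approx(mean, rel=0.03)
        assert draws.std() / draws.mean() == pytest.approx(0.3, rel=0.1)


def test_per_cell_atp_rest_is_fixed_point(params):
    pop = sample_population(PopulationSpec(n_cells=100, seed=6), params)
    expected = pop.params["k_atp_prod"] / pop.params["k_atp_use"]
    assert np.allclose(pop.params["atp0"], expected)


def test_seed_determinism(params):
    a = sample_population(PopulationSpec(n_cells=64, seed=9), params)
    b = sample_population(PopulationSpec(n_cells=64, seed=9), params)
    c = sample_population(PopulationSpec(n_cells=64, seed=10), params)
    for name in a.params:
        assert np.array_equal(np.broadcast_to(a.params[name], (64,)),
                              np.broadcast_to(b.params[name], (64,)))
    assert not np.array_equal(a.z, c.z)


def test_external_z_is_used(params):
    z = np.linspace(0, 1, 30)
    pop = sample_population(PopulationSpec(n_cells=30, seed=0), params, z=z)
    assert np.array_equal(pop.z, z)
    with pytest.raises(ValueError):
        sample_population(PopulationSpec(n_cells=30, seed=0), params,
                          z=z[:10])


def test_dead_fraction_requires_simulation(params):
    pop = sample_population(PopulationSpec(n_cells=10, seed=0), params)
    with pytest.raises(ValueError):
        dead_fraction(pop, 100.0)


def test_simulate_invitro_curve_and_frame(params, pop80):
    curve = simulate_invitro(pop80, 4.0, 720.0, grid_dt=2.0)
    assert curve.times[0] == 0.0 and curve.times[-1] == 720.0
    assert np.all((curve.fraction >= 0) & (curve.fraction <= 1))
    assert curve.at(720.0) == curve.fraction[-1]
    with pytest.raises(ValueError):
        curve.at(2000.0)
    assert dead_fraction(pop80, 720.0) == curve.fraction[-1]
    df = pop80.to_frame()
    assert len(df) == 80 and "death_time_min" in df.columns
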