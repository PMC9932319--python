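"""Tests for lobule geometry, blood flow, transport and the ST model."""

import numpy as np
import pytest

from apaptox import (
    BodyConfig, LobuleGeometryParams, PDParameters, PKParameters,
    PopulationSpec, STBodyConfig, effective_viscosity, generate_lobule,
    populate_lobule, ps_over_q, sample_population, scale_to_invivo,
    simulate_pk, simulate_st, simulate_transport, solve_flow,
)

from conftest import make_chain_network


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_generate_exact_counts_and_connectivity(tiny_lobule, tiny_geometry):
    assert tiny_lobule.n_hepatocytes == tiny_geometry.n_hepatocytes
    assert len(tiny_lobule.inlets) == tiny_geometry.n_portal_inlets
    assert tiny_lobule.graph.nodes[0]["kind"] == "central-outlet"
    assert np.all((tiny_lobule.cell_z >= 0) & (tiny_lobule.cell_z <= 1))
    r = tiny_lobule.edge_attr("radius")
    assert np.all(r >= tiny_geometry.sinusoid_radius_min)


def test_generate_seed_reproducible(tiny_geometry):
    import dataclasses
    a = generate_lobule(tiny_geometry)
    b = generate_lobule(tiny_geometry)
    c = generate_lobule(dataclasses.replace(tiny_geometry, seed=99))
    assert a.edges == b.edges
    assert np.array_equal(a.cell_z, b.cell_z)
    assert not np.array_equal(a.cell_z, c.cell_z)


def test_populate_uses_network_zonation(tiny_lobule, params):
    pop = populate_lobule(tiny_lobule, PopulationSpec(n_cells=1, seed=0),
                          params)
    assert pop.n_cells == tiny_lobule.n_hepatocytes   # spec size overridden
    assert np.array_equal(pop.z, tiny_lobule.cell_z)
    # pericentral cells (small z) carry the CYP capacity
    assert pop.params["vmax_cyp2e1"][np.argmin(pop.z)] > 0
    assert pop.params["vmax_cyp2e1"][np.argmax(pop.z)] == 0.0


def test_geometry_validation():
    with pytest.raises(ValueError):
        LobuleGeometryParams(lobule_radius=0.0).validate()
    with pytest.raises(ValueError):
        LobuleGeometryParams(n_hepatocytes=0).validate()


# ---------------------------------------------------------------------------
# viscosity
# ---------------------------------------------------------------------------

def test_viscosity_large_diameter_asymptote():
    eta = effective_viscosity(1000.0, plasma_viscosity=1.0)
    assert eta == pytest.approx(3.2, rel=0.01)


def test_viscosity_zero_hematocrit_is_plasma():
    assert effective_viscosity(8.0, plasma_viscosity=1.2e-3,
                               hematocrit=0.0) == pytest.approx(1.2e-3)


def test_viscosity_reference_formula_at_45():
    d = 9.0
    expected = (220.0 * np.exp(-1.3 * d) + 3.2
                - 2.44 * np.exp(-0.06 * d ** 0.645)) * 1.2e-3
    assert effective_viscosity(d) == pytest.approx(expected, rel=1e-12)
    assert effective_viscosity(d, hematocrit=0.3) < effective_viscosity(d)
    with pytest.raises(ValueError):
        effective_viscosity(0.0)


# ---------------------------------------------------------------------------
# flow
# ---------------------------------------------------------------------------

def test_single_tube_poiseuille_exact():
    net = make_chain_network([5.0], [500.0])
    dp = 100.0
    sol = solve_flow(net, inlet_pressure_pa=dp)
    g = np.pi * 5.0 ** 4 / (8.0 * effective_viscosity(10.0) * 500.0) * 60.0
    assert abs(sol.edge_flow_ml_min[0]) * 1e12 == pytest.approx(g * dp,
                                                                rel=1e-12)
    assert sol.pressure_drop_pa() == pytest.approx(dp, rel=1e-12)
    # single tube: velocity = Q / (pi r^2), in µm/s
    v = g * dp / (np.pi * 25.0) / 60.0
    assert abs(sol.edge_velocity_um_s[0]) == pytest.approx(v, rel=1e-12)


def test_series_tubes_harmonic_conductance():
    net = make_chain_network([5.0, 4.0], [300.0, 200.0])
    sol = solve_flow(net, inlet_pressure_pa=50.0)
    g1 = np.pi * 5 ** 4 / (8 * effective_viscosity(10.0) * 300) * 60
    g2 = np.pi * 4 ** 4 / (8 * effective_viscosity(8.0) * 200) * 60
    g_series = 1.0 / (1.0 / g1 + 1.0 / g2)
    assert abs(sol.edge_flow_ml_min[0]) * 1e12 == pytest.approx(
        g_series * 50.0, rel=1e-12)


def test_kirchhoff_and_prescribed_inflow(tiny_lobule):
    sol = solve_flow(tiny_lobule, total_inflow_ml_min=7.2e-5)
    assert sol.kirchhoff_residual() < 1e-10
    assert sol.total_inflow_ml_min == pytest.approx(7.2e-5, rel=1e-12)
    assert sol.pressure_drop_pa() > 0
    assert sol.mean_velocity_um_s() > 0


def test_flow_linearity(tiny_lobule):
    a = solve_flow(tiny_lobule, total_inflow_ml_min=7.2e-5)
    b = solve_flow(tiny_lobule, total_inflow_ml_min=1.44e-4)
    assert np.allclose(b.edge_flow_ml_min, 2.0 * a.edge_flow_ml_min,
                       rtol=1e-12)
    assert b.pressure_drop_pa() == pytest.approx(2.0 * a.pressure_drop_pa(),
                                                 rel=1e-12)
    with pytest.raises(ValueError):
        solve_flow(tiny_lobule)   # must prescribe exactly one drive
    with pytest.raises(ValueError):
        solve_flow(tiny_lobule, total_inflow_ml_min=1.0,
                   inlet_pressure_pa=1.0)


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def _passive_tube():
    """Single 500 µm tube with one zero-permeability hepatocyte."""
    net = make_chain_network([5.0], [500.0])
    sol = solve_flow(net, inlet_pressure_pa=100.0)
    p0 = PDParameters(permeability=0.0)
    pop = sample_population(PopulationSpec(n_cells=1, seed=0), p0,
                            z=np.array([0.5]))
    return net, sol, pop


def test_transport_step_delay_oracle():
    """Constant inlet front arrives after the residence time L/v and the
    outlet then matches the inlet concentration; mass closes to 1e-12."""
    net, sol, pop = _passive_tube()
    v = abs(sol.edge_velocity_um_s[0]) * 60.0   # µm/min
    tau = 500.0 / v
    res = simulate_transport(net, sol, 100.0, pop, horizon=3 * tau,
                             dt_macro=tau / 50.0)
    early = res.outlet_conc[res.times < 0.5 * tau]
    assert np.all(early < 1.0)                 # front not yet arrived
    i = np.searchsorted(res.times, 2.0 * tau)
    assert res.outlet_conc[i] == pytest.approx(100.0, rel=1e-3)
    assert res.mass_balance_error < 1e-12


def test_transport_zero_inlet_and_max_principle():
    net, sol, pop = _passive_tube()
    res0 = simulate_transport(net, sol, 0.0, pop, horizon=1.0, dt_macro=0.02)
    assert np.all(res0.seg_conc_final == 0.0)
    res = simulate_transport(net, sol, 250.0, pop, horizon=1.0, dt_macro=0.02)
    assert res.seg_conc_final.max() <= 250.0 + 1e-9
    assert np.all(res.seg_conc_final >= 0.0)


def test_transport_mass_balance_with_cells(tiny_lobule, params):
    pop = populate_lobule(tiny_lobule, PopulationSpec(n_cells=1, seed=2),
                          scale_to_invivo(params))
    sol = solve_flow(tiny_lobule, total_inflow_ml_min=7.2e-5)
    res = simulate_transport(tiny_lobule, sol, 2000.0, pop, horizon=30.0)
    assert res.mass_balance_error < 1e-6
    assert res.cum_uptake_umol > 0
    assert np.all(np.diff(res.dead_fraction) >= 0)


def test_transport_refinement_convergence():
    """Halving the segment size moves the outlet breakthrough toward the
    sharp front (less numerical diffusion), keeping mass closed."""
    net, sol, pop = _passive_tube()
    v = abs(sol.edge_velocity_um_s[0]) * 60.0
    tau = 500.0 / v
    vals = {}
    for dx in (50.0, 12.5):
        res = simulate_transport(net, sol, 100.0, pop, horizon=1.2 * tau,
                                 dt_macro=tau / 100.0, dx_target=dx)
        # concentration at 0.75 tau: ahead of the exact front => pure
        # numerical diffusion, must shrink with refinement
        i = np.searchsorted(res.times, 0.75 * tau)
        vals[dx] = res.outlet_conc[i]
        assert res.mass_balance_error < 1e-10
    assert vals[12.5] < vals[50.0]


# ---------------------------------------------------------------------------
# ST body model
# ---------------------------------------------------------------------------

def test_st_zero_permeability_matches_bateman(tiny_lobule):
    """With impermeable cells the lobule is a pass-through and blood obeys
    the closed-form two-compartment model (small transit-delay tolerance)."""
    p0 = scale_to_invivo(PDParameters()).replace(permeability=0.0)
    pop = populate_lobule(tiny_lobule, PopulationSpec(n_cells=1, seed=1), p0)
    st = STBodyConfig(q_lobule_in=7.2e-5, n_lobule=3.0e4,
                      body=BodyConfig(k_nonliver=0.018))
    res = simulate_st(tiny_lobule, st, pop, 300.0, 120.0)
    assert res.ledger_closure_error() < 1e-9
    ref = simulate_pk(PKParameters(k_el=0.018), res.pk.times, 300.0)
    dev = np.max(np.abs(res.pk.conc - ref.conc)) / ref.conc.max()
    assert dev < 0.005
    assert res.toxicity.fraction[-1] == 0.0


def test_st_ledger_closes_with_toxicity(tiny_lobule, params):
    pop = populate_lobule(tiny_lobule, PopulationSpec(n_cells=1, seed=3),
                          scale_to_invivo(params))
    st = STBodyConfig()
    res = simulate_st(tiny_lobule, st, pop, 300.0, 60.0)
    assert res.ledger_closure_error() < 1e-9
    assert res.diagnostics["q_liver_ml_min"] == pytest.approx(2.16)
    with pytest.raises(ValueError):
        STBodyConfig(q_lobule_in=0.0).validate()
    with pytest.warns(UserWarning, match="Q_liver"):
        STBodyConfig(q_lobule_in=1e-3).validate()


def test_ps_over_q_scaling(params):
    base = ps_over_q(params, q_liver_ml_min=2.16)
    double = ps_over_q(params.replace(permeability=2 * params.permeability),
                       q_liver_ml_min=2.16)
    assert double["ratio_liver"] == pytest.approx(2 * base["ratio_liver"])
    expected = (params.permeability * params.surface * 1e-12 * 3215 * 3e4
                / 2.16)
    assert base["ratio_liver"] == pytest.approx(expected, rel=1e-12)
    assert base["ratio_sinusoid"] > 0
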