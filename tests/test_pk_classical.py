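"""Tests for the two-compartment PK model and classical extrapolation."""

import numpy as np
import pandas as pd
import pytest

from apaptox import PKCurve, PKParameters, auc, cmax, \
    classical_extrapolation, fit_pk, simulate_pk
from apaptox.pk_classical import MW_APAP, dose_to_umol


def bateman_auc(p: PKParameters, dose: float, T: float) -> float:
    """Closed-form integral of the Bateman curve over [0, T]."""
    d = dose_to_umol(dose, p.body_weight_g)
    amp = p.f_bio * d / (p.v_blood * 1e-3)
    ka, ke = p.k_a, p.k_el
    return amp * ka / (ka - ke) * ((1 - np.exp(-ke * T)) / ke
                                   - (1 - np.exp(-ka * T)) / ka)


def test_dose_conversion():
    assert dose_to_umol(300.0, 25.0) == pytest.approx(
        300.0 * 25.0 / 1000.0 / MW_APAP * 1000.0)
    assert dose_to_umol(0.0, 25.0) == 0.0


def test_tmax_matches_analytic():
    p = PKParameters()
    t = np.linspace(0.0, 480.0, 96001)
    curve = simulate_pk(p, t, 300.0)
    t_max_analytic = np.log(p.k_a / p.k_el) / (p.k_a - p.k_el)
    t_max_grid = curve.times[np.argmax(curve.conc)]
    assert t_max_grid == pytest.approx(t_max_analytic, abs=0.01)


def test_trapezoid_auc_vs_closed_form():
    p = PKParameters()
    t = np.arange(0.0, 481.0, 1.0)
    curve = simulate_pk(p, t, 300.0)
    a, a_over_t = auc(curve, 480.0)
    exact = bateman_auc(p, 300.0, 480.0)
    assert abs(a - exact) / exact < 0.005
    assert a_over_t == pytest.approx(a / 480.0)


def test_dose_zero_and_homogeneity():
    p = PKParameters()
    t = np.arange(0.0, 241.0, 1.0)
    zero = simulate_pk(p, t, 0.0)
    assert np.all(zero.conc == 0.0) and cmax(zero) == 0.0
    c1 = simulate_pk(p, t, 100.0).conc
    c3 = simulate_pk(p, t, 300.0).conc
    assert np.allclose(c3, 3.0 * c1, rtol=1e-12)


def test_ka_equals_ke_limit_is_continuous():
    t = np.arange(0.0, 241.0, 1.0)
    p_eq = PKParameters(k_a=0.05, k_el=0.05)
    p_near = PKParameters(k_a=0.05, k_el=0.05 * (1 + 1e-9))
    c_eq = simulate_pk(p_eq, t, 300.0).conc
    c_near = simulate_pk(p_near, t, 300.0).conc
    assert np.allclose(c_eq, c_near, rtol=1e-6)


def test_curve_validation():
    with pytest.raises(ValueError):
        PKCurve(times=np.array([0.0, 0.0]), conc=np.array([0.0, 0.0]),
                dose_mg_per_kg=1.0)
    with pytest.raises(ValueError):
        PKCurve(times=np.array([0.0, 1.0]), conc=np.array([0.0, -1.0]),
                dose_mg_per_kg=1.0)
    with pytest.raises(ValueError):
        PKParameters(v_blood=0.0).validate()
    curve = simulate_pk(PKParameters(), np.arange(0.0, 61.0), 100.0)
    with pytest.raises(ValueError):
        auc(curve, 120.0)   # beyond the curve end
    with pytest.raises(ValueError):
        auc(curve, 0.0)


def test_classical_interpolation_log_midpoint():
    """(0.5 mM, 0.1) and (2.0 mM, 0.3): the log-scale midpoint 1.0 mM must
    map to dead fraction 0.2."""
    cr = pd.DataFrame({"conc_mM": [0.5, 2.0], "dead_fraction": [0.1, 0.3]})
    curve = PKCurve(times=np.array([0.0, 1.0, 2.0]),
                    conc=np.array([0.0, 1000.0, 500.0]), dose_mg_per_kg=42.0)
    out = classical_extrapolation(cr, {42.0: curve}, "cmax")
    assert out.loc[0, "equivalent_conc_mM"] == pytest.approx(1.0)
    assert out.loc[0, "predicted_dead_fraction"] == pytest.approx(0.2)


def test_classical_extrapolation_clamps_with_warning():
    cr = pd.DataFrame({"conc_mM": [0.5, 2.0], "dead_fraction": [0.1, 0.3]})
    hi = PKCurve(times=np.array([0.0, 1.0]), conc=np.array([0.0, 50000.0]),
                 dose_mg_per_kg=1.0)
    with pytest.warns(UserWarning, match="clamped"):
        out = classical_extrapolation(cr, {1.0: hi}, "cmax")
    assert out.loc[0, "predicted_dead_fraction"] == pytest.approx(0.3)
    with pytest.raises(ValueError):
        classical_extrapolation(cr, {1.0: hi}, "median")


def test_auc_mode_uses_time_average():
    cr = pd.DataFrame({"conc_mM": [0.01, 100.0], "dead_fraction": [0.0, 1.0]})
    p = PKParameters()
    t = np.arange(0.0, 1441.0, 1.0)
    curve = simulate_pk(p, t, 300.0)
    out = classical_extrapolation(cr, {300.0: curve}, "auc", T=1440.0)
    assert out.loc[0, "equivalent_conc_mM"] * 1e3 == pytest.approx(
        auc(curve, 1440.0)[1], rel=1e-9)


def test_fit_pk_recovers_truth_noiseless():
    truth = PKParameters(k_a=0.06, k_el=0.022, v_blood=16.0)
    times = np.array([5.0, 15.0, 30.0, 45.0, 60.0, 120.0, 240.0, 480.0])
    rows = []
    for dose in (56.0, 167.0, 300.0):
        c = simulate_pk(truth, np.append(0.0, times), dose)
        for t, v in zip(c.times[1:], c.conc[1:]):
            rows.append({"dose_mg_per_kg": dose, "time_min": t, "conc_uM": v})
    data = pd.DataFrame(rows)
    start = PKParameters()   # defaults as the initial guess
    fitted = fit_pk(data, start)
    assert fitted.k_a == pytest.approx(truth.k_a, rel=1e-4)
    assert fitted.k_el == pytest.approx(truth.k_el, rel=1e-4)
    assert fitted.v_blood == pytest.approx(truth.v_blood, rel=1e-4)
    with pytest.raises(ValueError):
        fit_pk(data.iloc[:2])
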