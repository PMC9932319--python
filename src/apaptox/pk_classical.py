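"""Two-compartment APAP pharmacokinetics and classical AUC/Cmax extrapolation.

The PK model has a peritoneal cavity (i.p. injection site) and a blood
compartment.  A fraction F of the dose transfers to blood at first-order
rate k_a; blood APAP is cleared by a lumped first-order term k_el.  The
blood concentration then follows the Bateman closed form

    C(t) = F*D*k_a / (V_blood*(k_a - k_el)) * (exp(-k_el*t) - exp(-k_a*t))

with D the dose in µmol.  The classical in-vitro-to-in-vivo extrapolation
(strategy 1) maps each dose to an equivalent in vitro concentration via
either Cmax or AUC/T and reads the predicted dead fraction off the in vitro
concentration-response curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pd_cell import L_PER_ML

__all__ = [
    "MW_APAP", "PKParameters", "PKCurve",
    "dose_to_umol", "simulate_pk", "auc", "cmax",
    "classical_extrapolation", "fit_pk",
]

#: molar mass of acetaminophen, g/mol
MW_APAP = 151.16


def dose_to_umol(dose_mg_per_kg: float, body_weight_g: float) -> float:
    """Administered dose in µmol for a given body weight."""
    mg = dose_mg_per_kg * body_weight_g / 1000.0
    return mg / MW_APAP * 1000.0


@dataclass
class PKParameters:
    """Two-compartment i.p. PK parameters (defaults: 25 g mouse)."""

    k_a: float = 0.08          # 1/min, peritoneum -> blood transfer
    f_bio: float = 0.9         # bioavailable fraction (0, 1]
    v_blood: float = 14.0      # mL, apparent distribution volume
    k_el: float = 0.018        # 1/min, first-order blood clearance
    body_weight_g: float = 25.0

    def validate(self) -> None:
        for name in ("k_a", "f_bio", "v_blood", "k_el", "body_weight_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PKParameters.{name} must be > 0")
        if self.f_bio > 1:
            raise ValueError("f_bio must be <= 1")

    def replace(self, **kw) -> "PKParameters":
        return replace(self, **kw)


@dataclass
class PKCurve:
    """Blood concentration time series for one dose."""

    times: np.ndarray          # min, ascending from 0
    conc: np.ndarray           # µM
    dose_mg_per_kg: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if len(self.times) == 0:
            raise ValueError("empty PK curve")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < -1e-12):
            raise ValueError("concentrations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_mg_per_kg": self.dose_mg_per_kg,
                             "time_min": self.times, "conc_uM": self.conc})


def simulate_pk(params: PKParameters, t_grid, dose_mg_per_kg: float) -> PKCurve:
    """Closed-form blood concentration on ``t_grid`` (minutes from 0)."""
    params.validate()
    t = np.asarray(t_grid, dtype=float)
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be ascending and start at >= 0")
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be >= 0")
    d_umol = dose_to_umol(dose_mg_per_kg, params.body_weight_g)
    ka, ke = params.k_a, params.k_el
    amp = params.f_bio * d_umol / (params.v_blood * L_PER_ML)  # µmol/L = µM
    if abs(ka - ke) < 1e-12 * max(ka, ke):
        c = amp * ka * t * np.exp(-ka * t)
    else:
        c = amp * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    return PKCurve(times=t, conc=np.maximum(c, 0.0), dose_mg_per_kg=dose_mg_per_kg)


def auc(curve: PKCurve, T: float) -> tuple[float, float]:
    """Trapezoidal AUC over [0, T] (µM·min) and its concentration
    equivalent AUC/T (µM)."""
    if T <= 0:
        raise ValueError("T must be > 0")
    if T > curve.times[-1] + 1e-9:
        raise ValueError(f"T={T} beyond curve end {curve.times[-1]}")
    mask = curve.times <= T
    t = np.append(curve.times[mask], T)
    c = np.append(curve.conc[mask], np.interp(T, curve.times, curve.conc))
    a = float(np.trapezoid(c, t))
    return a, a / T


def cmax(curve: PKCurve) -> float:
    """Maximum blood concentration over the curve's grid (µM)."""
    return float(np.max(curve.conc))


def classical_extrapolation(
    cr_vitro: pd.DataFrame,
    pk_per_dose: dict[float, PKCurve],
    mode: str = "cmax",
    T: float = 1440.0,
) -> pd.DataFrame:
    """Classical (strategy 1) extrapolation: equivalent exposure -> toxicity.

    ``cr_vitro`` must have columns ``conc_mM`` and ``dead_fraction`` (the
    24 h in vitro concentration-response table).  For each dose the
    equivalent in vitro concentration is Cmax or AUC/T of its PK curve; the
    predicted dead fraction is monotone piecewise-linear interpolation on
    log10 concentration, clamped (with a warning) outside the tabulated
    range.
    """
    if mode not in ("auc", "cmax"):
        raise ValueError("mode must be 'auc' or 'cmax'")
    if len(cr_vitro) == 0:
        raise ValueError("empty in vitro table")
    tab = cr_vitro.sort_values("conc_mM")
    conc_uM = tab["conc_mM"].to_numpy(dtype=float) * 1e3
    frac = tab["dead_fraction"].to_numpy(dtype=float)
    if np.any(conc_uM <= 0):
        raise ValueError("in vitro concentrations must be > 0")
    logc = np.log10(conc_uM)

    rows = []
    for dose in sorted(pk_per_dose):
        curve = pk_per_dose[dose]
        eq = cmax(curve) if mode == "cmax" else auc(curve, T)[1]
        if eq <= 0:
            pred = 0.0
        else:
            le = np.log10(eq)
            if le < logc[0] or le > logc[-1]:
                warnings.warn(
                    f"dose {dose}: equivalent concentration {eq:.1f} µM "
                    "outside the in vitro range; clamped", stacklevel=2)
                le = np.clip(le, logc[0], logc[-1])
            pred = float(np.interp(le, logc, frac))
        rows.append({"dose_mg_per_kg": dose, "mode": mode,
                     "equivalent_conc_mM": eq / 1e3,
                     "predicted_dead_fraction": pred})
    return pd.DataFrame(rows)


def fit_pk(
    data: pd.DataFrame,
    initial: PKParameters | None = None,
    *,
    fix_f_bio: bool = True,
) -> PKParameters:
    """Least-squares fit of (k_a, k_el, v_blood) to observed blood kinetics.

    ``data`` columns: ``dose_mg_per_kg``, ``time_min``, ``conc_uM`` — the
    sparse design used throughout (full curve at the reference dose, single
    late points elsewhere) is accepted as-is.  F is not identifiable
    separately from V_blood in the pure PK model, so it stays fixed by
    default and the apparent volume absorbs it.
    """
    p0 = initial or PKParameters()
    doses = data["dose_mg_per_kg"].to_numpy(dtype=float)
    times = data["time_min"].to_numpy(dtype=float)
    obs = data["conc_uM"].to_numpy(dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 observations to fit the PK model")

    names = ["k_a", "k_el", "v_blood"] + ([] if fix_f_bio else ["f_bio"])
    x0 = np.log10([getattr(p0, n) for n in names])

    def unpack(x) -> PKParameters:
        kw = {n: 10.0 ** v for n, v in zip(names, x)}
        if not fix_f_bio:
            kw["f_bio"] = min(kw["f_bio"], 1.0)
        return p0.replace(**kw)

    def resid(x):
        p = unpack(x)
        pred = np.empty_like(obs)
        for d in np.unique(doses):
            m = doses == d
            grid = np.unique(np.concatenate(([0.0], times[m])))
            c = simulate_pk(p, grid, d)
            pred[m] = np.interp(times[m], c.times, c.conc)
        return pred - obs

    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    fitted = unpack(sol.x)
    fitted.validate()
    return fitted
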