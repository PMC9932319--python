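"""In-text numeric anchors and synthetic dataset generators.

``inpaper`` serves the numeric values printed in the source study's text
(dose lists, positivity fractions, scaling factors, flow anchors), each
with its citation context.  The synthetic generators produce in vitro
toxicity tables and PK tables from a known ground-truth parameter set with
a configurable noise model — they stand in for the study's figure-level raw
data, which is never transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pd_cell import PDParameters
from .pk_classical import PKParameters, simulate_pk
from .population import PopulationSpec, sample_population, simulate_invitro

__all__ = [
    "InPaperValue", "INPAPER", "inpaper", "SyntheticDesign",
    "generate_invitro_dataset", "generate_pk_dataset",
]


@dataclass(frozen=True)
class InPaperValue:
    value: object
    units: str
    citation: str


#: numeric anchors printed in the source study's text (read-only)
INPAPER: dict[str, InPaperValue] = {
    "invivo_doses_mg_per_kg": InPaperValue(
        (89.0, 158.0, 281.0, 375.0, 500.0), "mg/kg",
        "in vivo hepatotoxicity dose list"),
    "pk_doses_mg_per_kg": InPaperValue(
        (56.0, 167.0, 300.0, 450.0), "mg/kg",
        "pharmacokinetic study dose list"),
    "pk_times_min": InPaperValue(
        (0.0, 5.0, 15.0, 30.0, 45.0, 60.0, 120.0, 240.0, 480.0), "min",
        "blood sampling schedule"),
    "invitro_conc_mM": InPaperValue(
        (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0), "mM",
        "in vitro concentration panel, 24 h endpoint"),
    "invitro_fit_conc_mM": InPaperValue(
        (0.25, 0.5, 1.0, 2.0, 4.0, 8.0), "mM",
        "concentrations used for fitting (>= 16 mM excluded: "
        "CYP-independent death)"),
    "kinetics_times_h": InPaperValue(
        (1.0, 4.0, 8.0, 18.0, 24.0), "h", "4 mM dead-cell kinetics"),
    "dead_fraction_4mM_24h": InPaperValue(
        0.40, "fraction",
        "approximately 40% of hepatocytes PI-positive at 4 and 8 mM"),
    "f_cyp2e1": InPaperValue(0.509, "fraction", "CYP2E1-positive cells"),
    "f_cyp1a2": InPaperValue(0.605, "fraction", "CYP1A2-positive cells"),
    "cyp2e1_factor": InPaperValue(
        3.3, "dimensionless", "in vivo / in vitro CYP2E1 activity"),
    "cyp1a2_factor": InPaperValue(
        1.8, "dimensionless", "in vivo / in vitro CYP1A2 activity"),
    "gsh_factor": InPaperValue(
        0.5, "dimensionless", "in vivo / in vitro GSH concentration"),
    "nonliver_fraction": InPaperValue(
        0.15, "fraction", "non-liver elimination share of the "
        "bioavailable dose (fit constraint)"),
    "atp0_uM": InPaperValue(5000.0, "µM", "initial ATP level"),
    "atp_death_uM": InPaperValue(100.0, "µM", "ATP death threshold"),
    "n_cells_ensemble": InPaperValue(
        3215, "cells", "virtual lobule hepatocyte count"),
    "n_cells_reduced": InPaperValue(
        160, "cells", "reduced ensemble with ~±5 pp dead-fraction agreement"),
    "ensemble_size_tolerance_pp": InPaperValue(
        5.0, "percentage points",
        "160- vs 3,251-cell dead-fraction difference"),
    "q_lobule_in_ml_min": InPaperValue(
        7.2e-5, "mL/min", "total input flow at the lobule portal fields"),
    "q_liver_range_ml_min": InPaperValue(
        (1.8, 12.0), "mL/min", "admissible liver volume flow band"),
    "q_liver_anchors_ml_min": InPaperValue(
        (1.8, 2.685, 2.7, 3.57, 5.3, 5.34), "mL/min",
        "liver flows examined in the spatial model"),
    "pressure_drop_pa": InPaperValue(
        113.0, "Pa", "portal-to-central pressure difference"),
    "mean_velocity_um_s": InPaperValue(47.0, "µm/s", "mean sinusoid speed"),
    "ps_over_q_liver": InPaperValue(
        26.45, "dimensionless", "PS_liver / Q_liver"),
    "ps_over_q_sinusoid": InPaperValue(
        2.56, "dimensionless", "PS_H / Q_sinusoid, single hepatocyte"),
    "n_lobule_range": InPaperValue(
        (2.5e4, 8.1e4), "lobules", "liver lobule count range"),
    "pv_cv_drop_fraction": InPaperValue(
        0.10, "fraction", "portal-to-central APAP concentration drop"),
    "passages_to_5pct": InPaperValue(
        30, "passages", "liver passages reducing blood APAP to ~5%"),
    "passage_time_s": InPaperValue(15.0, "s", "one liver passage in mouse"),
    "n_sensitive_named_insensitive": InPaperValue(
        ("permeability", "vmax_cyp2e1", "km_cyp2e1", "km_gst_gsh", "n_ros"),
        "parameter names",
        "parameters reported non-critical for the in vivo endpoint"),
}


def inpaper(key: str) -> tuple[object, str]:
    """Return ``(value, citation)`` for a stored in-text anchor."""
    try:
        item = INPAPER[key]
    except KeyError:
        raise KeyError(f"unknown in-text anchor {key!r}; known: "
                       f"{sorted(INPAPER)}") from None
    return item.value, item.citation


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDesign:
    """Ground-truth parameters and noise model for synthetic datasets.

    Noise: dead fractions get binomial well-sampling noise (``n_per_well``
    scored cells) plus additive Gaussian measurement error; PK
    concentrations get multiplicative log-normal error (median-preserving).
    Three replicates per condition by default, matching a three-animal
    design.
    """

    truth_pd: PDParameters = field(default_factory=PDParameters)
    truth_pk: PKParameters = field(default_factory=PKParameters)
    pop_spec: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(n_cells=160))
    n_replicates: int = 3
    n_per_well: int = 500            # cells scored per well (binomial)
    tox_noise_sd: float = 0.02       # additive Gaussian on dead fraction
    pk_noise_cv: float = 0.1         # log-normal sigma on concentrations
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if min(self.tox_noise_sd, self.pk_noise_cv) < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_per_well < 0:
            raise ValueError("n_per_well must be >= 0 (0 = exact fractions)")


def generate_invitro_dataset(
    design: SyntheticDesign,
    conc_mM=None,
    *,
    horizon: float = 1440.0,
    times_min=None,
    grid_dt: float = 2.0,
) -> pd.DataFrame:
    """Synthetic in vitro toxicity table (concentration, time, replicate,
    dead fraction) from the truth model.

    By default only the 24 h endpoint is reported at the in-text fitting
    concentrations; pass ``times_min`` for kinetic designs.  Values are
    clipped to [0, 1] after noise.  Seed-reproducible.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    if conc_mM is None:
        conc_mM = inpaper("invitro_fit_conc_mM")[0]
    if times_min is None:
        times_min = (horizon,)

    pop = sample_population(design.pop_spec, design.truth_pd)
    rows = []
    for c in conc_mM:
        curve = simulate_invitro(pop, float(c), horizon, grid_dt=grid_dt)
        for t in times_min:
            true_frac = curve.at(float(t))
            for rep in range(design.n_replicates):
                noisy = true_frac
                if design.n_per_well:       # binomial well-sampling noise
                    noisy = rng.binomial(design.n_per_well, true_frac) \
                        / design.n_per_well
                if design.tox_noise_sd > 0:
                    noisy += rng.normal(0.0, design.tox_noise_sd)
                rows.append({
                    "conc_mM": float(c), "time_min": float(t),
                    "replicate": rep,
                    "dead_fraction": float(np.clip(noisy, 0.0, 1.0)),
                    "true_dead_fraction": float(true_frac),
                })
    return pd.DataFrame(rows)


def generate_pk_dataset(
    design: SyntheticDesign,
    doses=None,
    times_min=None,
    *,
    sparse: bool = False,
    reference_dose: float = 300.0,
) -> pd.DataFrame:
    """Synthetic blood-kinetics table (dose, time, replicate, conc µM).

    ``sparse=True`` reproduces the fitting design: the full sampling
    schedule at ``reference_dose`` and a single late sample for the other
    doses.  Log-normal noise preserves the median concentration.
    """
    design.validate()
    rng = np.random.default_rng(design.seed + 1)
    if doses is None:
        doses = inpaper("pk_doses_mg_per_kg")[0]
    if times_min is None:
        times_min = inpaper("pk_times_min")[0]
    times_min = np.asarray(times_min, dtype=float)

    sigma = np.sqrt(np.log1p(design.pk_noise_cv ** 2))
    rows = []
    for dose in doses:
        if sparse and dose != reference_dose:
            tt = times_min[-1:]
        else:
            tt = times_min
        curve = simulate_pk(design.truth_pk, np.unique(np.append(0.0, tt)),
                            float(dose))
        for t in tt:
            true_c = float(np.interp(t, curve.times, curve.conc))
            for rep in range(design.n_replicates):
                noisy = true_c * rng.lognormal(0.0, sigma) \
                    if design.pk_noise_cv > 0 else true_c
                rows.append({
                    "dose_mg_per_kg": float(dose), "time_min": float(t),
                    "replicate": rep, "conc_uM": float(noisy),
                    "true_conc_uM": true_c,
                })
    return pd.DataFrame(rows)
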