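"""Bundled reference measurements and calibrated constants for wheat.

These tables come from a published calibration study of a Tavares-type
breakage model for a hard winter wheat (Zhoumai 22, conditioned to 16.3%
moisture) milled against white cast iron rollers.  They are the standard
inputs of the calibration workflow: contact-parameter test summaries,
angle-of-repose measurements, the Box-Behnken run table, the four
equivalent-diameter size classes with their fitted fracture-energy
statistics, the drop-weight test configuration, and the full simulation
parameter set.

All energies are mass-specific (J/kg), lengths mm unless noted, moduli Pa,
angles degrees.
"""

from __future__ import annotations

import math

import pandas as pd

# ---------------------------------------------------------------------------
# Contact-parameter tests: wheat vs white cast iron plate.
# Five groups x 20 kernels for friction, three drop heights x 50 kernels for
# restitution.  Values are per-group means and sample SDs.
# ---------------------------------------------------------------------------

STATIC_FRICTION_GROUP_MEANS = (0.425, 0.419, 0.438, 0.405, 0.442)
STATIC_FRICTION_GROUP_SDS = (0.082, 0.077, 0.089, 0.082, 0.097)
STATIC_FRICTION_OVERALL = 0.426

ROLLING_FRICTION_GROUP_MEANS = (0.177, 0.179, 0.180, 0.179, 0.181)
ROLLING_FRICTION_GROUP_SDS = (0.045, 0.036, 0.032, 0.037, 0.038)
ROLLING_FRICTION_OVERALL = 0.179

RESTITUTION_GROUP_MEANS = (0.404, 0.398, 0.395)
RESTITUTION_GROUP_SDS = (0.017, 0.016, 0.016)
RESTITUTION_OVERALL = 0.399

#: Rolling-friction test geometry: 30 degree slope, 20 mm release length.
ROLL_TEST_SLOPE_DEG = 30.0
ROLL_TEST_SLOPE_LENGTH_MM = 20.0

# ---------------------------------------------------------------------------
# Angle-of-repose physical test (10 replicates) and its mean.
# ---------------------------------------------------------------------------

REPOSE_ANGLES_DEG = (
    28.156, 29.705, 28.937, 29.314, 28.563,
    31.892, 30.641, 31.208, 30.982, 30.401,
)
REPOSE_MEAN_DEG = 29.765
REPOSE_SD_DEG = 1.12

#: Simulated repose angle at the optimised wheat-wheat contact parameters
#: (five DEM replicates) and its SD.
REPOSE_SIM_OPTIMUM_DEG = 30.078
REPOSE_SIM_OPTIMUM_SD_DEG = 0.32

#: Optimised wheat-wheat contact parameters (restitution, static, rolling).
WHEAT_WHEAT_CONTACT = {"restitution": 0.405, "static_friction": 0.322,
                       "rolling_friction": 0.039}
#: Measured wheat-roller contact parameters.
WHEAT_ROLLER_CONTACT = {"restitution": 0.399, "static_friction": 0.426,
                        "rolling_friction": 0.179}

# ---------------------------------------------------------------------------
# Box-Behnken design for the wheat-wheat contact calibration.
# Factors: c1 restitution, c2 static friction, c3 rolling friction.
# ---------------------------------------------------------------------------

BBD_FACTOR_BOUNDS = {
    "c1": (0.2, 0.6),
    "c2": (0.25, 0.45),
    "c3": (0.02, 0.06),
}

#: The 17 design runs with the simulated angle of repose alpha (degrees).
BBD_RUNS = (
    (0.2, 0.25, 0.04, 29.780),
    (0.6, 0.25, 0.04, 30.104),
    (0.2, 0.45, 0.04, 32.936),
    (0.6, 0.45, 0.04, 31.549),
    (0.2, 0.35, 0.02, 28.645),
    (0.6, 0.35, 0.02, 28.403),
    (0.2, 0.35, 0.06, 34.803),
    (0.6, 0.35, 0.06, 32.705),
    (0.4, 0.25, 0.02, 26.752),
    (0.4, 0.45, 0.02, 28.920),
    (0.4, 0.25, 0.06, 31.801),
    (0.4, 0.45, 0.06, 34.353),
    (0.4, 0.35, 0.04, 31.697),
    (0.4, 0.35, 0.04, 31.740),
    (0.4, 0.35, 0.04, 32.059),
    (0.4, 0.35, 0.04, 31.844),
    (0.4, 0.35, 0.04, 31.779),
)

#: The five center-point replicate responses (runs 13-17 above).
BBD_CENTER_ALPHAS = (31.697, 31.740, 32.059, 31.844, 31.779)
#: Reported DEM replicate scatter at the design center (sample SD, degrees).
BBD_CENTER_SD_DEG = 0.14

def bbd_run_table() -> pd.DataFrame:
    """The Box-Behnken run table as a DataFrame (c1, c2, c3, alpha)."""
    return pd.DataFrame(list(BBD_RUNS), columns=["c1", "c2", "c3", "alpha"])

# ---------------------------------------------------------------------------
# Compression-test size classes: triaxial dimensions (with tolerances),
# equivalent diameter, sample size, and the fitted log-normal statistics.
# ---------------------------------------------------------------------------

SIZE_CLASSES = pd.DataFrame(
    {
        "L_mm": [5.6, 6.0, 6.4, 6.8],
        "L_tol_mm": [0.2, 0.2, 0.2, 0.2],
        "W_mm": [3.18, 3.06, 3.21, 3.32],
        "W_tol_mm": [0.05, 0.05, 0.05, 0.05],
        "T_mm": [2.79, 3.49, 3.78, 3.86],
        "T_tol_mm": [0.05, 0.05, 0.05, 0.05],
        "De_mm": [3.68, 4.01, 4.28, 4.44],
        "n": [12, 22, 26, 20],
        "E50_J_per_kg": [2710.97, 2120.32, 1965.70, 1804.21],
        "sigma": [0.25, 0.34, 0.35, 0.35],
    }
)

#: Population frequency of the four size classes (sums to 1).
CLASS_WEIGHTS = (0.15, 0.28, 0.32, 0.25)

#: Published population-weighted median fracture energy (J/kg).  Note that a
#: direct weighted sum of the class E50 values with CLASS_WEIGHTS gives
#: 2080.41 J/kg; the published rounding is kept here as a config constant.
WEIGHTED_E50_PUBLISHED = 2069.78

#: Published size-law fit constants (residual energy J/kg, characteristic
#: microstructure size mm, size exponent).  Config constants only: they are
#: not mutually consistent with the SIZE_CLASSES E50 column.
SIZE_LAW_PUBLISHED = {"E_inf": 73.40, "d0": 5.34, "phi": 12.63, "r2": 0.99192}

# ---------------------------------------------------------------------------
# Material/elastic properties and full simulation parameter set.
# ---------------------------------------------------------------------------

WHEAT_DENSITY_KG_M3 = 3050.0
WHEAT_POISSON = 0.42
WHEAT_SHEAR_MODULUS_PA = 6.484e7

ROLLER_DENSITY_KG_M3 = 7500.0
ROLLER_POISSON = 0.25
ROLLER_SHEAR_MODULUS_PA = 4.5e10

#: Breakage-model constants for the simulation parameter set.
TAVARES_CONSTANTS = {
    "gamma": 5.0,                 # cumulative damage coefficient
    "E_inf": 73.40,               # residual crushing energy, J/kg
    "d0": 5.34,                   # characteristic microstructure size, mm
    "phi": 12.63,                 # size exponent of E50(d)
    "sigma": 0.32,                # SD of ln fracture energy
    "A": 50.0,                    # t10 asymptote, %
    "b": 0.1808,                  # t10 energy coefficient
    "d_min_break": 0.30,          # minimum fragment size, mm
    "e_min_collision": 1e-4,      # minimum collision energy, J/kg
    "shear_energy_fraction": 0.0, # Ct: shear energy ignored
    "truncation_ratio_pct": 100.0,  # 100% = untruncated (Emax = inf)
    "max_t10": 4.97,              # %, cap on the fine-progeny fraction
}

#: Pooled fracture-energy distribution used for forward impact simulation.
POOLED_E50_J_PER_KG = WEIGHTED_E50_PUBLISHED
POOLED_SIGMA = TAVARES_CONSTANTS["sigma"]

# ---------------------------------------------------------------------------
# Drop-weight impact test configuration (grams / metres as published).
# ---------------------------------------------------------------------------

DROP_WEIGHT = {
    "ball_mass_g": 32.0,
    "drop_height_m": 0.03,
    "kernel_mass_g": 0.035,
    "g_m_s2": 9.8,
}
#: The resulting mass-specific impact energy (J/kg).
DROP_WEIGHT_ENERGY_J_PER_KG = 268.8

# ---------------------------------------------------------------------------
# Compression validation: experimental vs DEM-simulated fracture indicators.
# ---------------------------------------------------------------------------

VALIDATION_EXPERIMENTAL = {"fracture_force_N": 95.52,
                           "fracture_energy_mJ": 155.70}
VALIDATION_SIMULATED_MEAN = {"fracture_force_N": 99.79,
                             "fracture_energy_mJ": 157.67}
VALIDATION_SIMULATED_SD = {"fracture_force_N": 0.41,
                           "fracture_energy_mJ": 0.30}
VALIDATION_N_REPLICATES = 5

#: Mean kernel dimensions of the tested batch (mm).
BATCH_MEAN_DIMS_MM = {"L": 6.35, "W": 3.50, "T": 2.83}

#: Indenter loading speed in the compression tests, mm/min.
COMPRESSION_SPEED_MM_MIN = 15.0


def wheat_elastic():
    """ElasticProps of the wheat kernel (shear modulus + Poisson ratio)."""
    from .tavares_core import ElasticProps

    return ElasticProps(shear_modulus=WHEAT_SHEAR_MODULUS_PA,
                        poisson_ratio=WHEAT_POISSON)


def roller_elastic():
    """ElasticProps of the white cast iron roller."""
    from .tavares_core import ElasticProps

    return ElasticProps(shear_modulus=ROLLER_SHEAR_MODULUS_PA,
                        poisson_ratio=ROLLER_POISSON)


def default_material():
    """MaterialParams populated with the calibrated simulation constants."""
    from .tavares_core import MaterialParams

    c = TAVARES_CONSTANTS
    emax_ratio = math.inf if c["truncation_ratio_pct"] >= 100.0 else None
    return MaterialParams(
        E_inf=c["E_inf"], d0=c["d0"], phi=c["phi"], sigma=c["sigma"],
        gamma=c["gamma"], A=c["A"], b=c["b"], emax_ratio=emax_ratio,
        d_min_break=c["d_min_break"], e_min_collision=c["e_min_collision"],
        max_t10=c["max_t10"],
    )


def default_drop_weight():
    """DropWeightConfig for the published drop-weight test (SI units)."""
    from .tavares_core import DropWeightConfig

    d = DROP_WEIGHT
    return DropWeightConfig(
        mb=d["ball_mass_g"] * 1e-3,
        H1=d["drop_height_m"],
        g=d["g_m_s2"],
        m0=d["kernel_mass_g"] * 1e-3,
    )
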