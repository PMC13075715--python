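"""Seeded generators for every input the calibration pipeline consumes.

No public dataset of the underlying bench tests exists, so each stage of
the pipeline is exercised on synthetic data carrying the statistical
structure the analysis assumes:

* per-kernel contact coefficients scattered around the reference means at
  the reported per-group SDs, mapped back through the inverse of the
  measurement equations to raw slip/roll/rebound records;
* compression curves: Hertzian loading ramps cut at the displacement where
  the accumulated specific energy reaches a fracture energy drawn from the
  class log-normal distribution, followed by a sharp post-fracture force
  drop, with optional additive force noise;
* repeated-impact outcome series produced by the forward damage model at a
  ground-truth gamma;
* a quadratic angle-of-repose surrogate (coefficients refit from the
  reference run table) with Gaussian replicate noise at the reported
  center-point SD of 0.14 degrees.

Every generator is a deterministic function of its config and seed, and
the config records the ground truth so recovery tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .contact_reduction import RollRecord, ReboundRecord, SlipRecord
from .fracture_calibration import CompressionCurve, ImpactSeries, KernelDims
from .repose_rsm import QuadraticModel, fit_quadratic, BBRun
from .tavares_core import DropWeightConfig, MaterialParams, ParticleState

__all__ = [
    "SyntheticConfig",
    "gen_contact_measurements",
    "gen_compression_dataset",
    "gen_impact_outcomes",
    "gen_repose_surface",
    "ground_truth_repose_model",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and sampling scales for the synthetic generators.

    Defaults mirror the reference calibration (contact means and SDs,
    size-class fracture statistics, gamma = 5, repose replicate SD 0.14
    degrees) so synthetic runs produce familiar magnitudes.  ``noise=0``
    scales all measurement scatter to zero for round-trip tests.
    """

    seed: int = 0
    noise: float = 1.0  # global multiplier on all measurement scatter

    # contact ground truth (wheat vs roller surface)
    static_friction: float = datasets.STATIC_FRICTION_OVERALL
    static_friction_sd: float = 0.085
    rolling_friction: float = datasets.ROLLING_FRICTION_OVERALL
    rolling_friction_sd: float = 0.038
    restitution: float = datasets.RESTITUTION_OVERALL
    restitution_sd: float = 0.016
    n_friction_groups: int = 5
    n_kernels_per_friction_group: int = 20
    n_rebound_groups: int = 3
    n_kernels_per_rebound_group: int = 50
    roll_slope_deg: float = datasets.ROLL_TEST_SLOPE_DEG
    roll_slope_length_mm: float = datasets.ROLL_TEST_SLOPE_LENGTH_MM
    rebound_drop_heights_mm: tuple[float, ...] = (200.0, 200.0, 200.0)
    rebound_fall_heights_mm: tuple[float, ...] = (160.0, 170.0, 180.0)

    # compression / fracture ground truth
    class_des_mm: tuple[float, ...] = tuple(datasets.SIZE_CLASSES["De_mm"])
    class_e50: tuple[float, ...] = tuple(datasets.SIZE_CLASSES["E50_J_per_kg"])
    class_sigma: tuple[float, ...] = tuple(datasets.SIZE_CLASSES["sigma"])
    class_weights: tuple[float, ...] = datasets.CLASS_WEIGHTS
    n_compression_kernels: int = 80
    kernel_mass_g: float = 0.035
    kernel_mass_sd_g: float = 0.003
    force_noise_N: float = 0.5
    curve_samples: int = 400

    # repeated-impact ground truth
    gamma: float = datasets.TAVARES_CONSTANTS["gamma"]
    impact_energy_J_per_kg: float = datasets.DROP_WEIGHT_ENERGY_J_PER_KG
    pooled_e50: float = datasets.POOLED_E50_J_PER_KG
    pooled_sigma: float = datasets.POOLED_SIGMA
    n_impact_kernels: int = 10_000
    n_max_impacts: int = 100

    # repose surrogate
    repose_noise_sd_deg: float = datasets.BBD_CENTER_SD_DEG


# ---------------------------------------------------------------------------
# Contact measurements
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled normal draws clipped to a physical range."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def gen_contact_measurements(cfg: SyntheticConfig) -> dict:
    """Raw slip, roll and rebound record groups with the configured truth.

    Per-kernel coefficients are drawn Gaussian around the ground-truth
    means (truncated to physical ranges) and mapped back through the
    inverse measurement equations: slip angle = arctan(mu); roll distance
    s = l sin(theta)/theta_r - l cos(theta); landing distance
    L1 = 2 e1 sqrt(H h).  With ``noise=0`` the reductions return the
    ground truth exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.noise
    slip_groups, roll_groups, rebound_groups = [], [], []
    tan_th = math.tan(math.radians(cfg.roll_slope_deg))
    cos_th = math.cos(math.radians(cfg.roll_slope_deg))
    sin_th = math.sin(math.radians(cfg.roll_slope_deg))
    l = cfg.roll_slope_length_mm

    for _ in range(cfg.n_friction_groups):
        mu = _truncated_normal(rng, cfg.static_friction,
                               k * cfg.static_friction_sd, 1e-3, 20.0,
                               cfg.n_kernels_per_friction_group)
        slip_groups.append([
            SlipRecord(tilt_angle_deg=math.degrees(math.atan(m)), count=1)
            for m in mu
        ])
        # rolling friction must stay below tan(theta) for the kernel to roll
        th_r = _truncated_normal(rng, cfg.rolling_friction,
                                 k * cfg.rolling_friction_sd, 1e-3,
                                 0.999 * tan_th,
                                 cfg.n_kernels_per_friction_group)
        roll_groups.append([
            RollRecord(
                slope_angle_deg=cfg.roll_slope_deg,
                slope_length_mm=l,
                roll_distance_mm=l * sin_th / t - l * cos_th,
            )
            for t in th_r
        ])

    for g in range(cfg.n_rebound_groups):
        h = cfg.rebound_drop_heights_mm[g % len(cfg.rebound_drop_heights_mm)]
        H = cfg.rebound_fall_heights_mm[g % len(cfg.rebound_fall_heights_mm)]
        e1 = _truncated_normal(rng, cfg.restitution, k * cfg.restitution_sd,
                               1e-3, 1.0, cfg.n_kernels_per_rebound_group)
        rebound_groups.append([
            ReboundRecord(drop_height_mm=h, fall_height_mm=H,
                          landing_distance_mm=2.0 * v * math.sqrt(H * h))
            for v in e1
        ])
    return {"slip": slip_groups, "roll": roll_groups,
            "rebound": rebound_groups}


# ---------------------------------------------------------------------------
# Compression dataset
# ---------------------------------------------------------------------------

def _hertz_stiffness(De_mm: float) -> float:
    """Hertz prefactor k (N / m^1.5) for a kernel of diameter De against
    the reference platen stiffnesses."""
    from .tavares_core import plane_strain_stiffness

    Kp = plane_strain_stiffness(datasets.wheat_elastic())
    Ks = plane_strain_stiffness(datasets.roller_elastic())
    K_eff = 1.0 / (1.0 / Kp + 1.0 / Ks)
    return (4.0 / 3.0) * K_eff * math.sqrt(De_mm * 1e-3 / 2.0)


def gen_compression_dataset(
    cfg: SyntheticConfig,
) -> tuple[list[CompressionCurve], pd.DataFrame]:
    """Synthetic single-kernel compression curves plus a manifest.

    Kernels are assigned to the four size classes at the configured
    frequencies; each draws a fracture energy from its class log-normal
    distribution and yields a Hertzian loading ramp cut at the
    displacement where the integrated specific energy reaches that draw,
    followed by a three-sample force collapse so the fracture-point
    detector has a cliff to find.  Kernel dimensions are jittered within
    the class tolerances with L solved so the equivalent diameter
    reproduces the class De exactly.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    k_noise = cfg.noise
    classes = rng.choice(len(cfg.class_des_mm), size=cfg.n_compression_kernels,
                         p=np.asarray(cfg.class_weights))
    sc = datasets.SIZE_CLASSES
    curves: list[CompressionCurve] = []
    manifest_rows = []
    for i, ci in enumerate(classes):
        De = cfg.class_des_mm[ci]
        W = sc["W_mm"][ci] + k_noise * rng.uniform(-1, 1) * sc["W_tol_mm"][ci]
        T = sc["T_mm"][ci] + k_noise * rng.uniform(-1, 1) * sc["T_tol_mm"][ci]
        L = 4.0 * De**3 / (W + T) ** 2  # exact class De by construction
        mass = float(_truncated_normal(rng, cfg.kernel_mass_g,
                                       k_noise * cfg.kernel_mass_sd_g,
                                       5e-3, 0.2, 1)[0])
        Ef = cfg.class_e50[ci] * math.exp(
            cfg.class_sigma[ci] * rng.standard_normal()
        )
        k_hertz = _hertz_stiffness(De)
        # displacement (m) where (2/5) k d^2.5 = Ef * mass(kg)
        d_c = (5.0 * Ef * mass * 1e-3 / (2.0 * k_hertz)) ** 0.4
        n = cfg.curve_samples
        d = np.linspace(0.0, d_c, n)
        f = k_hertz * d**1.5
        peak = f[-1]
        # post-fracture collapse over three samples
        step = d[1] - d[0] if n > 1 else 1e-6
        d_post = d[-1] + step * np.arange(1, 4)
        f_post = peak * np.array([0.55, 0.15, 0.03])
        disp = np.concatenate([d, d_post]) * 1e3  # -> mm
        force = np.concatenate([f, f_post])
        if k_noise * cfg.force_noise_N > 0:
            noise = rng.normal(0.0, k_noise * cfg.force_noise_N, force.size)
            noise[0] = 0.0
            force = np.clip(force + noise, 0.0, None)
        dims = KernelDims(L=L, W=W, T=T, mass=mass)
        curves.append(CompressionCurve(displacement=disp, force=force,
                                       dims=dims))
        manifest_rows.append({
            "kernel": i, "size_class": int(ci), "De_mm": De,
            "L_mm": L, "W_mm": W, "T_mm": T, "mass_g": mass,
            "true_Ef_J_per_kg": Ef,
        })
    manifest = pd.DataFrame(manifest_rows).set_index("kernel")
    return curves, manifest


# ---------------------------------------------------------------------------
# Impact outcomes
# ---------------------------------------------------------------------------

def gen_impact_outcomes(cfg: SyntheticConfig) -> ImpactSeries:
    """Per-kernel impacts-to-breakage from the forward damage model.

    Delegates to the repeated-impact simulator at the ground-truth gamma,
    so downstream gamma estimation is a closed recovery loop.
    """
    from .impact_sim import simulate_repeated_impacts

    material = datasets.default_material()
    dw = DropWeightConfig(mb=1.0, H1=cfg.impact_energy_J_per_kg / 9.8,
                          g=9.8, m0=1.0)
    res = simulate_repeated_impacts(
        dw, material, cfg.pooled_e50, cfg.pooled_sigma,
        n_kernels=cfg.n_impact_kernels, seed=cfg.seed + 2,
        n_max=cfg.n_max_impacts, gamma=cfg.gamma,
    )
    counts = np.where(res.censored, cfg.n_max_impacts,
                      res.impacts_to_breakage)
    return ImpactSeries(Ek=cfg.impact_energy_J_per_kg,
                        impacts_to_breakage=counts,
                        censored=res.censored.copy())


# ---------------------------------------------------------------------------
# Repose surrogate
# ---------------------------------------------------------------------------

def ground_truth_repose_model() -> QuadraticModel:
    """Quadratic repose surface refit by OLS from the reference run table."""
    runs = [BBRun(*r) for r in datasets.BBD_RUNS]
    return fit_quadratic(runs)


def gen_repose_surface(cfg: SyntheticConfig,
                       model: QuadraticModel | None = None):
    """A pluggable angle-of-repose evaluator ``f(c1, c2, c3) -> alpha``.

    Evaluates the ground-truth quadratic surface plus Gaussian replicate
    noise (SD ``repose_noise_sd_deg`` scaled by ``noise``).  Successive
    calls consume one seeded stream, so a fixed-seed evaluator filling a
    design is deterministic.
    """
    if model is None:
        model = ground_truth_repose_model()
    rng = np.random.default_rng(cfg.seed + 3)
    sd = cfg.noise * cfg.repose_noise_sd_deg

    def evaluate(c1: float, c2: float, c3: float) -> float:
        alpha = model.predict(c1, c2, c3)
        if sd > 0:
            alpha += rng.normal(0.0, sd)
        return float(alpha)

    evaluate.ground_truth = model
    return evaluate
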