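"""Core equations of the Tavares particle-breakage model.

The model describes single-particle breakage under impact or compression:

* the probability that a particle of median fracture energy ``E50`` breaks
  when stressed with mass-specific energy ``E`` follows an (optionally
  upper-truncated) log-normal distribution;
* the median fracture energy scales with particle size through a power law
  with a residual energy floor;
* sub-critical impacts do not break the particle but accumulate damage,
  lowering its fracture energy for subsequent stressing events;
* the fineness of the progeny after breakage is summarised by the t10 index
  (mass % of fragments finer than 1/10 of the parent size).

Energies are mass-specific (J/kg), particle sizes mm, moduli Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "ElasticProps",
    "MaterialParams",
    "ParticleState",
    "DropWeightConfig",
    "EnergySaturationError",
    "SupercriticalImpactError",
    "DamageConvergenceError",
    "plane_strain_stiffness",
    "relative_fracture_energy",
    "breakage_probability",
    "median_fracture_energy_for_size",
    "impact_energy",
    "collision_energy_ratio",
    "solve_damage",
    "damage_fixed_point",
    "apply_impact",
    "t10_fraction",
    "spawn_progeny",
]


class EnergySaturationError(ValueError):
    """Stressing energy at or above the truncation energy: breakage certain."""


class SupercriticalImpactError(ValueError):
    """Impact energy reaches the particle's fracture energy: it breaks."""


class DamageConvergenceError(RuntimeError):
    """Damage fixed-point iteration failed to converge."""

    def __init__(self, last_iterate: float, n_iter: int):
        self.last_iterate = last_iterate
        self.n_iter = n_iter
        super().__init__(
            f"damage iteration did not converge after {n_iter} steps "
            f"(last iterate {last_iterate!r})"
        )


@dataclass(frozen=True)
class ElasticProps:
    """Isotropic elastic constants of a contacting body.

    Exactly one of ``young_modulus`` / ``shear_modulus`` must be given; the
    other is derived via Y = 2 G (1 + nu).
    """

    poisson_ratio: float
    young_modulus: float | None = None
    shear_modulus: float | None = None

    def __post_init__(self):
        nu = self.poisson_ratio
        if not 0.0 < nu < 0.5:
            raise ValueError(f"poisson_ratio must lie in (0, 0.5), got {nu}")
        if (self.young_modulus is None) == (self.shear_modulus is None):
            raise ValueError(
                "give exactly one of young_modulus or shear_modulus"
            )
        if self.young_modulus is None:
            G = self.shear_modulus
            if G <= 0:
                raise ValueError("shear modulus must be positive")
            object.__setattr__(self, "young_modulus", 2.0 * G * (1.0 + nu))
        else:
            Y = self.young_modulus
            if Y <= 0:
                raise ValueError("Young modulus must be positive")
            object.__setattr__(self, "shear_modulus", Y / (2.0 * (1.0 + nu)))


@dataclass(frozen=True)
class MaterialParams:
    """Breakage-model constants for one material.

    ``emax_ratio`` sets the truncation energy as a multiple of the median
    fracture energy; ``math.inf`` means an untruncated log-normal.
    """

    E_inf: float          # residual crushing energy, J/kg
    d0: float             # characteristic microstructure size, mm
    phi: float            # size exponent of E50(d)
    sigma: float          # SD of ln fracture energy
    gamma: float          # cumulative damage coefficient
    A: float = 50.0       # t10 asymptote, %
    b: float = 0.1808     # t10 energy coefficient
    emax_ratio: float = math.inf
    d_min_break: float = 0.30       # minimum fragment size, mm
    e_min_collision: float = 1e-4   # minimum collision energy, J/kg
    max_t10: float = 100.0          # %, cap on the fine-progeny fraction

    def __post_init__(self):
        checks = {
            "E_inf": self.E_inf > 0,
            "d0": self.d0 > 0,
            "phi": self.phi > 0,
            "sigma": self.sigma > 0,
            "gamma": self.gamma > 0,
            "A": 0 < self.A <= 100,
            "b": self.b > 0,
            "emax_ratio": self.emax_ratio > 1,
            "d_min_break": self.d_min_break > 0,
            "e_min_collision": self.e_min_collision > 0,
            "max_t10": 0 < self.max_t10 <= 100,
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid MaterialParams field(s): {bad}")


@dataclass
class ParticleState:
    """One kernel: size, mass, current fracture energy, accumulated damage."""

    dn: float       # particle size, mm
    mass: float     # kg
    Ef: float       # current fracture energy, J/kg
    damage: float = 0.0
    broken: bool = False

    def __post_init__(self):
        if self.dn <= 0 or self.mass <= 0:
            raise ValueError("dn and mass must be positive")
        if not self.broken and self.Ef <= 0:
            raise ValueError("Ef must be positive for an unbroken particle")
        if not 0.0 <= self.damage <= 1.0:
            raise ValueError("damage must lie in [0, 1]")


@dataclass(frozen=True)
class DropWeightConfig:
    """Drop-weight impact test: steel ball dropped onto a single kernel."""

    mb: float          # steel ball mass, kg
    H1: float          # drop height, m
    g: float = 9.8     # m/s^2
    m0: float = 3.5e-5  # kernel mass, kg

    def __post_init__(self):
        if min(self.mb, self.g, self.m0) <= 0 or self.H1 < 0:
            raise ValueError("DropWeightConfig values must be positive "
                             "(H1 may be zero)")


# ---------------------------------------------------------------------------
# Stiffness and energy partitioning
# ---------------------------------------------------------------------------

def plane_strain_stiffness(props: ElasticProps) -> float:
    """Plane-strain modulus K = Y / (1 - nu^2) in Pa."""
    return props.young_modulus / (1.0 - props.poisson_ratio**2)


def collision_energy_ratio(wheat: ElasticProps, tool: ElasticProps) -> float:
    """Fraction e = 1/(1 + Kp/Ks) of collision energy absorbed by the particle.

    The stiffer the tool relative to the particle, the closer e is to 1.
    """
    ratio = plane_strain_stiffness(wheat) / plane_strain_stiffness(tool)
    return 1.0 / (1.0 + ratio)


# ---------------------------------------------------------------------------
# Breakage probability
# ---------------------------------------------------------------------------

def relative_fracture_energy(E: float, Emax: float) -> float:
    """Relative energy E* = Emax*E/(Emax - E); equals E for Emax = inf."""
    if E <= 0:
        raise ValueError("E must be positive")
    if math.isinf(Emax):
        return E
    if E >= Emax:
        raise EnergySaturationError(
            f"E={E} >= Emax={Emax}: breakage probability is 1"
        )
    return Emax * E / (Emax - E)


def breakage_probability(E, E50: float, sigma: float,
                         Emax: float = math.inf):
    """Log-normal breakage probability P(E); accepts scalars or arrays.

    P = 1/2 [1 + erf((ln E* - ln E50) / (sqrt(2) sigma))], with P(0) = 0 and
    P = 1 for E >= Emax when the distribution is truncated.
    """
    if E50 <= 0 or sigma <= 0:
        raise ValueError("E50 and sigma must be positive")
    scalar = np.isscalar(E) or np.ndim(E) == 0
    E = np.atleast_1d(np.asarray(E, dtype=float))
    if np.any(E < 0):
        raise ValueError("E must be nonnegative")
    P = np.zeros_like(E)
    if math.isinf(Emax):
        pos = E > 0
        Estar = E[pos]
    else:
        P[E >= Emax] = 1.0
        pos = (E > 0) & (E < Emax)
        Epos = E[pos]
        Estar = Emax * Epos / (Emax - Epos)
    P[pos] = 0.5 * (1.0 + erf(
        (np.log(Estar) - math.log(E50)) / (math.sqrt(2.0) * sigma)
    ))
    return float(P[0]) if scalar else P


def median_fracture_energy_for_size(dn: float, wheat: ElasticProps,
                                    tool: ElasticProps,
                                    params: MaterialParams) -> float:
    """Size-dependent median fracture energy, J/kg.

    E50(d) = E_inf * (1 + Kp/Ks) * [1 + (d0/dn)^phi]: small particles are
    disproportionately stronger; E50 decays to the residual energy floor
    E_inf*(1 + Kp/Ks) for large particles.
    """
    if dn <= 0:
        raise ValueError("dn must be positive")
    ratio = plane_strain_stiffness(wheat) / plane_strain_stiffness(tool)
    return params.E_inf * (1.0 + ratio) * (1.0 + (params.d0 / dn) ** params.phi)


def impact_energy(cfg: DropWeightConfig) -> float:
    """Mass-specific impact energy of one steel-ball drop, J/kg.

    v0 = sqrt(2 g H1);  Ek = mb v0^2 / (2 m0).
    """
    v0_sq = 2.0 * cfg.g * cfg.H1
    return cfg.mb * v0_sq / (2.0 * cfg.m0)


# ---------------------------------------------------------------------------
# Damage accumulation
# ---------------------------------------------------------------------------

def damage_fixed_point(r, gamma: float, tol: float = 1e-10,
                       max_iter: int = 200):
    """Solve D = [(2g/(2g - 5D + 5)) * r]^(2g/5) by successive substitution.

    ``r`` is the sub-critical energy ratio e*Ek/Ef (scalar or array, < 1).
    Starts from D = 0, clamps each iterate to [0, 1].  The iteration is
    monotone increasing and bounded, so it converges to the least fixed
    point; non-convergence within ``max_iter`` raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 1):
        raise ValueError("energy ratio r must lie in [0, 1)")
    p = 2.0 * gamma / 5.0
    D = np.zeros_like(r)
    for _ in range(max_iter):
        Dn = np.clip(
            (2.0 * gamma / (2.0 * gamma - 5.0 * D + 5.0) * r) ** p, 0.0, 1.0
        )
        delta = np.max(np.abs(Dn - D)) if Dn.size else 0.0
        D = Dn
        if delta < tol:
            return float(D) if D.ndim == 0 else D
    raise DamageConvergenceError(
        float(np.max(D)) if D.size else 0.0, max_iter
    )


def solve_damage(Ek: float, state: ParticleState, gamma: float,
                 e: float) -> float:
    """Damage D accrued by one sub-critical impact of energy ``Ek``.

    Requires e*Ek < state.Ef; a super-critical impact should break the
    particle instead (raises SupercriticalImpactError).
    """
    if Ek < 0:
        raise ValueError("Ek must be nonnegative")
    if Ek == 0:
        return 0.0
    if e * Ek >= state.Ef:
        raise SupercriticalImpactError(
            f"e*Ek = {e * Ek} >= Ef = {state.Ef}: particle breaks"
        )
    return damage_fixed_point(e * Ek / state.Ef, gamma)


def apply_impact(state: ParticleState, Ek: float, gamma: float,
                 e: float) -> ParticleState:
    """Apply one impact: break the particle or weaken its fracture energy.

    Returns a new state; if e*Ek >= Ef the broken flag is set, otherwise
    Ef' = Ef (1 - D) and the accumulated damage composes multiplicatively:
    1 - damage' = (1 - damage)(1 - D).  Ef never increases.
    """
    if state.broken:
        raise ValueError("cannot impact an already broken particle")
    if e * Ek >= state.Ef:
        return replace(state, broken=True)
    D = solve_damage(Ek, state, gamma, e)
    return replace(
        state,
        Ef=state.Ef * (1.0 - D),
        damage=1.0 - (1.0 - state.damage) * (1.0 - D),
    )


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def t10_fraction(Ek: float, E50: float, e: float, A: float,
                 b: float) -> float:
    """t10 fineness index, %: t10 = A [1 - exp(-b e Ek / E50)].

    Monotone increasing in Ek with asymptote A.
    """
    if min(E50, e, A, b) <= 0 or Ek < 0:
        raise ValueError("t10_fraction arguments must be positive (Ek >= 0)")
    return A * (1.0 - math.exp(-b * e * Ek / E50))


def spawn_progeny(state: ParticleState, t10: float,
                  params: MaterialParams) -> list[ParticleState]:
    """Replace a broken parent by a mass-conserving two-bin fragment set.

    The fine bin carries t10% of the parent mass at one-tenth the parent
    size (floored at ``params.d_min_break``); the coarse bin carries the
    remainder at the mass-consistent reduced size.  Parents already at or
    below the minimum breakable size are returned unchanged (unbroken).
    """
    if not state.broken:
        raise ValueError("spawn_progeny requires a broken particle")
    if not 0.0 <= t10 <= params.max_t10:
        raise ValueError(f"t10 must lie in [0, {params.max_t10}] %")
    if state.dn <= params.d_min_break:
        return [replace(state, broken=False)]
    f = t10 / 100.0
    fragments: list[ParticleState] = []
    if f > 0:
        fragments.append(ParticleState(
            dn=max(state.dn / 10.0, params.d_min_break),
            mass=state.mass * f,
            Ef=state.Ef,
        ))
    coarse_mass = state.mass * (1.0 - f)
    if coarse_mass > 0:
        fragments.append(ParticleState(
            dn=max(state.dn * (1.0 - f) ** (1.0 / 3.0), params.d_min_break),
            mass=coarse_mass,
            Ef=state.Ef,
        ))
    return fragments
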