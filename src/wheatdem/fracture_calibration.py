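"""Calibration of the breakage-model parameters from bench tests.

Single-kernel compression curves give each kernel's specific fracture
energy (area under the force-displacement curve up to the fracture point,
divided by kernel mass).  Pooled per size class, the energies are fitted
with a log-normal CDF against median-rank plotting positions to obtain the
class median E50 and log-SD sigma; a population-weighted E50 and the
size-scaling law E50(d) follow.  Repeated drop-weight impact outcomes then
calibrate the damage-accumulation coefficient gamma by matching the
forward-simulated breakage-probability curve.

Units: displacement mm, force N, mass g in :class:`KernelDims` (so that
N*mm / g = J/kg directly), energies J/kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .tavares_core import DropWeightConfig, MaterialParams

__all__ = [
    "KernelDims",
    "CompressionCurve",
    "SizeClassStats",
    "ImpactSeries",
    "SizeLawFit",
    "GammaEstimate",
    "equivalent_diameter",
    "specific_fracture_energy",
    "detect_fracture_point",
    "rank_breakage_probability",
    "fit_lognormal_fracture_energy",
    "weighted_E50",
    "fit_E50_size_law",
    "assign_size_class",
    "estimate_gamma",
]


@dataclass(frozen=True)
class KernelDims:
    """Triaxial kernel dimensions (mm) and mass (g)."""

    L: float
    W: float
    T: float
    mass: float

    def __post_init__(self):
        if min(self.L, self.W, self.T) <= 0:
            raise ValueError("dimensions must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass
class CompressionCurve:
    """Force-displacement record of one kernel under compression."""

    displacement: np.ndarray  # mm, strictly increasing from 0
    force: np.ndarray         # N
    dims: KernelDims

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        d = self.displacement
        if d[0] < 0 or np.any(np.diff(d) <= 0):
            raise ValueError("displacement must be strictly increasing "
                             "starting at >= 0")
        if np.any(self.force < 0):
            raise ValueError("force must be nonnegative")


@dataclass
class SizeClassStats:
    """Per-size-class log-normal fit and population weight."""

    De_class: float   # class equivalent diameter, mm
    n: int
    E50: float        # J/kg
    sigma: float
    weight: float     # population frequency fraction
    r2: float = float("nan")


@dataclass
class ImpactSeries:
    """Repeated drop-weight outcomes: impacts-to-breakage per kernel.

    ``censored`` marks kernels still unbroken when the test stopped; their
    count records the number of impacts sustained.
    """

    Ek: float                     # per-impact energy, J/kg
    impacts_to_breakage: np.ndarray  # positive ints
    censored: np.ndarray | None = None

    def __post_init__(self):
        self.impacts_to_breakage = np.asarray(self.impacts_to_breakage,
                                              dtype=int)
        if np.any(self.impacts_to_breakage < 1):
            raise ValueError("impact counts must be >= 1")
        if self.censored is None:
            self.censored = np.zeros(self.impacts_to_breakage.shape,
                                     dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)

    def empirical_curve(self, n_max: int) -> np.ndarray:
        """P(broken by impact n) for n = 1..n_max over all kernels."""
        n_kernels = self.impacts_to_breakage.size
        broken_at = np.where(self.censored, np.iinfo(np.int64).max,
                             self.impacts_to_breakage)
        ns = np.arange(1, n_max + 1)
        return (broken_at[None, :] <= ns[:, None]).mean(axis=1)


def equivalent_diameter(d: KernelDims) -> float:
    """Isovolumetric equivalent diameter De = [L (W+T)^2 / 4]^(1/3), mm."""
    return (d.L * (d.W + d.T) ** 2 / 4.0) ** (1.0 / 3.0)


def specific_fracture_energy(curve: CompressionCurve,
                             fracture_index: int) -> float:
    """Specific fracture energy, J/kg: trapezoidal integral of F dDelta
    up to the fracture point, divided by kernel mass.

    With displacement in mm, force in N and mass in g the quotient is in
    J/kg without further conversion (1 N mm / 1 g = 1 J/kg).
    """
    if not 0 <= fracture_index < curve.displacement.size:
        raise ValueError("fracture_index outside the curve")
    if curve.dims.mass <= 0:
        raise ValueError("kernel mass must be positive")
    area = np.trapezoid(curve.force[: fracture_index + 1],
                        curve.displacement[: fracture_index + 1])
    return float(area / curve.dims.mass)


def detect_fracture_point(curve: CompressionCurve,
                          drop_fraction: float = 0.30,
                          window: int = 3,
                          min_peak_frac: float = 0.05) -> int:
    """Index of the fracture point: the running-maximum sample preceding
    the first force drop of at least ``drop_fraction`` of that maximum
    within ``window`` samples.

    The drop is assessed against the local maximum of the preceding
    ``window`` samples, so it must happen quickly (a fracture cliff), and
    only once that maximum exceeds ``min_peak_frac`` of the curve's global
    maximum, so measurement noise around zero force at the start of
    loading cannot register as a fracture.
    """
    f = curve.force
    if f.size < 10:
        raise ValueError("need at least 10 samples")
    floor = min_peak_frac * float(f.max())
    for j in range(1, f.size):
        local_max = float(f[max(0, j - window): j].max())
        if local_max > floor and f[j] <= (1.0 - drop_fraction) * local_max:
            return int(np.argmax(f[:j]))
    raise ValueError(
        "no qualifying force drop found; supply the fracture index manually"
    )


def rank_breakage_probability(n_samples: int) -> np.ndarray:
    """Median-rank plotting positions P_i = (i - 0.5)/N for i = 1..N."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return (np.arange(1, n_samples + 1) - 0.5) / n_samples


def fit_lognormal_fracture_energy(
    energies: Sequence[float],
) -> tuple[float, float, float]:
    """Fit the log-normal breakage CDF to rank-probability points.

    Least squares of P = Phi((ln E - ln E50)/sigma) against the empirical
    plotting positions in (ln E, P) space, matching the conventional
    plotted-curve fit with reported R^2.  Returns (E50, sigma, R^2).
    """
    e = np.sort(np.asarray(list(energies), dtype=float))
    if e.size < 5:
        raise ValueError("need at least 5 energies")
    if np.any(e <= 0):
        raise ValueError("energies must be positive")
    lnE = np.log(e)
    P = rank_breakage_probability(e.size)

    # exact start from the linearised probit fit
    z = stats.norm.ppf(P)
    slope, intercept = np.polyfit(lnE, z, 1)
    mu0, sig0 = -intercept / slope, 1.0 / slope

    def model(x, mu, sigma):
        return stats.norm.cdf((x - mu) / sigma)

    popt, _ = optimize.curve_fit(model, lnE, P, p0=[mu0, max(sig0, 1e-6)],
                                 maxfev=20000)
    mu, sigma = popt
    sigma = abs(float(sigma))
    pred = model(lnE, mu, sigma)
    ss_res = float(((P - pred) ** 2).sum())
    ss_tot = float(((P - P.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(np.exp(mu)), sigma, r2


def weighted_E50(stats_list: Sequence[SizeClassStats]) -> float:
    """Population-weighted median fracture energy over size classes."""
    w = np.array([s.weight for s in stats_list], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"class weights must sum to 1 (got {w.sum()})")
    e50 = np.array([s.E50 for s in stats_list], dtype=float)
    return float((w * e50).sum())


def assign_size_class(De: float, class_des: Sequence[float]) -> int:
    """Index of the nearest size-class equivalent diameter."""
    des = np.asarray(class_des, dtype=float)
    return int(np.argmin(np.abs(des - De)))


@dataclass
class SizeLawFit:
    """Fitted size-scaling law E50(d) = E_inf (1+Kp/Ks) [1 + (d0/d)^phi]."""

    E_inf: float
    d0: float
    phi: float
    r2: float
    sse: float
    degenerate: bool = False


def fit_E50_size_law(
    pairs: Sequence[tuple[float, float]],
    stiffness_ratio: float = 0.0,
    n_starts: int = 20,
    seed: int = 0,
) -> SizeLawFit:
    """Nonlinear least squares of the size-scaling law to (De, E50) pairs.

    Multi-start over log-spaced initial values (deterministic given
    ``seed``); the best-SSE solution wins.  A fitted phi near zero (the
    response does not depend on size) is flagged degenerate.
    """
    pairs = list(pairs)
    if len(pairs) < 4:
        raise ValueError("need at least 4 (De, E50) pairs")
    De = np.array([p[0] for p in pairs], dtype=float)
    E50 = np.array([p[1] for p in pairs], dtype=float)
    k = 1.0 + stiffness_ratio

    def resid(logp):
        e_inf, d0, phi = np.exp(np.clip(logp, -50.0, 50.0))
        # evaluate the power term in log space, capped to stay finite for
        # extreme multi-start candidates
        term = np.exp(np.minimum(phi * np.log(d0 / De), 300.0))
        return e_inf * k * (1.0 + term) - E50

    rng = np.random.default_rng(seed)
    e_inf_grid = np.geomspace(E50.min() / 50.0, E50.min(), 5)
    d0_grid = np.geomspace(De.min() / 2.0, De.max() * 2.0, 4)
    phi_grid = np.geomspace(0.5, 20.0, 5)
    starts = [(a, b, c) for a in e_inf_grid for b in d0_grid
              for c in phi_grid]
    rng.shuffle(starts)
    starts = starts[: max(n_starts, 1)]

    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(resid, np.log(s), method="lm",
                                         max_nfev=5000)
        except Exception:
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise RuntimeError(
            f"size-law fit failed to converge from any of {len(starts)} "
            "starting points"
        )
    sse, sol = best
    e_inf, d0, phi = np.exp(sol.x)
    ss_tot = float(((E50 - E50.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 1.0
    degenerate = phi < 1e-3 or (d0 / De.max()) ** phi < 1e-8
    return SizeLawFit(E_inf=float(e_inf), d0=float(d0), phi=float(phi),
                      r2=r2, sse=sse, degenerate=degenerate)


@dataclass
class GammaEstimate:
    """Result of the damage-coefficient grid search."""

    gamma: float          # refined estimate
    gamma_grid_best: float
    grid: np.ndarray
    sse: np.ndarray
    n_kernels: int
    seed: int


def estimate_gamma(
    series: ImpactSeries,
    E50: float,
    sigma: float,
    e: float,
    cfg: DropWeightConfig | None = None,
    grid: np.ndarray | None = None,
    n_kernels: int = 10_000,
    n_max: int | None = None,
    seed: int = 0,
    material: MaterialParams | None = None,
) -> GammaEstimate:
    """Least-squares calibration of the damage coefficient gamma.

    For each candidate gamma on the grid (default 0.5..20 step 0.1) the
    repeated-impact experiment is forward-simulated with ``n_kernels``
    virtual kernels (one fixed seed shared by all candidates, so the SSE
    surface is deterministic and smooth in gamma) and compared with the
    empirical breakage-probability curve from ``series``.  The grid
    minimum is refined by a parabolic step through its neighbours.
    """
    from .impact_sim import simulate_repeated_impacts
    from . import datasets

    if series.impacts_to_breakage.size == 0:
        raise ValueError("empty impact series")
    if grid is None:
        grid = np.round(np.arange(0.5, 20.0 + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if n_max is None:
        n_max = int(series.impacts_to_breakage.max())
    if material is None:
        material = datasets.default_material()
    if cfg is None:
        # Ek = mb*g*H1/m0: any config delivering the series energy will do
        cfg = DropWeightConfig(mb=1.0, H1=series.Ek / 9.8, g=9.8, m0=1.0)
    p_emp = series.empirical_curve(n_max)
    if np.any(np.diff(p_emp) < -1e-12):
        warnings.warn("empirical breakage curve is non-monotone",
                      stacklevel=2)

    sse = np.empty(grid.size)
    for i, g in enumerate(grid):
        res = simulate_repeated_impacts(
            cfg, material, E50, sigma, n_kernels=n_kernels, seed=seed,
            n_max=n_max, e=e, gamma=g,
        )
        sse[i] = float(((res.p_break - p_emp) ** 2).sum())

    k = int(np.argmin(sse))
    gamma_grid = float(grid[k])
    gamma_ref = gamma_grid
    if 0 < k < grid.size - 1:
        # parabolic vertex through the three points around the minimum
        x0, x1, x2 = grid[k - 1: k + 2]
        y0, y1, y2 = sse[k - 1: k + 2]
        denom = (y0 - 2.0 * y1 + y2)
        if denom > 0:
            step = 0.5 * (y0 - y2) / denom
            gamma_ref = float(x1 + step * (x2 - x1))
    return GammaEstimate(gamma=gamma_ref, gamma_grid_best=gamma_grid,
                         grid=grid, sse=sse, n_kernels=n_kernels, seed=seed)
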