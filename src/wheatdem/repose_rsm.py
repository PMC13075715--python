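"""Box-Behnken design and response-surface calibration of contact parameters.

The three wheat-wheat contact coefficients (restitution c1, static friction
c2, rolling friction c3) cannot be measured directly; they are calibrated
by matching the simulated angle of repose of a poured pile to the measured
one.  A three-factor Box-Behnken design samples the factor box, a full
quadratic surface is fitted by ordinary least squares, an ANOVA with
lack-of-fit / pure-error decomposition assesses the fit, and the surface is
inverted for the factor triple whose predicted repose angle matches the
experimental target.

The multi-particle DEM pile simulation itself is out of scope here: any
callable ``(c1, c2, c3) -> alpha`` can supply responses, e.g. a recorded
run table or the synthetic surrogate in :mod:`wheatdem.synthetic_data`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BBRun",
    "QuadraticModel",
    "OptimizationResult",
    "TERM_NAMES",
    "box_behnken_design",
    "quadratic_design_matrix",
    "fit_quadratic",
    "anova",
    "center_replicate_stats",
    "optimize_contact_params",
    "relative_error",
]

#: Order of the 10-term full quadratic basis in three factors.
TERM_NAMES = (
    "intercept", "c1", "c2", "c3",
    "c1:c2", "c1:c3", "c2:c3",
    "c1^2", "c2^2", "c3^2",
)


@dataclass
class BBRun:
    """One design run: factor triple and (possibly pending) response."""

    c1: float
    c2: float
    c3: float
    alpha: float | None = None


@dataclass
class QuadraticModel:
    """Fitted full-quadratic response surface in natural factor units."""

    coefficients: dict[str, float]
    bounds: tuple[tuple[float, float], tuple[float, float],
                  tuple[float, float]]
    r2: float
    n_runs: int

    def predict(self, c1, c2, c3):
        """Predicted response; broadcasts over array inputs."""
        c1 = np.asarray(c1, dtype=float)
        c2 = np.asarray(c2, dtype=float)
        c3 = np.asarray(c3, dtype=float)
        b = self.coefficients
        out = (
            b["intercept"]
            + b["c1"] * c1 + b["c2"] * c2 + b["c3"] * c3
            + b["c1:c2"] * c1 * c2 + b["c1:c3"] * c1 * c3
            + b["c2:c3"] * c2 * c3
            + b["c1^2"] * c1**2 + b["c2^2"] * c2**2 + b["c3^2"] * c3**2
        )
        return float(out) if out.ndim == 0 else out


@dataclass
class OptimizationResult:
    """Outcome of inverting the response surface for a target angle."""

    params: tuple[float, float, float]
    achieved_alpha: float
    deviation: float
    non_unique: bool
    on_boundary: bool


def box_behnken_design(
    bounds: Sequence[tuple[float, float]],
    n_center: int = 5,
) -> list[BBRun]:
    """Three-factor Box-Behnken design: 12 edge midpoints + center runs.

    Each non-center run sets one factor to its center and the other two to
    their low/high levels; with ``n_center=5`` this yields 17 runs.
    """
    if len(bounds) != 3:
        raise ValueError("exactly three factor bounds required")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("degenerate factor bounds (high must exceed low)")
    mid = (lo + hi) / 2.0
    levels = {-1.0: lo, 0.0: mid, 1.0: hi}  # exact bounds at the extremes
    runs = []
    for i, j in itertools.combinations(range(3), 2):
        for si, sj in itertools.product((-1.0, 1.0), repeat=2):
            coded = np.zeros(3)
            coded[i], coded[j] = si, sj
            natural = [levels[c][k] for k, c in enumerate(coded)]
            runs.append(BBRun(*natural))
    for _ in range(n_center):
        runs.append(BBRun(*mid))
    return runs


def quadratic_design_matrix(c1, c2, c3) -> np.ndarray:
    """Model matrix of the full quadratic basis, columns in TERM_NAMES order."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    c3 = np.asarray(c3, dtype=float)
    return np.column_stack([
        np.ones_like(c1), c1, c2, c3,
        c1 * c2, c1 * c3, c2 * c3,
        c1**2, c2**2, c3**2,
    ])


def _runs_to_arrays(runs: Sequence[BBRun]):
    withy = [r for r in runs if r.alpha is not None]
    c = np.array([[r.c1, r.c2, r.c3] for r in withy])
    y = np.array([r.alpha for r in withy], dtype=float)
    return c, y


def fit_quadratic(runs: Sequence[BBRun]) -> QuadraticModel:
    """Ordinary least squares of the full quadratic surface (natural units)."""
    c, y = _runs_to_arrays(runs)
    if len(y) < 10:
        raise ValueError("need at least 10 runs with responses")
    X = quadratic_design_matrix(c[:, 0], c[:, 1], c[:, 2])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased terms via the null space of X
        _, s, vt = np.linalg.svd(X)
        null = vt[rank:]
        aliased = [TERM_NAMES[j] for j in range(X.shape[1])
                   if np.any(np.abs(null[:, j]) > 1e-8)]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    bounds = tuple((float(c[:, k].min()), float(c[:, k].max()))
                   for k in range(3))
    return QuadraticModel(
        coefficients=dict(zip(TERM_NAMES, beta.astype(float))),
        bounds=bounds, r2=r2, n_runs=len(y),
    )


def anova(model: QuadraticModel, runs: Sequence[BBRun]) -> pd.DataFrame:
    """Variance decomposition of the fitted surface.

    Partial (Type-III) sum of squares per single-df term, residual split
    into lack-of-fit and pure error (from exact factor-replicate groups),
    F ratios against the residual mean square (lack of fit against pure
    error), and p-values from the F distribution.  Term SS are computed on
    the coded (-1..+1) design, the convention of response-surface software,
    so linear-term SS are free of correlation with the quadratic columns;
    fitted values and the residual decomposition are coding-invariant.
    """
    c, y = _runs_to_arrays(runs)
    lo, hi = c.min(axis=0), c.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    c = 2.0 * (c - lo) / span - 1.0  # code factors to [-1, 1]
    X = quadratic_design_matrix(c[:, 0], c[:, 1], c[:, 2])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_model = ss_tot - ss_res
    df_res = n - p

    # partial SS of each single-df term: beta_j^2 / [(X'X)^-1]_jj
    xtx_inv = np.linalg.inv(X.T @ X)
    term_ss = {
        name: float(beta[j] ** 2 / xtx_inv[j, j])
        for j, name in enumerate(TERM_NAMES) if name != "intercept"
    }

    # pure error from replicate groups (identical factor settings)
    groups: dict[tuple[float, float, float], list[float]] = {}
    for row, yi in zip(c, y):
        groups.setdefault(tuple(np.round(row, 12)), []).append(yi)
    ss_pe, df_pe = 0.0, 0
    for vals in groups.values():
        if len(vals) > 1:
            v = np.asarray(vals)
            ss_pe += float(((v - v.mean()) ** 2).sum())
            df_pe += len(vals) - 1
    has_reps = df_pe > 0
    if not has_reps:
        warnings.warn("no replicated runs: lack-of-fit rows omitted",
                      stacklevel=2)

    ms_res = ss_res / df_res if df_res > 0 else np.nan

    def frow(source, df, ss, ms_denominator):
        ms = ss / df if df > 0 else np.nan
        if ms_denominator and ms_denominator > 0 and df > 0:
            F = ms / ms_denominator
            pval = float(stats.f.sf(F, df, frow.df_den))
        else:
            F, pval = np.nan, np.nan
        return {"source": source, "df": df, "sum_sq": ss,
                "mean_sq": ms, "F": F, "p": pval}

    rows = []
    frow.df_den = df_res
    rows.append(frow("model", p - 1, ss_model, ms_res))
    for name, ss in term_ss.items():
        rows.append(frow(name, 1, ss, ms_res))
    rows.append(frow("residual", df_res, ss_res, None))
    if has_reps:
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        ms_pe = ss_pe / df_pe
        frow.df_den = df_pe
        rows.append(frow("lack_of_fit", df_lof, ss_lof, ms_pe))
        rows.append(frow("pure_error", df_pe, ss_pe, None))
    rows.append(frow("total", n - 1, ss_tot, None))
    return pd.DataFrame(rows).set_index("source")


def center_replicate_stats(responses: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1) of center-point replicates."""
    v = np.asarray(list(responses), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two replicates")
    return float(v.mean()), float(v.std(ddof=1))


def optimize_contact_params(
    model: QuadraticModel,
    target_alpha: float,
    resolution: int = 200,
) -> OptimizationResult:
    """Factor triple on the box whose predicted angle best matches the target.

    Dense grid search (``resolution`` points per factor, evaluated in
    slices) followed by Nelder-Mead refinement clipped to the box.  When
    several grid points attain the optimum (the level set is a surface),
    the candidate closest to the box center is returned and the result is
    flagged non-unique.
    """
    (lo1, hi1), (lo2, hi2), (lo3, hi3) = model.bounds
    g1 = np.linspace(lo1, hi1, resolution)
    g2 = np.linspace(lo2, hi2, resolution)
    g3 = np.linspace(lo3, hi3, resolution)
    C2, C3 = np.meshgrid(g2, g3, indexing="ij")
    center = np.array([(lo1 + hi1) / 2, (lo2 + hi2) / 2, (lo3 + hi3) / 2])
    scale = np.array([hi1 - lo1, hi2 - lo2, hi3 - lo3])

    best_dev = np.inf
    best_point = center.copy()
    best_center_dist = np.inf
    pred_min, pred_max = np.inf, -np.inf
    tie_tol = 1e-9
    for v1 in g1:  # slice over c1 to bound memory
        pred = model.predict(v1, C2, C3)
        pred_min = min(pred_min, float(pred.min()))
        pred_max = max(pred_max, float(pred.max()))
        dev = np.abs(pred - target_alpha)
        m = float(dev.min())
        if m < best_dev - tie_tol:
            best_dev = m
            best_center_dist = np.inf
        if m <= best_dev + tie_tol:
            ii, jj = np.where(dev <= best_dev + tie_tol)
            pts = np.column_stack([
                np.full(ii.size, v1), C2[ii, jj], C3[ii, jj]
            ])
            d = np.linalg.norm((pts - center) / scale, axis=1)
            k = int(np.argmin(d))
            if d[k] < best_center_dist:
                best_center_dist = float(d[k])
                best_point = pts[k]

    def objective(x):
        x = np.clip(x, [lo1, lo2, lo3], [hi1, hi2, hi3])
        return abs(model.predict(*x) - target_alpha)

    res = optimize.minimize(objective, best_point, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    refined = np.clip(res.x, [lo1, lo2, lo3], [hi1, hi2, hi3])
    if objective(refined) <= best_dev:
        best_point = refined
        best_dev = float(objective(refined))

    achieved = model.predict(*best_point)
    on_boundary = best_dev > 1e-6
    if on_boundary:
        warnings.warn(
            f"target angle {target_alpha} not attainable on the factor box; "
            f"returning boundary best (deviation {best_dev:.4g})",
            stacklevel=2,
        )
    # a target attained strictly inside the prediction range lies on a
    # level *surface* of the quadratic: the solution is a manifold
    non_unique = (not on_boundary) and (pred_min < target_alpha < pred_max)
    return OptimizationResult(
        params=tuple(float(v) for v in best_point),
        achieved_alpha=float(achieved),
        deviation=float(best_dev),
        non_unique=non_unique,
        on_boundary=on_boundary,
    )


def relative_error(sim: float, exp: float) -> float:
    """Relative error 100*|sim - exp|/|exp| in percent, to 2 decimals."""
    if exp == 0:
        raise ValueError("experimental value must be nonzero")
    return round(100.0 * abs(sim - exp) / abs(exp), 2)
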