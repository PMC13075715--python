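"""Reduction of raw contact-parameter measurements to DEM coefficients.

Three bench tests feed the wheat / white-cast-iron contact calibration:

* inclined-plane slip: the tilt angle at which kernels start to slide gives
  the static friction coefficient mu = tan(angle), count-weighted because
  the rig records how many kernels slip at each angle;
* inclined-plane rolling: the distance a kernel rolls past the slope foot
  gives the rolling friction coefficient via an energy balance;
* rebound trajectory off a 45 degree plate: the horizontal landing distance
  together with drop and fall heights gives the restitution coefficient.

Summaries mirror the conventional reporting: per-group sample mean and SD
(n-1 denominator) and an unweighted mean of group means as the overall
value, rounded to three decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SlipRecord",
    "RollRecord",
    "ReboundRecord",
    "static_friction_from_slip",
    "rolling_friction",
    "restitution",
    "restitution_summary",
    "table1_summary",
]


@dataclass(frozen=True)
class SlipRecord:
    """Tilt angle (degrees) at slip and the number of kernels slipping."""

    tilt_angle_deg: float
    count: int = 1

    def __post_init__(self):
        if not 0.0 < self.tilt_angle_deg < 90.0:
            raise ValueError("tilt angle must lie in (0, 90) degrees")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class RollRecord:
    """Slope angle (deg), slope length and roll distance (both mm)."""

    slope_angle_deg: float
    slope_length_mm: float
    roll_distance_mm: float

    def __post_init__(self):
        if min(self.slope_angle_deg, self.slope_length_mm,
               self.roll_distance_mm) <= 0:
            raise ValueError("all RollRecord fields must be positive")


@dataclass(frozen=True)
class ReboundRecord:
    """Drop height h, fall height H and horizontal landing distance L1 (mm).

    h: release point to collision point (vertical); H: collision point to
    landing plane (vertical); L1: horizontal distance collision -> landing.
    """

    drop_height_mm: float
    fall_height_mm: float
    landing_distance_mm: float

    def __post_init__(self):
        if min(self.drop_height_mm, self.fall_height_mm) <= 0:
            raise ValueError("heights must be positive")
        if self.landing_distance_mm < 0:
            raise ValueError("landing distance must be nonnegative")


def static_friction_from_slip(
    records: Sequence[SlipRecord],
) -> tuple[float, float]:
    """Count-weighted mean and sample SD of mu = tan(slip angle).

    Weighting by the per-angle kernel count makes the result identical to
    pooling one record per kernel.
    """
    if not records:
        raise ValueError("need at least one slip record")
    mu = np.array([math.tan(math.radians(r.tilt_angle_deg)) for r in records])
    w = np.array([r.count for r in records], dtype=float)
    n = w.sum()
    mean = float(np.sum(w * mu) / n)
    if n > 1:
        sd = float(math.sqrt(np.sum(w * (mu - mean) ** 2) / (n - 1)))
    else:
        sd = 0.0
    return mean, sd


def rolling_friction(rec: RollRecord) -> float:
    """Rolling friction = l sin(theta) / (l cos(theta) + s).

    Energy balance of a kernel released on a slope of length l at angle
    theta that comes to rest a distance s past the slope foot.
    """
    th = math.radians(rec.slope_angle_deg)
    l, s = rec.slope_length_mm, rec.roll_distance_mm
    return l * math.sin(th) / (l * math.cos(th) + s)


def restitution(rec: ReboundRecord) -> float:
    """Restitution coefficient e1 = L1 / (2 sqrt(H h)).

    Projectile kinematics of the horizontal rebound off the 45 degree
    plate; the cos(45) factors of the full derivation cancel.
    """
    return rec.landing_distance_mm / (
        2.0 * math.sqrt(rec.fall_height_mm * rec.drop_height_mm)
    )


def restitution_summary(
    records: Sequence[ReboundRecord],
) -> tuple[float, float, int]:
    """Mean, sample SD and retained count of plausible restitution values.

    Records implying e1 > 1 are physically impossible for a passive
    collision and are excluded with a warning.
    """
    values = np.array([restitution(r) for r in records])
    keep = values <= 1.0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} rebound record(s) with implausible e1 > 1",
            stacklevel=2,
        )
    values = values[keep]
    if values.size == 0:
        raise ValueError("no plausible rebound records remain")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, int(values.size)


def table1_summary(
    groups: Iterable[Sequence[float]],
    pooled: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Per-group mean/SD and the overall coefficient for one contact test.

    ``groups`` holds per-kernel coefficient values, one sequence per test
    group.  The overall value is the unweighted mean of group means (the
    convention of the reference summaries), rounded to 3 decimals;
    ``pooled=True`` averages all kernels instead.
    """
    rows = []
    all_values: list[float] = []
    for i, g in enumerate(groups, start=1):
        g = np.asarray(list(g), dtype=float)
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
        rows.append({
            "group": i,
            "n": int(g.size),
            "mean": float(g.mean()),
            "sd": float(g.std(ddof=1)) if g.size > 1 else 0.0,
        })
        all_values.extend(g.tolist())
    if not rows:
        raise ValueError("need at least one group")
    table = pd.DataFrame(rows).set_index("group")
    if pooled:
        overall = float(np.mean(all_values))
    else:
        overall = float(table["mean"].mean())
    return table, round(overall, 3)
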