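"""Dormancy release in dry storage.

Two quantities: the thermal after-ripening time accumulated above a
lower-limit storage temperature (°C·hour), and the rate of widening of
the thermal niche (RWTN) — the storage hours needed per 1 °C rise of the
higher-limit temperature, obtained as the reciprocal of the slope from an
ordinary least-squares fit of Th50 against storage hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import f as f_dist

from .types import STORAGE_HOURS, InsufficientDataError

__all__ = ["StorageRegime", "RwtnFit", "thermal_afterripening_time", "fit_rwtn"]

#: Lower-limit storage temperature below which after-ripening does not
#: occur for this species.
DEFAULT_TSL = 5.0


@dataclass(frozen=True)
class StorageRegime:
    """Constant-temperature dry-storage treatment."""

    Ts: float
    Tsl: float = DEFAULT_TSL
    duration: float = 0.0  # hours

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("storage duration cannot be negative")


@dataclass(frozen=True)
class RwtnFit:
    """OLS fit of Th50 on storage hours, with RWTN = 1/slope."""

    a: float
    b: float
    se_b: float
    r2: float
    p_value: float
    rwtn: float
    n: int
    degenerate_slope: bool = False


def thermal_afterripening_time(regime: StorageRegime) -> float:
    """Thermal time (°C·hour) accumulated during a storage regime.

    ``max(0, Ts - Tsl) * duration``: no accumulation at or below the
    lower-limit storage temperature.
    """
    return max(0.0, regime.Ts - regime.Tsl) * regime.duration


def fit_rwtn(
    th50_by_stage: Mapping[str, float],
    stage_hours: Mapping[str, float] = STORAGE_HOURS,
) -> RwtnFit:
    """Regress Th50 on storage hours and derive the niche-widening rate.

    Only stages present in both mappings enter the fit.  The slope's
    standard error is ``sqrt((SSres / (n - 2)) / Sxx)`` and significance
    is a two-sided F test with (1, n - 2) degrees of freedom.  A flat
    line (|b| < 1e-12) yields ``rwtn = inf`` with a degenerate flag.
    """
    stages = [s for s in th50_by_stage if s in stage_hours]
    if len(stages) < 3:
        raise InsufficientDataError(f"need >= 3 stages with storage hours, got {len(stages)}")
    x = np.array([stage_hours[s] for s in stages], dtype=float)
    y = np.array([th50_by_stage[s] for s in stages], dtype=float)
    if np.unique(x).size < 3:
        raise InsufficientDataError("storage hours must be distinct for >= 3 stages")

    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    b = sxy / sxx
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    se_b = math.sqrt((ss_res / (n - 2)) / sxx)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if ss_res > 0:
        f_stat = (ss_tot - ss_res) / (ss_res / (n - 2))
        p = float(f_dist.sf(f_stat, 1, n - 2))
    else:
        p = 0.0
    degenerate = abs(b) < 1e-12
    rwtn = math.inf if degenerate else 1.0 / b
    return RwtnFit(a=a, b=b, se_b=se_b, r2=r2, p_value=p, rwtn=rwtn, n=n,
                   degenerate_slope=degenerate)
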