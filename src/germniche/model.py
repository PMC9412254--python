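"""Population-based threshold germination model.

The germinable fraction at temperature ``T`` is the probability mass of
seeds whose lower-limit threshold sits below ``T`` and whose higher-limit
threshold sits above it, both limits being normally distributed across the
population.  Within that window, germination timing follows normally
distributed thermal-time requirements accumulated above the base
temperature (sub-optimal range) or below the maximum temperature
(supra-optimal range).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.special import ndtr

from .types import CardinalTemps, InsufficientDataError, StageParams, ThermalWindow

__all__ = [
    "std_normal_cdf",
    "germinable_fraction",
    "accumulate_thermal_time",
    "cumulative_germination",
    "classify_dormancy_type",
]

ArrayLike = Union[float, np.ndarray]


def std_normal_cdf(z: ArrayLike) -> ArrayLike:
    """Standard normal CDF; rejects non-finite input."""
    arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("std_normal_cdf requires finite input")
    out = ndtr(arr)
    return float(out) if np.isscalar(z) or arr.ndim == 0 else out


def germinable_fraction(T: ArrayLike, window: ThermalWindow) -> ArrayLike:
    """Fraction of the population able to germinate at temperature ``T``.

    Computed as ``phi((T - Tl50)/sigma_Tl) - phi((T - Th50)/sigma_Th)``,
    clamped at zero.  The difference-of-CDFs form is algebraically the
    same as subtracting the upper-limit survival term from one; clamping
    only matters when the two threshold distributions overlap.
    """
    arr = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("temperature must be finite")
    gf = ndtr((arr - window.Tl50) / window.sigma_Tl) - ndtr((arr - window.Th50) / window.sigma_Th)
    gf = np.clip(gf, 0.0, 1.0)
    return float(gf) if np.isscalar(T) or arr.ndim == 0 else gf


def accumulate_thermal_time(
    T: float, t: ArrayLike, cardinals: CardinalTemps
) -> Tuple[str, ArrayLike]:
    """Thermal time accrued after ``t`` days at constant temperature ``T``.

    Returns ``("sub", max(0, T - Tb) * t)`` for temperatures at or below
    the optimum and ``("sup", max(0, Tm - T) * t)`` above it.  The tie at
    ``T == To`` goes to the sub-optimal branch.
    """
    tarr = np.asarray(t, dtype=float)
    if np.any(tarr < 0):
        raise ValueError("time must be non-negative")
    if T <= cardinals.To:
        label, rate = "sub", max(0.0, T - cardinals.Tb)
    else:
        label, rate = "sup", max(0.0, cardinals.Tm - T)
    theta = rate * tarr
    return label, (float(theta) if np.isscalar(t) or tarr.ndim == 0 else theta)


def cumulative_germination(T: float, t: ArrayLike, params: StageParams) -> ArrayLike:
    """Expected cumulative germinated fraction after ``t`` days at ``T``.

    The permissive-window layer and the timing layer are combined
    multiplicatively (independence assumption):
    ``GF(T) * phi((theta_acc(T, t) - theta50) / sigma_theta)`` with the
    sub- or supra-optimal thermal-time pair selected by the range of ``T``.
    """
    gf = germinable_fraction(T, params.window)
    label, theta = accumulate_thermal_time(T, t, params.cardinals)
    if label == "sub":
        t50, sd = params.timing.theta_sub50, params.timing.sigma_sub
    else:
        t50, sd = params.timing.theta_sup50, params.timing.sigma_sup
    frac = gf * ndtr((np.asarray(theta, dtype=float) - t50) / sd)
    return float(frac) if np.isscalar(t) or np.ndim(t) == 0 else frac


def _span(values: Sequence[float]) -> float:
    return values[-1] - values[0]


def classify_dormancy_type(stage_sequence: List[StageParams], tol: float = 1.0) -> str:
    """Classify the pattern of thermal-niche change across dormancy stages.

    ``Type1``: the higher limit rises while the lower limit stays put;
    ``Type2``: the lower limit falls while the higher limit stays put;
    ``Type3``: the window widens at both ends; ``none`` otherwise.
    Changes are measured from the first to the last stage and compared
    against ``tol`` (°C).
    """
    if len(stage_sequence) < 2:
        raise InsufficientDataError("need at least two stages to classify dormancy type")
    pops = {p.population for p in stage_sequence}
    if len(pops) > 1:
        raise ValueError(f"stages span multiple populations: {sorted(pops)}")
    d_low = _span([p.window.Tl50 for p in stage_sequence])
    d_high = _span([p.window.Th50 for p in stage_sequence])
    low_moves = d_low < -tol
    high_moves = d_high > tol
    if high_moves and abs(d_low) <= tol:
        return "Type1"
    if low_moves and abs(d_high) <= tol:
        return "Type2"
    if low_moves and high_moves:
        return "Type3"
    return "none"
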