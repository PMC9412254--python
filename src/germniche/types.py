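"""Core domain types for population-based threshold germination modelling.

All temperatures are degrees Celsius.  Thermal time during incubation is
accumulated in °C·day (censuses are daily); thermal time in dry storage is
accumulated in °C·hour (storage elapses over months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Recognised dormancy stages, in developmental order: immature (D),
#: mature (M), and after-ripened for 1, 2 and 5 months.
STAGES = ("D", "M", "AR1", "AR2", "AR5")

#: Dry-storage hours per stage used for the niche-widening regression.
#: Months are coded as 30 days x 24 h; the immature stage precedes storage
#: and is excluded.
STORAGE_HOURS = {"M": 0.0, "AR1": 720.0, "AR2": 1440.0, "AR5": 3600.0}

#: Storage-hour coding including the immature stage (harvested two weeks
#: before maturity), used only to order niche envelopes.
ENVELOPE_HOURS = {"D": -336.0, **STORAGE_HOURS}


class InsufficientDataError(ValueError):
    """Raised when an operation receives fewer observations than it needs."""


@dataclass(frozen=True)
class ThermalWindow:
    """Permissive temperature window of a seed population.

    ``Tl50``/``Th50`` are the mean lower- and higher-limit temperatures;
    half the population cannot germinate below/above them.  ``sigma_Tl``
    and ``sigma_Th`` are the normal spreads of the two limits.
    """

    Tl50: float
    sigma_Tl: float
    Th50: float
    sigma_Th: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.Tl50, self.sigma_Tl, self.Th50, self.sigma_Th])):
            raise ValueError("window parameters must be finite")
        if self.sigma_Tl <= 0 or self.sigma_Th <= 0:
            raise ValueError("window spreads must be strictly positive")
        if self.Tl50 >= self.Th50:
            raise ValueError(f"Tl50 ({self.Tl50}) must be below Th50 ({self.Th50})")


@dataclass(frozen=True)
class CardinalTemps:
    """Base, optimum and maximum temperatures, constant for a population."""

    Tb: float
    To: float
    Tm: float

    def __post_init__(self) -> None:
        if not (self.Tb < self.To < self.Tm):
            raise ValueError(f"require Tb < To < Tm, got {self.Tb}, {self.To}, {self.Tm}")


@dataclass(frozen=True)
class ThermalTimeParams:
    """Normally distributed thermal-time requirements (°C·day).

    ``theta_sub50``/``sigma_sub`` describe the sub-optimal range (above Tb);
    ``theta_sup50``/``sigma_sup`` the supra-optimal range (below Tm).
    """

    theta_sub50: float
    sigma_sub: float
    theta_sup50: float
    sigma_sup: float

    def __post_init__(self) -> None:
        vals = (self.theta_sub50, self.sigma_sub, self.theta_sup50, self.sigma_sup)
        if not all(np.isfinite(vals)) or any(v <= 0 for v in vals):
            raise ValueError("thermal-time parameters must be finite and strictly positive")


@dataclass(frozen=True)
class StageParams:
    """Fitted population parameters for one population at one dormancy stage."""

    population: str
    stage: str
    window: ThermalWindow
    timing: ThermalTimeParams
    cardinals: CardinalTemps
    r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")


@dataclass
class GerminationTimeCourse:
    """Cumulative germination of one dish at one incubation temperature."""

    temperature: float
    days: np.ndarray
    cum_fraction: np.ndarray
    n_seeds: int
    replicate: str
    population: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cum_fraction = np.asarray(self.cum_fraction, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.cum_fraction.shape:
            raise ValueError("days and cum_fraction must be 1-d arrays of equal length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValueError("census days must be strictly increasing")
        if np.any(self.cum_fraction < 0) or np.any(self.cum_fraction > 1):
            raise ValueError("cumulative fractions must lie in [0, 1]")
        if self.cum_fraction.size and np.any(np.diff(self.cum_fraction) < -1e-12):
            raise ValueError("cumulative fractions must be non-decreasing")

    @property
    def final_fraction(self) -> float:
        return float(self.cum_fraction[-1]) if self.cum_fraction.size else 0.0


@dataclass(frozen=True)
class ClimateSeries:
    """Long-term (e.g. 20-year) mean temperature per calendar month."""

    months: Sequence[int]
    mean_temp: Sequence[float]

    def __post_init__(self) -> None:
        months = tuple(int(m) for m in self.months)
        temps = tuple(float(t) for t in self.mean_temp)
        if len(months) != len(temps) or not 1 <= len(months) <= 12:
            raise ValueError("climate series needs 1-12 months with matching temperatures")
        if any(not 1 <= m <= 12 for m in months) or len(set(months)) != len(months):
            raise ValueError("months must be distinct labels in 1..12")
        if not all(np.isfinite(temps)):
            raise ValueError("mean temperatures must be finite")
        object.__setattr__(self, "months", months)
        object.__setattr__(self, "mean_temp", temps)

    def temp_of(self, month: int) -> float:
        return self.mean_temp[self.months.index(month)]
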