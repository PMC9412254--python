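"""Stage-parameter estimation from multi-temperature germination censuses.

Parameters of the threshold window and of the thermal-time distributions
are estimated jointly by minimising the RMSE between simulated and
observed cumulative germinated fractions, pooled over every daily census
of every dish at every usable temperature.  The optimiser is a bounded
local least-squares solver restarted from seeded Latin-hypercube points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import cumulative_germination
from .types import (
    CardinalTemps,
    GerminationTimeCourse,
    InsufficientDataError,
    StageParams,
    ThermalTimeParams,
    ThermalWindow,
)

__all__ = ["FitConfig", "FitResult", "rmse", "r_squared", "fit_stage", "drop_temperature"]

#: Incubation temperature at which no population germinates; removed from
#: both the model and the analysis.
EXCLUDED_TEMPERATURE = 30.0

#: Default box constraints, spanning all observed parameter magnitudes
#: with margin.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "Tl50": (0.0, 15.0),
    "sigma_Tl": (0.05, 15.0),
    "Th50": (10.0, 40.0),
    "sigma_Th": (0.05, 25.0),
    "theta_sub50": (1.0, 60.0),
    "sigma_sub": (0.1, 25.0),
    "theta_sup50": (1.0, 60.0),
    "sigma_sup": (0.1, 25.0),
}

_PARAM_ORDER = tuple(DEFAULT_BOUNDS)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser configuration: bounds, restarts, seed, convergence tol."""

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 8
    seed: int = 0
    tol: float = 1e-8
    fixed: Dict[str, float] = field(default_factory=dict)
    extra_starts: Tuple[Dict[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")


@dataclass(frozen=True)
class FitResult:
    params: StageParams
    rmse: float
    r2: Optional[float]
    n_obs: int
    converged: bool
    start_index: int
    start_objectives: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse cannot be negative")


def rmse(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length fraction vectors."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.size == 0:
        raise ValueError("observed and simulated must be non-empty and equal length")
    return float(np.sqrt(np.mean((obs - sim) ** 2)))


def r_squared(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SSres/SStot."""
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape or obs.size < 2:
        raise ValueError("need at least two paired observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; r_squared undefined")
    ss_res = float(np.sum((obs - sim) ** 2))
    return 1.0 - ss_res / ss_tot


def drop_temperature(
    timecourses: Sequence[GerminationTimeCourse], temperature: float = EXCLUDED_TEMPERATURE
) -> List[GerminationTimeCourse]:
    """Remove dishes incubated at ``temperature`` (default 30 °C)."""
    return [tc for tc in timecourses if tc.temperature != temperature]


def _vector_to_params(
    x: np.ndarray,
    free_names: Sequence[str],
    fixed: Dict[str, float],
    cardinals: CardinalTemps,
    population: str,
    stage: str,
) -> Optional[StageParams]:
    values = dict(fixed)
    values.update(zip(free_names, x))
    try:
        window = ThermalWindow(
            values["Tl50"], values["sigma_Tl"], values["Th50"], values["sigma_Th"]
        )
        timing = ThermalTimeParams(
            values["theta_sub50"], values["sigma_sub"],
            values["theta_sup50"], values["sigma_sup"],
        )
        return StageParams(population, stage, window, timing, cardinals)
    except ValueError:
        return None


def simulate_timecourses(
    params: StageParams, timecourses: Sequence[GerminationTimeCourse]
) -> np.ndarray:
    """Model-predicted cumulative fractions on each dish's census grid."""
    return np.concatenate(
        [np.atleast_1d(cumulative_germination(tc.temperature, tc.days, params))
         for tc in timecourses]
    )


def fit_stage(
    timecourses: Sequence[GerminationTimeCourse],
    cardinals: CardinalTemps,
    config: FitConfig = FitConfig(),
    population: str = "",
    stage: str = "M",
) -> FitResult:
    """Fit window and thermal-time parameters to one stage's censuses.

    Observations at the excluded temperature (30 °C) are dropped first;
    the remaining data must span at least three temperatures.  Dishes in
    which nothing germinated stay in the objective as zero-fraction
    observations.  When every observation is zero the data carry no
    usable signal and a non-converged result is returned instead of an
    arbitrary boundary solution.
    """
    data = drop_temperature(timecourses)
    temps = sorted({tc.temperature for tc in data})
    if len(temps) < 3:
        raise InsufficientDataError(
            f"need censuses at >= 3 temperatures after the 30 degC filter, got {len(temps)}"
        )
    if not population:
        population = next((tc.population for tc in data if tc.population), "")
    observed = np.concatenate([tc.cum_fraction for tc in data])

    # which thermal-time branch is exercised decides which pairs are free
    has_sub = any(t <= cardinals.To for t in temps)
    has_sup = any(t > cardinals.To for t in temps)
    free_names = [
        n for n in _PARAM_ORDER
        if n not in config.fixed
        and not (n in ("theta_sup50", "sigma_sup") and not has_sup)
        and not (n in ("theta_sub50", "sigma_sub") and not has_sub)
    ]
    lo = np.array([config.bounds[n][0] for n in free_names])
    hi = np.array([config.bounds[n][1] for n in free_names])
    fixed = dict(config.fixed)
    for name in _PARAM_ORDER:
        if name not in free_names and name not in fixed:
            fixed[name] = 0.5 * sum(config.bounds[name])  # inert branch placeholder

    def residuals(x: np.ndarray) -> np.ndarray:
        params = _vector_to_params(x, free_names, fixed, cardinals, population, stage)
        if params is None:
            return observed - (-1.0)  # invalid region: large constant misfit
        return observed - simulate_timecourses(params, data)

    degenerate = not np.any(observed > 0)

    sampler = qmc.LatinHypercube(d=len(free_names), seed=config.seed)
    starts = list(qmc.scale(sampler.random(config.n_starts), lo, hi))
    for extra in config.extra_starts:
        merged = {**fixed, **extra}
        starts.append(np.clip([merged[n] for n in free_names], lo, hi))

    best: Optional[Tuple[float, np.ndarray, int]] = None
    objectives: List[float] = []
    any_success = False
    for i, x0 in enumerate(starts):
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        if degenerate:
            objectives.append(float("nan"))
            continue
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            xtol=config.tol, ftol=config.tol, gtol=config.tol)
        obj = rmse(observed, observed - sol.fun)
        objectives.append(obj)
        any_success = any_success or sol.success
        if best is None or obj < best[0]:
            best = (obj, sol.x, i)
    if degenerate or best is None:
        x_fallback = np.clip(0.5 * (lo + hi), lo, hi)
        params = _vector_to_params(x_fallback, free_names, fixed, cardinals, population, stage)
        return FitResult(params, rmse(observed, np.zeros_like(observed)) if not degenerate else 0.0,
                         None, observed.size, False, -1, tuple(objectives))

    obj, x_best, idx = best
    params = _vector_to_params(x_best, free_names, fixed, cardinals, population, stage)
    simulated = simulate_timecourses(params, data)
    try:
        r2 = r_squared(observed, simulated)
    except ValueError:
        r2 = None
    if r2 is not None:
        params = dataclasses.replace(params, r2=max(0.0, min(1.0, r2)))
    return FitResult(params, obj, r2, observed.size, any_success, idx, tuple(objectives))
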