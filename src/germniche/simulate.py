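"""Synthetic germination censuses, Th50 trajectories and climate series.

The generators mirror the laboratory design — a temperature gradient,
replicate dishes of a fixed seed count, daily scoring — so that every
downstream estimator can be exercised and validated offline against a
known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .model import cumulative_germination
from .types import STORAGE_HOURS, ClimateSeries, GerminationTimeCourse, StageParams

__all__ = [
    "DesignSpec",
    "generate_timecourses",
    "generate_th50_trajectory",
    "generate_climate",
]


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design for one simulated germination trial."""

    temperatures: Tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    dishes: int = 3
    seeds_per_dish: int = 20
    census_days: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dishes < 1 or self.seeds_per_dish < 0 or self.census_days < 1:
            raise ValueError("design counts must be positive (seeds may be zero)")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ValueError("temperatures must be distinct")


def _rng(seed_or_rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_timecourses(
    truth: StageParams,
    design: DesignSpec,
    rng: Union[int, np.random.Generator, None] = None,
) -> List[GerminationTimeCourse]:
    """Draw binomial germination censuses from a known parameter truth.

    Daily increments are drawn sequentially from the conditional binomial
    given the seeds still ungerminated, so cumulative counts are monotone
    by construction — censuses are cumulative because germinated seeds
    are removed from the dish.  Deterministic given the seed.
    """
    gen = _rng(design.rng_seed if rng is None else rng)
    days = np.arange(1, design.census_days + 1, dtype=float)
    out: List[GerminationTimeCourse] = []
    for temp in design.temperatures:
        probs = np.clip(np.atleast_1d(cumulative_germination(temp, days, truth)), 0.0, 1.0)
        for dish in range(design.dishes):
            counts = np.zeros(days.size, dtype=int)
            done = 0
            p_prev = 0.0
            for i, p in enumerate(probs):
                remaining = design.seeds_per_dish - done
                if remaining > 0 and p > p_prev and p_prev < 1.0:
                    cond = min(1.0, (p - p_prev) / (1.0 - p_prev))
                    done += int(gen.binomial(remaining, cond))
                counts[i] = done
                p_prev = p
            frac = counts / design.seeds_per_dish if design.seeds_per_dish else counts * 0.0
            out.append(
                GerminationTimeCourse(
                    temperature=temp,
                    days=days.copy(),
                    cum_fraction=frac.astype(float),
                    n_seeds=design.seeds_per_dish,
                    replicate=f"d{dish + 1}",
                    population=truth.population,
                    stage=truth.stage,
                )
            )
    return out


def generate_th50_trajectory(
    th0: float,
    rate: float,
    stage_hours: Mapping[str, float] = STORAGE_HOURS,
    noise_sd: float = 0.0,
    rng_seed: Union[int, np.random.Generator, None] = 0,
) -> Dict[str, float]:
    """Th50 per stage along a linear widening trend with Gaussian noise."""
    if rate < 0:
        raise ValueError("widening rate cannot be negative")
    gen = _rng(rng_seed)
    return {
        stage: th0 + rate * hours + (gen.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for stage, hours in stage_hours.items()
    }


def generate_climate(
    amplitude: float,
    mean: float,
    phase_month: int,
    rng_seed: Union[int, np.random.Generator, None] = 0,
    noise_sd: float = 0.0,
) -> ClimateSeries:
    """Sinusoidal monthly mean temperatures, warmest at ``phase_month``."""
    if amplitude < 0:
        raise ValueError("amplitude cannot be negative")
    gen = _rng(rng_seed)
    months = list(range(1, 13))
    temps = [
        mean
        + amplitude * np.cos(2.0 * np.pi * (m - phase_month) / 12.0)
        + (gen.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for m in months
    ]
    return ClimateSeries(months=months, mean_temp=temps)
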