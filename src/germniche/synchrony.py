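"""Synchrony-of-germination (SOG) statistic.

SOG is the root-mean-square distance of simulated percentile-level values
from the mean of the observed data set: values are the (interpolated)
days at which each dish's cumulative germination first reaches each
percentile of a fixed grid.  Smaller SOG means more synchronous
germination.  An alternative paired reading — RMS of simulated-minus-
observed differences — sits behind ``mode="paired"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .fitting import drop_temperature
from .model import cumulative_germination
from .types import GerminationTimeCourse, StageParams

__all__ = ["SynchronyInput", "sog", "percentile_days", "stage_sog", "DEFAULT_PERCENTILES"]

DEFAULT_PERCENTILES: Tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))


@dataclass(frozen=True)
class SynchronyInput:
    """Matched simulated/observed values per percentile-and-replicate point."""

    simulated: Tuple[float, ...]
    observed: Tuple[float, ...]
    percentiles: Tuple[float, ...] = DEFAULT_PERCENTILES

    def __post_init__(self) -> None:
        sim = tuple(float(v) for v in self.simulated)
        obs = tuple(float(v) for v in self.observed)
        if len(sim) == 0 or len(sim) != len(obs):
            raise ValueError("simulated and observed must be non-empty and equal length")
        if any(not 0 < p < 1 for p in self.percentiles):
            raise ValueError("percentiles must lie strictly inside (0, 1)")
        object.__setattr__(self, "simulated", sim)
        object.__setattr__(self, "observed", obs)


def sog(data: SynchronyInput, mode: str = "mu") -> float:
    """Synchrony statistic for one population x stage.

    ``mode="mu"`` (default): sqrt(sum_i (Xs_i - mean(Xo))^2 / N).
    ``mode="paired"``: sqrt(sum_i (Xs_i - Xo_i)^2 / N).
    """
    xs = np.asarray(data.simulated, dtype=float)
    xo = np.asarray(data.observed, dtype=float)
    if mode == "mu":
        dev = xs - xo.mean()
    elif mode == "paired":
        dev = xs - xo
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'mu' or 'paired'")
    return float(np.sqrt(np.sum(dev**2) / xs.size))


def percentile_days(
    tc: GerminationTimeCourse, percentiles: Sequence[float] = DEFAULT_PERCENTILES
) -> np.ndarray:
    """Day at which cumulative germination first reaches each percentile.

    Linearly interpolated between censuses, with an implicit (day 0,
    fraction 0) origin; NaN for percentiles never reached.
    """
    days = tc.days
    frac = tc.cum_fraction
    if days.size == 0 or days[0] > 0:
        days = np.concatenate([[0.0], days])
        frac = np.concatenate([[0.0], frac])
    frac = np.maximum.accumulate(frac)  # guard float dips
    out = np.full(len(percentiles), np.nan)
    for i, p in enumerate(percentiles):
        idx = np.searchsorted(frac, p)
        if idx >= frac.size:
            continue  # never reached
        if idx == 0 or frac[idx] == frac[idx - 1]:
            out[i] = days[idx]
        else:
            w = (p - frac[idx - 1]) / (frac[idx] - frac[idx - 1])
            out[i] = days[idx - 1] + w * (days[idx] - days[idx - 1])
    return out


def stage_sog(
    timecourses: Sequence[GerminationTimeCourse],
    params: StageParams,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    mode: str = "mu",
) -> Optional[float]:
    """SOG for one stage from observed censuses and fitted parameters.

    Observed percentile days come from each dish; simulated ones from the
    model evaluated on the same census grid.  In ``mu`` mode every finite
    simulated point is compared against the mean of all finite observed
    points; in ``paired`` mode only points finite on both sides are kept.
    Returns None when no percentile is reached on the required side(s).
    """
    sim_vals: List[float] = []
    obs_vals: List[float] = []
    pairs: List[Tuple[float, float]] = []
    for tc in drop_temperature(timecourses):
        obs_d = percentile_days(tc, percentiles)
        model_tc = GerminationTimeCourse(
            temperature=tc.temperature,
            days=tc.days,
            cum_fraction=np.clip(
                np.atleast_1d(cumulative_germination(tc.temperature, tc.days, params)), 0, 1
            ),
            n_seeds=tc.n_seeds,
            replicate=tc.replicate,
        )
        sim_d = percentile_days(model_tc, percentiles)
        obs_vals.extend(obs_d[np.isfinite(obs_d)])
        sim_vals.extend(sim_d[np.isfinite(sim_d)])
        pairs.extend((s, o) for s, o in zip(sim_d, obs_d) if math.isfinite(s) and math.isfinite(o))

    if mode == "mu":
        if not sim_vals or not obs_vals:
            return None
        mu = float(np.mean(obs_vals))
        return float(np.sqrt(np.mean((np.asarray(sim_vals) - mu) ** 2)))
    if not pairs:
        return None
    sim, obs = zip(*pairs)
    return sog(SynchronyInput(sim, obs, tuple(percentiles)), mode="paired")
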