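"""Thermal-niche envelopes and germination-timing prediction.

The envelope stacks each stage's permissive window (Tl50..Th50) along the
after-ripening axis.  Germination timing is predicted by scanning forward
from seed maturity along a piecewise-linear interpolation of monthly mean
temperatures until the curve first enters the stage-appropriate window,
the stage advancing with elapsed storage hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import ENVELOPE_HOURS, ClimateSeries, InsufficientDataError, StageParams

__all__ = ["NicheEnvelope", "TimingPrediction", "build_envelope", "overlaps", "predict_timing"]

HOURS_PER_MONTH = 720.0  # 30-day months, matching the storage-hour coding


@dataclass(frozen=True)
class NicheEnvelope:
    """Stage-indexed lower/upper permissive temperature bounds."""

    population: str
    stages: Tuple[str, ...]
    hours: Tuple[float, ...]
    lower: Tuple[float, ...]
    upper: Tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.stages)
        if not (len(self.hours) == len(self.lower) == len(self.upper) == n):
            raise ValueError("stage, hour and bound sequences must align")
        if any(lo >= up for lo, up in zip(self.lower, self.upper)):
            raise ValueError("lower bound must be below upper bound at every stage")
        if any(h2 <= h1 for h1, h2 in zip(self.hours, self.hours[1:])):
            raise ValueError("stages must be strictly ordered by storage hours")

    def index_of(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise KeyError(f"stage {stage!r} not in envelope") from None

    def stage_at_elapsed(self, elapsed_hours: float) -> int:
        """Index of the stage in force after ``elapsed_hours`` of storage.

        Piecewise-constant and right-continuous: the latest stage whose
        storage hours do not exceed the elapsed time (the first stage
        before any threshold is reached).
        """
        idx = 0
        for i, h in enumerate(self.hours):
            if h <= elapsed_hours:
                idx = i
        return idx


@dataclass(frozen=True)
class TimingPrediction:
    predicted_temp: Optional[float]
    crossing_month: Optional[int]
    months_after_maturity: Optional[float]
    crossed: bool


def build_envelope(
    fits: Sequence[StageParams], stage_hours: Mapping[str, float] = ENVELOPE_HOURS
) -> NicheEnvelope:
    """Assemble a population's envelope from its fitted stage windows."""
    if len(fits) < 2:
        raise InsufficientDataError("need at least two stages to build an envelope")
    pops = {p.population for p in fits}
    if len(pops) > 1:
        raise ValueError(f"envelope cannot mix populations: {sorted(pops)}")
    missing = [p.stage for p in fits if p.stage not in stage_hours]
    if missing:
        raise ValueError(f"no storage hours for stages {missing}")
    ordered = sorted(fits, key=lambda p: stage_hours[p.stage])
    return NicheEnvelope(
        population=pops.pop(),
        stages=tuple(p.stage for p in ordered),
        hours=tuple(float(stage_hours[p.stage]) for p in ordered),
        lower=tuple(p.window.Tl50 for p in ordered),
        upper=tuple(p.window.Th50 for p in ordered),
    )


def overlaps(envelope: NicheEnvelope, stage: str, mean_temp: float) -> bool:
    """True iff ``mean_temp`` falls inside the stage's closed window."""
    i = envelope.index_of(stage)
    return envelope.lower[i] <= mean_temp <= envelope.upper[i]


def _climate_knots(climate: ClimateSeries, maturity_month: int, horizon: int = 13) -> Tuple[np.ndarray, np.ndarray]:
    """Cyclic monthly knots (months-after-maturity, temperature)."""
    if maturity_month not in climate.months:
        raise ValueError(f"maturity month {maturity_month} missing from climate series")
    if len(climate.months) != 12:
        raise ValueError("timing prediction needs a full 12-month climate series")
    taus = np.arange(horizon, dtype=float)
    temps = np.array(
        [climate.temp_of((maturity_month - 1 + int(k)) % 12 + 1) for k in taus]
    )
    return taus, temps


def predict_timing(
    envelope: NicheEnvelope, climate: ClimateSeries, maturity_month: int
) -> TimingPrediction:
    """First entry of the mean-temperature curve into the active window.

    Scans month segments forward from maturity.  Within each segment the
    temperature is linear in time and the envelope bounds are piecewise
    constant (the stage switches as storage hours accumulate), so the
    first crossing is found exactly: either the segment starts inside the
    window, or the line meets the violated bound and the predicted
    temperature equals that bound.
    """
    taus, temps = _climate_knots(climate, maturity_month)

    def bounds_at(tau: float) -> Tuple[float, float]:
        i = envelope.stage_at_elapsed(tau * HOURS_PER_MONTH)
        return envelope.lower[i], envelope.upper[i]

    # split month segments at stage-switch times so bounds are constant
    switch_taus = sorted(
        h / HOURS_PER_MONTH for h in envelope.hours if 0.0 < h / HOURS_PER_MONTH < 12.0
    )
    breakpoints = sorted(set([float(t) for t in taus[:-1]] + switch_taus + [12.0]))
    for t0, t1 in zip(breakpoints, breakpoints[1:]):
        if t1 > 12.0:
            break
        y0 = float(np.interp(t0, taus, temps))
        y1 = float(np.interp(t1, taus, temps))
        lo, up = bounds_at(t0)
        if lo <= y0 <= up:
            tau_star, temp_star = t0, y0
        else:
            bound = up if y0 > up else lo
            # need the line to reach the violated bound within (t0, t1]
            if y0 > up and y1 > up:
                continue
            if y0 < lo and y1 < lo:
                continue
            w = (bound - y0) / (y1 - y0)
            tau_star, temp_star = t0 + w * (t1 - t0), bound
        month = (maturity_month - 1 + int(np.floor(tau_star + 1e-12))) % 12 + 1
        return TimingPrediction(temp_star, month, tau_star, True)
    return TimingPrediction(None, None, None, False)
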