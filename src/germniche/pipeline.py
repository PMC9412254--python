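"""End-to-end analysis: fit stages, classify dormancy, quantify niche
widening and synchrony, and predict germination timing.

All randomness flows from the single configured seed, so two runs with
the same configuration produce identical outputs.
"""

from __future__ import annotations

import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import io
from .afterripening import fit_rwtn
from .fitting import FitConfig, FitResult, fit_stage
from .model import classify_dormancy_type
from .niche import NicheEnvelope, build_envelope, predict_timing
from .synchrony import stage_sog
from .types import (
    ENVELOPE_HOURS,
    STAGES,
    STORAGE_HOURS,
    CardinalTemps,
    GerminationTimeCourse,
    InsufficientDataError,
    StageParams,
)

log = logging.getLogger("germniche")


@dataclass
class PipelineConfig:
    counts_path: Path
    cardinals_path: Path
    out_dir: Path
    climate_path: Optional[Path] = None
    stage_hours: Mapping[str, float] = field(default_factory=lambda: dict(STORAGE_HOURS))
    sog_mode: str = "mu"
    seed: int = 0
    n_starts: int = 8
    maturity_month: int = 7
    make_figures: bool = True

    def __post_init__(self) -> None:
        hours = [self.stage_hours[s] for s in STAGES if s in self.stage_hours]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("stage hours must be strictly increasing along the stage order")


@dataclass
class PipelineReport:
    params: List[StageParams]
    fit_results: Dict[Tuple[str, str], FitResult]
    dormancy_types: Dict[str, str]
    rwtn: pd.DataFrame
    sog: pd.DataFrame
    timing: Optional[pd.DataFrame]
    envelopes: Dict[str, NicheEnvelope]
    out_dir: Path


def _group_by_pop_stage(
    timecourses: Sequence[GerminationTimeCourse],
) -> Dict[Tuple[str, str], List[GerminationTimeCourse]]:
    groups: Dict[Tuple[str, str], List[GerminationTimeCourse]] = defaultdict(list)
    for tc in timecourses:
        groups[(tc.population, tc.stage)].append(tc)
    return dict(groups)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out_dir = Path(config.out_dir)
    timecourses = io.read_counts(config.counts_path)
    cardinals = io.read_cardinals(config.cardinals_path)
    climate = io.read_climate(config.climate_path) if config.climate_path else None
    out_dir.mkdir(parents=True, exist_ok=True)

    groups = _group_by_pop_stage(timecourses)
    fit_results: Dict[Tuple[str, str], FitResult] = {}
    params: List[StageParams] = []
    sog_rows = []
    for (pop, stage) in sorted(groups):
        if pop not in cardinals:
            raise KeyError(f"stage {stage} of population {pop!r}: no cardinal temperatures")
        t0 = time.perf_counter()
        cfg = FitConfig(n_starts=config.n_starts, seed=config.seed)
        try:
            result = fit_stage(groups[(pop, stage)], cardinals[pop], cfg,
                               population=pop, stage=stage)
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"fitting {pop}/{stage}: {exc}") from exc
        fit_results[(pop, stage)] = result
        params.append(result.params)
        value = stage_sog(groups[(pop, stage)], result.params, mode=config.sog_mode)
        sog_rows.append({"population": pop, "stage": stage, "sog": value,
                         "mode": config.sog_mode})
        log.info("fitted %s/%s: rmse=%.4f converged=%s (%.1fs)",
                 pop, stage, result.rmse, result.converged, time.perf_counter() - t0)

    by_pop: Dict[str, List[StageParams]] = defaultdict(list)
    for p in params:
        by_pop[p.population].append(p)
    stage_order = {s: i for i, s in enumerate(STAGES)}
    dormancy_types = {}
    rwtn_rows = []
    envelopes = {}
    timing_rows = []
    for pop, plist in sorted(by_pop.items()):
        plist.sort(key=lambda p: stage_order[p.stage])
        if len(plist) >= 2:
            dormancy_types[pop] = classify_dormancy_type(plist)
        th50 = {p.stage: p.window.Th50 for p in plist}
        try:
            fit = fit_rwtn(th50, config.stage_hours)
            rwtn_rows.append({"population": pop, "a": fit.a, "b": fit.b, "se_b": fit.se_b,
                              "RWTN": fit.rwtn, "p_value": fit.p_value, "R2": fit.r2})
        except InsufficientDataError:
            log.warning("population %s: too few after-ripening stages for RWTN", pop)
        try:
            env = build_envelope(plist, {**ENVELOPE_HOURS, **config.stage_hours})
            envelopes[pop] = env
        except (InsufficientDataError, ValueError) as exc:
            log.warning("population %s: no envelope (%s)", pop, exc)
            continue
        if climate is not None:
            pred = predict_timing(env, climate, config.maturity_month)
            timing_rows.append({
                "population": pop,
                "predicted_temp_c": pred.predicted_temp,
                "crossing_month": pred.crossing_month,
                "months_after_maturity": pred.months_after_maturity,
                "crossed": pred.crossed,
            })

    io.write_params(params, out_dir / "params.csv")
    rwtn_df = pd.DataFrame(rwtn_rows, columns=["population", "a", "b", "se_b",
                                               "RWTN", "p_value", "R2"])
    rwtn_df.to_csv(out_dir / "rwtn.csv", index=False)
    sog_df = pd.DataFrame(sog_rows, columns=["population", "stage", "sog", "mode"])
    sog_df.to_csv(out_dir / "sog.csv", index=False)
    timing_df = None
    if climate is not None:
        timing_df = pd.DataFrame(timing_rows, columns=["population", "predicted_temp_c",
                                                       "crossing_month",
                                                       "months_after_maturity", "crossed"])
        timing_df.to_csv(out_dir / "timing.csv", index=False)
    pd.DataFrame(
        [{"population": pop, "dormancy_type": typ} for pop, typ in sorted(dormancy_types.items())]
    ).to_csv(out_dir / "dormancy_types.csv", index=False)

    if config.make_figures and envelopes:
        from .plotting import plot_envelopes

        fig = plot_envelopes(envelopes, climate)
        for ext in ("png", "svg"):
            fig.savefig(out_dir / f"niche.{ext}", dpi=150, bbox_inches="tight")

    return PipelineReport(params=params, fit_results=fit_results,
                          dormancy_types=dormancy_types, rwtn=rwtn_df, sog=sog_df,
                          timing=timing_df, envelopes=envelopes, out_dir=out_dir)
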