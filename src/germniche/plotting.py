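"""Niche-envelope figures: per-population permissive bands across
after-ripening stages, with long-term monthly means overlaid as squares."""

from __future__ import annotations

import math
from typing import Dict, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .niche import NicheEnvelope
from .types import ClimateSeries


def plot_envelopes(
    envelopes: Dict[str, NicheEnvelope], climate: Optional[ClimateSeries] = None
):
    """One panel per population: the Tl50..Th50 band along storage hours."""
    n = len(envelopes)
    ncols = min(3, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False, sharey=True)
    for ax, (pop, env) in zip(axes.flat, sorted(envelopes.items())):
        hours = [h / 720.0 for h in env.hours]  # months of storage
        ax.fill_between(hours, env.lower, env.upper, alpha=0.3, color="tab:green",
                        label="thermal niche")
        ax.plot(hours, env.upper, "-o", color="tab:green", ms=3)
        ax.plot(hours, env.lower, "-o", color="tab:olive", ms=3)
        if climate is not None:
            lo, hi = min(hours), max(hours)
            xs = [lo + (hi - lo) * i / 11.0 for i in range(12)]
            ax.plot(xs, climate.mean_temp, "s", color="black", ms=4,
                    label="monthly mean")
        ax.set_title(pop)
        ax.set_xlabel("storage (months)")
        ax.set_ylabel("temperature (degC)")
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    handles, labels = axes.flat[0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="lower right")
    fig.tight_layout()
    return fig
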