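from __future__ import annotations

import numpy as np
import pytest

import germniche as g
from germniche.io import load_table1

#: Cardinal temperatures used for synthetic studies; the sub-optimal
#: branch covers the whole 5-25 degC test gradient.
DEFAULT_CARDINALS = g.CardinalTemps(Tb=0.0, To=25.0, Tm=36.0)


def stage_params_from_table1(population: str, stage: str,
                             cardinals: g.CardinalTemps = DEFAULT_CARDINALS) -> g.StageParams:
    t1 = load_table1()
    row = t1[(t1.population == population) & (t1.stage == stage)].iloc[0]
    return g.StageParams(
        population=population,
        stage=stage,
        window=g.ThermalWindow(row.Tl50, row.sigma_Tl, row.Th50, row.sigma_Th),
        timing=g.ThermalTimeParams(row.theta_sub50, row.sigma_sub,
                                   row.theta_sup50, row.sigma_sup),
        cardinals=cardinals,
        r2=float(row.R2),
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def cardinals():
    return DEFAULT_CARDINALS


@pytest.fixture(scope="session")
def arak_ar5(cardinals):
    return stage_params_from_table1("Arak", "AR5", cardinals)


@pytest.fixture(scope="session")
def bajestan_recovery(cardinals):
    """Fitted Th50 across 50 seeded synthetic replicates of an
    identifiable truth (Bajestan M: Th50 well inside the 5-25 gradient).
    Shared by the estimator-bias and generator-roundtrip tests."""
    truth = stage_params_from_table1("Bajestan", "M", cardinals)
    estimates = []
    for seed in range(50):
        tcs = g.generate_timecourses(truth, g.DesignSpec(rng_seed=seed))
        res = g.fit_stage(tcs, cardinals, g.FitConfig(n_starts=6, seed=seed),
                          population="Bajestan", stage="M")
        estimates.append(res.params.window.Th50)
    return truth, np.array(estimates)


@pytest.fixture()
def cardinals_yaml(tmp_path):
    def _write(populations, Tb=0.0, To=25.0, Tm=36.0):
        path = tmp_path / "cardinals.yaml"
        lines = [f"{pop}: {{Tb: {Tb}, To: {To}, Tm: {Tm}}}" for pop in populations]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
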