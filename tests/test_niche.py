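import numpy as np
import pytest

import germniche as g
from germniche.niche import build_envelope, overlaps, predict_timing
from germniche.types import ENVELOPE_HOURS

from conftest import stage_params_from_table1


@pytest.fixture()
def arak_envelope(cardinals):
    fits = [stage_params_from_table1("Arak", s, cardinals) for s in g.STAGES]
    return build_envelope(fits)


def flat_envelope(lower, upper, population="p"):
    return g.NicheEnvelope(population=population, stages=("M", "AR1"),
                           hours=(0.0, 720.0), lower=(lower, lower), upper=(upper, upper))


class TestBuildEnvelope:
    def test_arak_bounds(self, arak_envelope):
        assert arak_envelope.stages == ("D", "M", "AR1", "AR2", "AR5")
        assert arak_envelope.lower == pytest.approx((6.6,) * 5)
        assert arak_envelope.upper == pytest.approx((19.3, 23, 26, 32, 35))

    def test_single_stage_rejected(self, cardinals):
        with pytest.raises(g.InsufficientDataError):
            build_envelope([stage_params_from_table1("Arak", "M", cardinals)])

    def test_mixed_population_rejected(self, cardinals):
        fits = [stage_params_from_table1("Arak", "M", cardinals),
                stage_params_from_table1("Zabol", "AR5", cardinals)]
        with pytest.raises(ValueError):
            build_envelope(fits)

    def test_width_nondecreasing_for_all_published_populations(self, table1, cardinals):
        for pop in table1.population.unique():
            env = build_envelope([stage_params_from_table1(pop, s, cardinals)
                                  for s in g.STAGES])
            widths = np.array(env.upper) - np.array(env.lower)
            assert np.all(np.diff(widths) >= -1e-12), pop


class TestOverlaps:
    def test_closed_lower_bound(self, arak_envelope):
        assert overlaps(arak_envelope, "M", 6.6)

    def test_above_upper(self, arak_envelope):
        assert not overlaps(arak_envelope, "M", 28.0)

    def test_unknown_stage(self, arak_envelope):
        with pytest.raises(KeyError):
            overlaps(arak_envelope, "AR9", 15.0)

    def test_monotone_in_envelope_width(self):
        temp = 26.0
        narrow = flat_envelope(10, 25)
        wide = flat_envelope(9, 27)
        assert not overlaps(narrow, "M", temp)
        assert overlaps(wide, "M", temp)
        for t in np.linspace(-5, 40, 91):
            if overlaps(narrow, "M", t):
                assert overlaps(wide, "M", t)


class TestStageSelection:
    def test_right_continuous_piecewise_constant(self, arak_envelope):
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(0.0)] == "M"
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(719.9)] == "M"
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(720.0)] == "AR1"
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(1440.0)] == "AR2"
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(3599.0)] == "AR2"
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(3600.0)] == "AR5"
        assert arak_envelope.stages[arak_envelope.stage_at_elapsed(99999.0)] == "AR5"


class TestPredictTiming:
    def test_inside_at_maturity(self):
        env = flat_envelope(0, 40)
        climate = g.generate_climate(amplitude=10, mean=18, phase_month=7)
        pred = predict_timing(env, climate, maturity_month=7)
        assert pred.crossed
        assert pred.crossing_month == 7
        assert pred.predicted_temp == pytest.approx(28.0)
        assert pred.months_after_maturity == 0.0

    def test_linear_interpolation_hits_bound_exactly(self):
        env = flat_envelope(0, 25)
        temps = {9: 28.0, 10: 22.0}
        series = g.ClimateSeries(months=list(range(1, 13)),
                                 mean_temp=[temps.get(m, 30.0) for m in range(1, 13)])
        pred = predict_timing(env, series, maturity_month=9)
        assert pred.crossed
        assert pred.predicted_temp == pytest.approx(25.0)
        assert pred.crossing_month == 9
        assert pred.months_after_maturity == pytest.approx(0.5)

    def test_no_crossing_flagged(self):
        env = flat_envelope(0, 10)
        climate = g.generate_climate(amplitude=2, mean=25, phase_month=7)
        pred = predict_timing(env, climate, maturity_month=7)
        assert not pred.crossed
        assert pred.predicted_temp is None

    def test_wider_envelope_crosses_no_later(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            mean = rng.uniform(15, 25)
            amp = rng.uniform(5, 15)
            climate = g.generate_climate(amplitude=amp, mean=mean, phase_month=7)
            narrow = flat_envelope(5, 20)
            wide = flat_envelope(4, 24)
            p_narrow = predict_timing(narrow, climate, maturity_month=7)
            p_wide = predict_timing(wide, climate, maturity_month=7)
            if p_narrow.crossed:
                assert p_wide.crossed
                assert p_wide.months_after_maturity <= p_narrow.months_after_maturity + 1e-9

    def test_translation_consistency(self, cardinals):
        fits = [stage_params_from_table1("Zabol", s, cardinals) for s in g.STAGES]
        env = build_envelope(fits)
        climate = g.generate_climate(amplitude=12, mean=18, phase_month=7)
        base = predict_timing(env, climate, maturity_month=7)
        c = 3.7
        shifted_env = g.NicheEnvelope(env.population, env.stages, env.hours,
                                      tuple(v + c for v in env.lower),
                                      tuple(v + c for v in env.upper))
        shifted_climate = g.ClimateSeries(climate.months,
                                          tuple(t + c for t in climate.mean_temp))
        shifted = predict_timing(shifted_env, shifted_climate, maturity_month=7)
        assert shifted.crossed == base.crossed
        if base.crossed:
            assert shifted.crossing_month == base.crossing_month
            assert shifted.months_after_maturity == pytest.approx(base.months_after_maturity)
            assert shifted.predicted_temp == pytest.approx(base.predicted_temp + c)

    def test_sinusoid_crossing_bracketed_analytically(self):
        # warm sinusoid relaxing through 25 degC: crossing must fall in the
        # segment whose endpoints bracket the bound
        env = flat_envelope(0, 25)
        climate = g.generate_climate(amplitude=12, mean=18, phase_month=7)
        pred = predict_timing(env, climate, maturity_month=7)
        assert pred.crossed
        assert pred.predicted_temp == pytest.approx(25.0)
        temps = [climate.temp_of((7 - 1 + k) % 12 + 1) for k in range(13)]
        k = int(np.floor(pred.months_after_maturity))
        assert temps[k] >= 25.0 >= temps[k + 1]
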