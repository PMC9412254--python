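import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germniche as g
from germniche.model import classify_dormancy_type

from conftest import DEFAULT_CARDINALS, stage_params_from_table1


def erf_cdf(z: float) -> float:
    """Independent high-precision normal-CDF oracle."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestStdNormalCdf:
    def test_symmetry_at_zero(self):
        assert g.std_normal_cdf(0.0) == pytest.approx(0.5, abs=1e-15)

    def test_tail_limit(self):
        assert g.std_normal_cdf(10.0) == pytest.approx(1.0, abs=1e-12)

    def test_against_erf_oracle(self):
        assert g.std_normal_cdf(1.0) == pytest.approx(erf_cdf(1.0), abs=1e-12)
        assert g.std_normal_cdf(1.0) == pytest.approx(0.841345, abs=1e-6)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_rejects_nonfinite(self, bad):
        with pytest.raises(ValueError):
            g.std_normal_cdf(bad)

    @given(st.floats(-8, 8), st.floats(-8, 8))
    def test_monotone(self, z1, z2):
        lo, hi = sorted([z1, z2])
        assert g.std_normal_cdf(lo) <= g.std_normal_cdf(hi)


class TestGerminableFraction:
    def test_saturated_window(self):
        w = g.ThermalWindow(10, 1, 30, 1)
        assert g.germinable_fraction(20, w) == pytest.approx(1.0, abs=1e-9)

    def test_median_of_lower_limit(self):
        w = g.ThermalWindow(10, 2, 60, 2)
        assert g.germinable_fraction(10, w) == pytest.approx(0.5, abs=1e-9)

    def test_arak_ar5_at_33(self, arak_ar5):
        # phi(13.2) - phi(-1) from the published stage parameters
        assert g.germinable_fraction(33, arak_ar5.window) == pytest.approx(0.8413, abs=1e-3)

    def test_vanishes_in_far_tails(self):
        w = g.ThermalWindow(8, 2, 28, 3)
        assert g.germinable_fraction(w.Tl50 - 10 * w.sigma_Tl, w) == pytest.approx(0.0, abs=1e-9)
        assert g.germinable_fraction(w.Th50 + 10 * w.sigma_Th, w) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            g.ThermalWindow(20, 2, 10, 2)
        with pytest.raises(ValueError):
            g.ThermalWindow(5, -1, 25, 2)

    @given(
        T=st.floats(-10, 45),
        tl=st.floats(0, 14),
        stl=st.floats(0.1, 10),
        th=st.floats(15, 40),
        sth=st.floats(0.1, 10),
        delta=st.floats(0.0, 5.0),
    )
    @settings(max_examples=100)
    def test_bounded_and_monotone_in_limits(self, T, tl, stl, th, sth, delta):
        w = g.ThermalWindow(tl, stl, th, sth)
        gf = g.germinable_fraction(T, w)
        assert 0.0 <= gf <= 1.0
        wider_hi = g.ThermalWindow(tl, stl, th + delta, sth)
        wider_lo = g.ThermalWindow(tl - delta, stl, th, sth)
        assert g.germinable_fraction(T, wider_hi) >= gf - 1e-12
        assert g.germinable_fraction(T, wider_lo) >= gf - 1e-12


class TestAccumulateThermalTime:
    def test_zero_at_base(self):
        label, theta = g.accumulate_thermal_time(DEFAULT_CARDINALS.Tb, 7.0, DEFAULT_CARDINALS)
        assert (label, theta) == ("sub", 0.0)

    def test_suboptimal_rate(self):
        card = g.CardinalTemps(5, 25, 35)
        label, theta = g.accumulate_thermal_time(15, 3.0, card)
        assert (label, theta) == ("sub", 30.0)

    def test_supraoptimal_rate(self):
        card = g.CardinalTemps(5, 25, 35)
        label, theta = g.accumulate_thermal_time(30, 2.0, card)
        assert (label, theta) == ("sup", 10.0)

    def test_tie_break_at_optimum(self):
        card = g.CardinalTemps(5, 25, 35)
        assert g.accumulate_thermal_time(25, 1.0, card)[0] == "sub"

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            g.accumulate_thermal_time(15, -1.0, DEFAULT_CARDINALS)


class TestCumulativeGermination:
    def test_zero_time(self, arak_ar5):
        assert g.cumulative_germination(15, 0.0, arak_ar5) <= 0.01

    def test_saturates_to_germinable_fraction(self, arak_ar5):
        gf = g.germinable_fraction(15, arak_ar5.window)
        assert g.cumulative_germination(15, 1e6, arak_ar5) == pytest.approx(gf, abs=1e-9)

    def test_hand_evaluated_arak_ar5(self):
        # Tb = 6.6 from configuration; theta accrues at (15 - 6.6) per day
        card = g.CardinalTemps(6.6, 25.0, 36.0)
        p = stage_params_from_table1("Arak", "AR5", card)
        expected = (erf_cdf((15 - 6.6) / 2) - erf_cdf((15 - 35) / 2)) * erf_cdf(
            ((15 - 6.6) * 3 - 15) / 4.4
        )
        assert g.cumulative_germination(15, 3.0, p) == pytest.approx(expected, abs=1e-12)

    @given(
        T=st.floats(1, 30),
        t1=st.floats(0, 40),
        t2=st.floats(0, 40),
        th=st.floats(15, 40),
        sth=st.floats(0.1, 10),
        theta=st.floats(1, 50),
        sigma=st.floats(0.5, 20),
    )
    @settings(max_examples=200)
    def test_monotone_in_time_and_bounded(self, T, t1, t2, th, sth, theta, sigma):
        p = g.StageParams(
            "x", "M",
            g.ThermalWindow(5, 3, th, sth),
            g.ThermalTimeParams(theta, sigma, theta, sigma),
            g.CardinalTemps(0, 25, 36),
        )
        lo, hi = sorted([t1, t2])
        c_lo, c_hi = g.cumulative_germination(T, lo, p), g.cumulative_germination(T, hi, p)
        assert c_lo <= c_hi + 1e-12
        assert c_hi <= g.germinable_fraction(T, p.window) + 1e-12


class TestClassifyDormancyType:
    def _seq(self, pairs):
        return [
            g.StageParams(
                "p", stage,
                g.ThermalWindow(tl, 2, th, 2),
                g.ThermalTimeParams(15, 4, 15, 4),
                DEFAULT_CARDINALS,
            )
            for stage, tl, th in pairs
        ]

    def test_arak_is_type1(self, table1, cardinals):
        seq = [stage_params_from_table1("Arak", s, cardinals) for s in g.STAGES]
        assert classify_dormancy_type(seq) == "Type1"

    def test_identical_windows_none(self):
        seq = self._seq([("M", 5, 25), ("AR1", 5, 25), ("AR5", 5, 25)])
        assert classify_dormancy_type(seq) == "none"

    def test_type2(self):
        seq = self._seq([("M", 12, 30), ("AR1", 9, 30), ("AR5", 6, 30)])
        assert classify_dormancy_type(seq) == "Type2"

    def test_type3(self):
        seq = self._seq([("M", 12, 20), ("AR5", 6, 30)])
        assert classify_dormancy_type(seq) == "Type3"

    def test_single_stage_rejected(self):
        with pytest.raises(g.InsufficientDataError):
            classify_dormancy_type(self._seq([("M", 5, 25)]))

    def test_mixed_populations_rejected(self):
        seq = self._seq([("M", 5, 25), ("AR5", 5, 30)])
        seq[1] = g.StageParams("other", "AR5", seq[1].window, seq[1].timing, seq[1].cardinals)
        with pytest.raises(ValueError):
            classify_dormancy_type(seq)
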