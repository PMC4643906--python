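"""Closed-form velocity and response equations: identities and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import inhibkin as ik
from inhibkin.kinetic_models import InvalidParameterError

pos = st.floats(min_value=1e-3, max_value=1e3)


class TestMMVelocity:
    @pytest.mark.parametrize(
        "S, Km, Vmax, expected",
        [
            (1.0, 1.0, 1.0, 0.5),  # half saturation at S = Km
            (2.0, 2.0, 7.0, 3.5),
            (0.0, 1.5, 1.0, 0.0),  # blank well
            (1e9, 1.0, 1.0, pytest.approx(1.0, rel=1e-6)),  # saturating limit
        ],
    )
    def test_identities(self, S, Km, Vmax, expected):
        assert ik.mm_velocity(S, ik.MMParameters(Km=Km, Vmax=Vmax)) == pytest.approx(
            expected
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ik.MMParameters(Km=-1.0, Vmax=1.0)
        with pytest.raises(InvalidParameterError):
            ik.MMParameters(Km=1.0, Vmax=0.0)
        with pytest.raises(InvalidParameterError):
            ik.mm_velocity(-0.1, ik.MMParameters(Km=1.0, Vmax=1.0))


class TestMixedInhibition:
    def test_hand_substitution(self):
        # Vmax=1, Km=1, S=1, Ki=1, alpha=2, I=1:
        # Vmax_app = 1/(1+1/2) = 2/3, Km_app = 1*(1+1)/(1+1/2) = 4/3
        # v = (2/3)/(1 + 4/3) = 2/7
        v = ik.mixed_inhibition_velocity(
            1.0, 1.0, ik.MMParameters(Km=1, Vmax=1), ik.InhibitionParameters(Ki=1, alpha=2)
        )
        assert v == pytest.approx(2.0 / 7.0, rel=1e-12)

    @given(S=pos, Km=pos, Vmax=pos)
    def test_zero_inhibitor_reduces_to_mm(self, S, Km, Vmax):
        p = ik.MMParameters(Km=Km, Vmax=Vmax)
        q = ik.InhibitionParameters(Ki=0.8, alpha=3.2)
        assert ik.mixed_inhibition_velocity(S, 0.0, p, q) == pytest.approx(
            ik.mm_velocity(S, p), rel=1e-12
        )

    @given(S=pos, I=pos, Km=pos, Ki=pos)
    def test_large_alpha_matches_competitive(self, S, I, Km, Ki):
        p = ik.MMParameters(Km=Km, Vmax=1.0)
        q = ik.InhibitionParameters(Ki=Ki, alpha=1e9)
        v_mixed = ik.mixed_inhibition_velocity(S, I, p, q)
        v_comp = ik.competitive_velocity(S, I, p, Ki)
        assert v_mixed == pytest.approx(v_comp, rel=1e-6)

    def test_competitive_mode_delegates(self, mm):
        q = ik.InhibitionParameters(Ki=0.8, mode="competitive")
        assert ik.mixed_inhibition_velocity(1.0, 1.0, mm, q) == pytest.approx(
            ik.competitive_velocity(1.0, 1.0, mm, 0.8), rel=1e-15
        )

    @given(
        S=pos, Km=pos, Ki=pos, alpha=st.floats(min_value=0.1, max_value=100.0),
        I1=st.floats(min_value=0, max_value=100), dI=st.floats(min_value=1e-3, max_value=100),
    )
    def test_strictly_decreasing_in_inhibitor(self, S, Km, Ki, alpha, I1, dI):
        p = ik.MMParameters(Km=Km, Vmax=1.0)
        q = ik.InhibitionParameters(Ki=Ki, alpha=alpha)
        assert ik.mixed_inhibition_velocity(S, I1 + dI, p, q) < ik.mixed_inhibition_velocity(
            S, I1, p, q
        )

    @given(
        S=pos, Km=pos, Ki=pos, alpha=st.floats(min_value=0.1, max_value=100.0),
        I=st.floats(min_value=0, max_value=100), dS=st.floats(min_value=1e-3, max_value=100),
    )
    def test_strictly_increasing_in_substrate(self, S, Km, Ki, alpha, I, dS):
        p = ik.MMParameters(Km=Km, Vmax=1.0)
        q = ik.InhibitionParameters(Ki=Ki, alpha=alpha)
        assert ik.mixed_inhibition_velocity(S + dS, I, p, q) > ik.mixed_inhibition_velocity(
            S, I, p, q
        )


class TestCompetitiveVelocity:
    def test_at_km_and_ki(self, mm):
        # S=Km and I=Ki: v = Vmax/(1 + 1*(1+1)) = Vmax/3
        assert ik.competitive_velocity(mm.Km, 0.8, mm, 0.8) == pytest.approx(
            mm.Vmax / 3.0, rel=1e-12
        )

    def test_saturating_inhibitor_kills_activity(self, mm):
        assert ik.competitive_velocity(1.0, 1e12, mm, 0.8) == pytest.approx(0.0, abs=1e-9)


class TestDixonLine:
    def test_hand_coefficients_competitive_limit(self):
        p = ik.MMParameters(Km=1.0, Vmax=1.0)
        q = ik.InhibitionParameters(Ki=1.0, mode="competitive")
        slope, intercept = ik.dixon_line_coefficients(1.0, p, q)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(2.0)

    @given(
        S1=pos, S2=pos, Km=pos, Vmax=pos, Ki=pos,
        alpha=st.floats(min_value=0.1, max_value=1e3),
    )
    def test_lines_intersect_at_minus_ki(self, S1, S2, Km, Vmax, Ki, alpha):
        if abs(S1 - S2) < 1e-6 * max(S1, S2):
            return  # identical substrate levels give one line, not two
        p = ik.MMParameters(Km=Km, Vmax=Vmax)
        q = ik.InhibitionParameters(Ki=Ki, alpha=alpha)
        m1, b1 = ik.dixon_line_coefficients(S1, p, q)
        m2, b2 = ik.dixon_line_coefficients(S2, p, q)
        x = (b2 - b1) / (m1 - m2)
        y = m1 * x + b1
        assert x == pytest.approx(-Ki, rel=1e-8)
        assert y == pytest.approx((1 - 1 / alpha) / Vmax, rel=1e-6, abs=1e-12)

    @given(S=pos, I=st.floats(min_value=0, max_value=50), Ki=pos,
           alpha=st.floats(min_value=0.1, max_value=100.0))
    def test_reciprocal_velocity_is_exactly_linear_in_inhibitor(self, S, I, Ki, alpha):
        p = ik.MMParameters(Km=1.5, Vmax=1.0)
        q = ik.InhibitionParameters(Ki=Ki, alpha=alpha)
        slope, intercept = ik.dixon_line_coefficients(S, p, q)
        v = ik.mixed_inhibition_velocity(S, I, p, q)
        assert 1.0 / v == pytest.approx(slope * I + intercept, rel=1e-10)


class TestFourPL:
    def test_midpoint_at_ic50(self, potency_613):
        conc_M = ik.pic50_to_ic50_uM(6.13) * 1e-6
        assert ik.four_pl_response(math.log10(conc_M), potency_613) == pytest.approx(50.0)

    def test_hand_value_ten_times_ic50(self):
        p = ik.PotencyParameters(pIC50=6.0, hill_slope=1.0)
        assert ik.four_pl_response(math.log10(10e-6), p) == pytest.approx(100.0 / 11.0)

    def test_zero_concentration_limit_is_top(self, potency_613):
        assert ik.four_pl_response(-30.0, potency_613) == pytest.approx(100.0)

    def test_top_must_exceed_bottom(self):
        with pytest.raises(InvalidParameterError):
            ik.PotencyParameters(pIC50=6.0, top=50.0, bottom=60.0)

    @given(x1=st.floats(min_value=-9, max_value=-3), dx=st.floats(min_value=1e-3, max_value=3))
    def test_monotone_decreasing_in_concentration(self, x1, dx):
        p = ik.PotencyParameters(pIC50=6.13, hill_slope=1.0)
        assert ik.four_pl_response(x1 + dx, p) < ik.four_pl_response(x1, p)


class TestPotencyConversion:
    @pytest.mark.parametrize(
        "pic50, ic50_uM",
        [
            (6.13, 0.74),  # (R)-Flu-AM1, rat
            (5.25, 5.7),   # (R)-Ibu-AM5, rat
            (6.23, 0.59),  # (S)-Ibu-AM5, rat
            (4.17, 68.0),  # ibufenac-AM1
            (5.92, 1.2),   # racemic Ibu-AM5
            (6.00, 1.0),
            (5.08, 8.3),   # wild-type lysate
            (4.43, 37.0),  # carprofen, wild-type lysate
        ],
    )
    def test_published_potency_pairs_are_consistent(self, pic50, ic50_uM):
        # pI50s rounded to two decimals carry a ±1.2% relative wobble on the
        # implied IC50 (ln10 * 0.005), so agree to 2%
        assert ik.pic50_to_ic50_uM(pic50) == pytest.approx(ic50_uM, rel=0.02)

    @given(pic50=st.floats(min_value=2.0, max_value=10.0))
    def test_round_trip(self, pic50):
        assert ik.ic50_uM_to_pic50(ik.pic50_to_ic50_uM(pic50)) == pytest.approx(
            pic50, rel=1e-12
        )

    def test_nonpositive_ic50_rejected(self):
        with pytest.raises(InvalidParameterError):
            ik.ic50_uM_to_pic50(0.0)


class TestTwoInhibitorVelocity:
    def test_exclusive_slope_independent_of_second_inhibitor(self, mm):
        # 1/v is linear in I1 with slope (Km/S)/(Vmax*K1) regardless of I2
        S, K1, K2 = 0.5, 0.8, 30.0
        for I2 in (0.0, 15.0, 60.0):
            v1 = ik.two_inhibitor_velocity(S, 1.0, I2, mm, K1, K2)
            v0 = ik.two_inhibitor_velocity(S, 0.0, I2, mm, K1, K2)
            slope = (1 / v1 - 1 / v0) / 1.0
            assert slope == pytest.approx((mm.Km / S) / (mm.Vmax * K1), rel=1e-10)

    def test_synergy_term_steepens_with_second_inhibitor(self, mm):
        S, K1, K2 = 0.5, 0.8, 30.0
        slopes = []
        for I2 in (0.0, 15.0, 60.0):
            v1 = ik.two_inhibitor_velocity(S, 1.0, I2, mm, K1, K2, beta=1.0)
            v0 = ik.two_inhibitor_velocity(S, 0.0, I2, mm, K1, K2, beta=1.0)
            slopes.append(1 / v1 - 1 / v0)
        assert slopes[0] < slopes[1] < slopes[2]
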