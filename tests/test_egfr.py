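"""Equation values, rounding, staging, and age arithmetic."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egfr_discordance import (
    EquationConstants,
    RoundingMode,
    StageScheme,
    age_at_date,
    assign_stage,
    ckdepi_egfr,
    mdrd_egfr,
    round_to_precision,
)
from egfr_discordance.egfr import DEFAULT_STAGES, assign_stage_array


class TestMdrd:
    @pytest.mark.parametrize(
        "age,scr,female,black,expected_tenth",
        [
            (60, 1.1, False, False, 68.3),
            (60, 1.1, True, False, 50.7),
            (70, 1.3, False, True, 66.1),
        ],
    )
    def test_known_values(self, age, scr, female, black, expected_tenth):
        v = mdrd_egfr(age, scr, female, black)
        assert round_to_precision(v, 0.1) == pytest.approx(expected_tenth)

    def test_female_equals_male_times_factor(self):
        m = mdrd_egfr(60, 1.1, False, False)
        f = mdrd_egfr(60, 1.1, True, False)
        assert f == pytest.approx(m * 0.742, rel=1e-15)

    @given(
        age=st.integers(18, 120),
        scr=st.floats(0.1, 30.0),
        black=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_gender_race_factors_exact(self, age, scr, black):
        male = mdrd_egfr(age, scr, False, black)
        female = mdrd_egfr(age, scr, True, black)
        assert female / male == pytest.approx(0.742, rel=1e-12)
        nb = mdrd_egfr(age, scr, False, False)
        b = mdrd_egfr(age, scr, False, True)
        assert b / nb == pytest.approx(1.212, rel=1e-12)

    @given(
        age=st.integers(18, 119),
        scr=st.floats(0.1, 29.0),
        female=st.booleans(),
        black=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_decreasing_in_scr_and_age(self, age, scr, female, black):
        base = mdrd_egfr(age, scr, female, black)
        assert mdrd_egfr(age, scr + 0.5, female, black) < base
        assert mdrd_egfr(age + 1, scr, female, black) < base

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            mdrd_egfr(60, 0.0, False, False)
        with pytest.raises(ValueError):
            mdrd_egfr(0, 1.0, False, False)

    def test_vectorized_matches_scalar(self):
        ages = np.array([40, 60, 80])
        scrs = np.array([0.8, 1.1, 2.0])
        vec = mdrd_egfr(ages, scrs, False, False)
        for a, s, v in zip(ages, scrs, vec):
            assert v == pytest.approx(mdrd_egfr(int(a), float(s), False, False))


class TestCkdEpi:
    def test_known_value_at_male_knot(self):
        v = ckdepi_egfr(60, 0.9, False, False)
        assert round_to_precision(v, 0.1) == pytest.approx(92.5)

    def test_value_at_knot_is_scale_times_age_term(self):
        c = EquationConstants()
        v = ckdepi_egfr(50, c.ckdepi_kappa_female, True, False)
        expected = c.ckdepi_scale * c.ckdepi_age_base**50 * c.ckdepi_female_factor
        assert v == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("female,kappa", [(False, 0.9), (True, 0.7)])
    def test_continuous_at_knot(self, female, kappa):
        eps = 1e-6
        lo = ckdepi_egfr(55, kappa - eps, female, False)
        hi = ckdepi_egfr(55, kappa + eps, female, False)
        assert abs(lo - hi) < 1e-3
        # gap shrinks with epsilon
        lo2 = ckdepi_egfr(55, kappa - 1e-9, female, False)
        hi2 = ckdepi_egfr(55, kappa + 1e-9, female, False)
        assert abs(lo2 - hi2) < abs(lo - hi)


class TestRounding:
    @pytest.mark.parametrize(
        "value,precision,expected",
        [
            (62.7, 1.0, 63.0),
            (58.9, 1.0, 59.0),
            (68.2839, 0.1, 68.3),
            (62.5, 1.0, 63.0),  # half away from zero
            (0.969996, 0.1, 1.0),
        ],
    )
    def test_half_away_from_zero(self, value, precision, expected):
        assert round_to_precision(value, precision) == pytest.approx(expected)

    def test_half_even_mode(self):
        assert round_to_precision(62.5, 1.0, RoundingMode.HALF_EVEN) == 62.0
        assert round_to_precision(63.5, 1.0, RoundingMode.HALF_EVEN) == 64.0

    @given(value=st.floats(0.01, 300.0), precision=st.sampled_from([0.1, 1.0, 0.01]))
    @settings(max_examples=200, deadline=None)
    def test_result_within_half_precision(self, value, precision):
        r = round_to_precision(value, precision)
        assert abs(r - value) <= precision / 2 + 1e-9
        assert abs(r / precision - round(r / precision)) < 1e-6

    def test_invalid_precision(self):
        with pytest.raises(ValueError):
            round_to_precision(1.0, 0.0)


class TestStaging:
    @pytest.mark.parametrize(
        "egfr,label",
        [
            (90.0, "eGFR 90+"),
            (89.9, "eGFR 60-89"),
            (60.0, "eGFR 60-89"),
            (59.0, "Stage 3a"),
            (45.0, "Stage 3a"),
            (44.9, "Stage 3b"),
            (30.0, "Stage 3b"),
            (29.9, "Stage 4"),
            (15.0, "Stage 4"),
            (14.9, "Stage 5"),
            (0.1, "Stage 5"),
            (250.0, "eGFR 90+"),
        ],
    )
    def test_boundaries(self, egfr, label):
        assert assign_stage(egfr) == label

    @given(egfr=st.floats(0.1, 300.0))
    @settings(max_examples=300, deadline=None)
    def test_exactly_one_stage(self, egfr):
        label = assign_stage(egfr)
        hits = [b for b in DEFAULT_STAGES.bands if b[1] <= egfr < b[2]]
        assert len(hits) == 1 and hits[0][0] == label

    def test_vectorized_matches_scalar(self):
        vals = np.array([90.0, 59.0, 44.9, 15.0, 14.9, 120.0])
        idx = assign_stage_array(vals)
        labels = [DEFAULT_STAGES.labels[i] for i in idx]
        assert labels == [assign_stage(float(v)) for v in vals]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_stage(0.0)

    def test_malformed_scheme_rejected(self):
        with pytest.raises(ValueError):
            StageScheme(bands=(("a", 50.0, math.inf), ("b", 0.0, 40.0)))


class TestAge:
    @pytest.mark.parametrize(
        "dob,on,expected",
        [
            (dt.date(1950, 6, 15), dt.date(2013, 6, 14), 62),
            (dt.date(1950, 6, 15), dt.date(2013, 6, 15), 63),
            (dt.date(1995, 1, 1), dt.date(2013, 1, 1), 18),
            (dt.date(1952, 2, 29), dt.date(2013, 2, 28), 60),
            (dt.date(1952, 2, 29), dt.date(2013, 3, 1), 61),
        ],
    )
    def test_completed_years(self, dob, on, expected):
        assert age_at_date(dob, on) == expected

    def test_before_birth_rejected(self):
        with pytest.raises(ValueError):
            age_at_date(dt.date(2000, 1, 1), dt.date(1999, 12, 31))


class TestConstants:
    def test_round_trip_json(self, tmp_path):
        c = EquationConstants(mdrd_scale=186.0)
        p = tmp_path / "constants.json"
        c.to_json(p)
        assert EquationConstants.from_json(p) == c

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            EquationConstants(mdrd_scr_exp=0.5)
        with pytest.raises(ValueError):
            EquationConstants(mdrd_scale=-1.0)

    def test_race_detail_invariance(self, snapshot_factory):
        # only the black / non-black distinction enters the equations: a
        # white and an asian patient with identical other fields get the
        # same eGFR from both equations
        from egfr_discordance.egfr import RaceDetail
        import dataclasses

        base = snapshot_factory(age=60, female=True, scr=1.1)
        for race in (RaceDetail.ASIAN, RaceDetail.AMERICAN_INDIAN, RaceDetail.OTHER):
            other = dataclasses.replace(base, race_detail=race)
            assert other.race_black == base.race_black is False
            assert mdrd_egfr(other.age, other.scr, other.female, other.race_black) == \
                mdrd_egfr(base.age, base.scr, base.female, base.race_black)
            assert ckdepi_egfr(other.age, other.scr, other.female, other.race_black) == \
                ckdepi_egfr(base.age, base.scr, base.female, base.race_black)
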