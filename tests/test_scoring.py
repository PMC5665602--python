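"""Score-engine unit and property tests.

The worked examples were hand-looked-up in the published band tables;
the property tests sweep the physiological input grids to confirm that
every value falls in exactly one band and that attribution sums to the
total.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edscores import (
    Avpu,
    MedsCriteria,
    MissingInputError,
    Vitals,
    avpu_from_gcs,
    meds_score,
    mews_score,
    raps_score,
    rems_score,
    tachypnea_or_hypoxia,
)
from edscores.scoring import round_half_up


def v(**kw):
    return Vitals(**kw)


class TestRaps:
    @pytest.mark.parametrize(
        "pr,mapr,rr,gcs,total",
        [
            (106, 94, 20, 15, 0),  # survivor-typical vitals, all zero bands
            (120.5, 72.5, 22, 15, 2),  # rounding before lookup; PR in the +2 band
            (30, 40, 4, 3, 16),  # every variable in its maximal band
            (70, 70, 12, 14, 0),  # zero-band lower edges
            (109, 109, 24, 15, 0),  # zero-band upper edges
            (110, 110, 25, 13, 2 + 2 + 1 + 1),
        ],
    )
    def test_examples(self, pr, mapr, rr, gcs, total):
        got = raps_score(v(pulse_rate=pr, mean_arterial_pressure=mapr, respiratory_rate=rr, gcs=gcs))
        assert got.total == total
        assert got.total == sum(got.components.values())

    def test_missing_input_names_field(self):
        with pytest.raises(MissingInputError, match="mean_arterial_pressure"):
            raps_score(v(pulse_rate=80, respiratory_rate=16, gcs=15))

    def test_impute_normal_scores_zero(self):
        assert raps_score(Vitals(), impute_normal=True).total == 0


class TestRems:
    @pytest.mark.parametrize(
        "age,pr,mapr,rr,gcs,spo2,total",
        [
            (30, 80, 90, 16, 15, 99, 0),
            (78, 120, 72, 22, 15, 95, 8),  # age > 74 gives +6, PR 110-139 gives +2
            (80, 30, 40, 3, 3, 60, 26),  # maximal profile
            (45, 80, 90, 16, 15, 90, 2),  # age band edge 45 -> +2; SpO2 90 still 0
            (44, 80, 90, 16, 15, 89, 1),  # SpO2 86-89 -> +1
        ],
    )
    def test_examples(self, age, pr, mapr, rr, gcs, spo2, total):
        got = rems_score(
            v(pulse_rate=pr, mean_arterial_pressure=mapr, respiratory_rate=rr, gcs=gcs, spo2=spo2), age
        )
        assert got.total == total

    def test_requires_spo2(self):
        with pytest.raises(MissingInputError, match="spo2"):
            rems_score(v(pulse_rate=80, mean_arterial_pressure=90, respiratory_rate=16, gcs=15), 50)


class TestMews:
    @pytest.mark.parametrize(
        "sbp,hr,rr,temp,avpu,total",
        [
            (110, 95, 12, 37.0, Avpu.ALERT, 0),
            (65, 135, 32, 34.5, Avpu.UNRESPONSIVE, 14),  # maximal profile
            (70, 40, 21, 38.45, Avpu.VOICE, 10),  # gap and rounding conventions
            (100, 50, 15, 38.4, Avpu.ALERT, 3),  # band upper edges: +1 +1 +1 +0
            (101, 51, 14, 35.0, Avpu.ALERT, 0),  # zero-band lower edges
            (200, 130, 30, 38.5, Avpu.PAIN, 2 + 3 + 3 + 2 + 2),
        ],
    )
    def test_examples(self, sbp, hr, rr, temp, avpu, total):
        got = mews_score(v(systolic_bp=sbp, pulse_rate=hr, respiratory_rate=rr, temperature=temp, avpu=avpu))
        assert got.total == total

    def test_gap_values_take_higher_acuity_band(self):
        base = dict(respiratory_rate=12, temperature=37.0, avpu=Avpu.ALERT)
        assert mews_score(v(systolic_bp=70, pulse_rate=80, **base)).components["systolic_bp"] == 3
        assert mews_score(v(systolic_bp=71, pulse_rate=80, **base)).components["systolic_bp"] == 2
        assert mews_score(v(systolic_bp=120, pulse_rate=40, **base)).components["heart_rate"] == 2
        assert mews_score(v(systolic_bp=120, pulse_rate=41, **base)).components["heart_rate"] == 1

    def test_temperature_rounding_to_tenth(self):
        # 38.449 rounds to 38.4 (zero band); 38.45 rounds half-up to 38.5 (+2)
        base = dict(systolic_bp=120, pulse_rate=80, respiratory_rate=12, avpu=Avpu.ALERT)
        assert mews_score(v(temperature=38.449, **base)).total == 0
        assert mews_score(v(temperature=38.45, **base)).total == 2

    def test_explicit_avpu_takes_precedence_over_gcs(self):
        got = mews_score(
            v(systolic_bp=120, pulse_rate=80, respiratory_rate=12, temperature=37.0, gcs=3, avpu=Avpu.ALERT)
        )
        assert got.components["avpu"] == 0

    def test_avpu_derived_from_gcs_when_absent(self):
        got = mews_score(v(systolic_bp=120, pulse_rate=80, respiratory_rate=12, temperature=37.0, gcs=3))
        assert got.components["avpu"] == 3


class TestMeds:
    def normal_vitals(self):
        return v(respiratory_rate=16, spo2=98, gcs=15)

    def test_all_negative_is_zero(self):
        crit = MedsCriteria(age=40, platelet_count=300, band_percent=2)
        assert meds_score(self.normal_vitals(), crit).total == 0

    def test_all_positive_is_27(self):
        crit = MedsCriteria(
            age=70,
            terminal_illness=True,
            septic_shock=True,
            platelet_count=100,
            band_percent=10,
            lower_respiratory_infection=True,
            nursing_home_resident=True,
            altered_mental_status=True,
            oxygen_by_mask=True,
        )
        assert meds_score(v(respiratory_rate=30, spo2=80, gcs=3), crit).total == 27

    def test_partial_profile(self):
        crit = MedsCriteria(age=70, septic_shock=True, platelet_count=120, band_percent=2)
        got = meds_score(v(respiratory_rate=18, spo2=95, gcs=15), crit)
        assert got.total == 9
        assert {k for k, p in got.components.items() if p} == {"age_gt_65", "septic_shock", "platelets_lt_150"}

    def test_age_threshold_strict(self):
        crit65 = MedsCriteria(age=65, platelet_count=300, band_percent=2)
        crit66 = MedsCriteria(age=66, platelet_count=300, band_percent=2)
        assert meds_score(self.normal_vitals(), crit65).components["age_gt_65"] == 0
        assert meds_score(self.normal_vitals(), crit66).components["age_gt_65"] == 3

    def test_missing_band_percent_raises(self):
        crit = MedsCriteria(age=40, platelet_count=300)
        with pytest.raises(MissingInputError, match="band_percent"):
            meds_score(self.normal_vitals(), crit)

    def test_ams_default_from_gcs(self):
        crit = MedsCriteria(age=40, platelet_count=300, band_percent=2)
        assert meds_score(v(respiratory_rate=16, spo2=98, gcs=13), crit).components["altered_mental_status"] == 2
        assert meds_score(v(respiratory_rate=16, spo2=98, gcs=14), crit).components["altered_mental_status"] == 0


@pytest.mark.parametrize(
    "rr,mask,spo2,expected",
    [
        (20, False, 90, False),  # boundary: strict inequalities on both sides
        (22, False, 98, True),
        (12, True, 99, True),
        (20.4, False, 90, True),  # strict comparison on the measured value, no rounding
        (12, False, 89.9, True),
    ],
)
def test_tachypnea_or_hypoxia(rr, mask, spo2, expected):
    assert tachypnea_or_hypoxia(v(respiratory_rate=rr, spo2=spo2), mask) is expected


@pytest.mark.parametrize(
    "gcs,expected",
    [(15, Avpu.ALERT), (14, Avpu.ALERT), (13, Avpu.VOICE), (10, Avpu.VOICE), (9, Avpu.VOICE),
     (8, Avpu.PAIN), (4, Avpu.PAIN), (3, Avpu.UNRESPONSIVE)],
)
def test_avpu_from_gcs(gcs, expected):
    assert avpu_from_gcs(gcs) is expected


def test_avpu_from_gcs_rejects_out_of_range():
    for bad in (2, 16, 7.5):
        with pytest.raises(ValueError):
            avpu_from_gcs(bad)


def test_round_half_up_is_decimal_exact():
    assert round_half_up(120.5) == 121
    assert round_half_up(0.5) == 1
    assert round_half_up(38.45, 1) == 38.5  # binary float of 38.45 is slightly below
    assert round_half_up(38.449, 1) == 38.4


# ---------------------------------------------------------------------------
# Invariants


def test_band_exhaustiveness_sweep():
    """Every in-range input hits exactly one band in every score (grid sweep)."""
    for pr in range(0, 301):
        raps_score(v(pulse_rate=pr, mean_arterial_pressure=90, respiratory_rate=16, gcs=15))
    for mapr in range(0, 301):
        raps_score(v(pulse_rate=80, mean_arterial_pressure=mapr, respiratory_rate=16, gcs=15))
    for rr in range(0, 81):
        raps_score(v(pulse_rate=80, mean_arterial_pressure=90, respiratory_rate=rr, gcs=15))
        mews_score(v(systolic_bp=120, pulse_rate=80, respiratory_rate=rr, temperature=37.0, avpu=Avpu.ALERT))
    for gcs in range(3, 16):
        raps_score(v(pulse_rate=80, mean_arterial_pressure=90, respiratory_rate=16, gcs=gcs))
        rems_score(v(pulse_rate=80, mean_arterial_pressure=90, respiratory_rate=16, gcs=gcs, spo2=98), 40)
    for spo2 in range(0, 101):
        rems_score(v(pulse_rate=80, mean_arterial_pressure=90, respiratory_rate=16, gcs=15, spo2=spo2), 40)
    for age in range(18, 111):
        rems_score(v(pulse_rate=80, mean_arterial_pressure=90, respiratory_rate=16, gcs=15, spo2=98), age)
    for sbp in range(0, 301):
        mews_score(v(systolic_bp=sbp, pulse_rate=80, respiratory_rate=12, temperature=37.0, avpu=Avpu.ALERT))
    for hr in range(0, 301):
        mews_score(v(systolic_bp=120, pulse_rate=hr, respiratory_rate=12, temperature=37.0, avpu=Avpu.ALERT))
    for t10 in range(250, 451):  # 25.0 to 45.0 degC in 0.1 steps
        mews_score(v(systolic_bp=120, pulse_rate=80, respiratory_rate=12, temperature=t10 / 10, avpu=Avpu.ALERT))


def _unimodal_valley(points):
    """Points must fall to a minimum then rise (non-strictly) -- acuity is unimodal."""
    lowest = points.index(min(points))
    falling, rising = points[: lowest + 1], points[lowest:]
    return all(a >= b for a, b in zip(falling, falling[1:])) and all(
        a <= b for a, b in zip(rising, rising[1:])
    )


def test_band_points_form_unimodal_valley():
    pr_pts = [
        raps_score(v(pulse_rate=x, mean_arterial_pressure=90, respiratory_rate=16, gcs=15)).components["pulse_rate"]
        for x in range(0, 301)
    ]
    sbp_pts = [
        mews_score(v(systolic_bp=x, pulse_rate=80, respiratory_rate=12, temperature=37.0, avpu=Avpu.ALERT)).components["systolic_bp"]
        for x in range(0, 301)
    ]
    hr_pts = [
        mews_score(v(systolic_bp=120, pulse_rate=x, respiratory_rate=12, temperature=37.0, avpu=Avpu.ALERT)).components["heart_rate"]
        for x in range(0, 301)
    ]
    assert _unimodal_valley(pr_pts)
    assert _unimodal_valley(sbp_pts)
    assert _unimodal_valley(hr_pts)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pr=st.floats(0, 300),
    mapr=st.floats(0, 300),
    rr=st.floats(0, 80),
    sbp=st.floats(0, 300),
    temp=st.floats(25, 45),
    spo2=st.floats(0, 100),
    gcs=st.integers(3, 15),
    age=st.integers(18, 110),
)
def test_totals_in_range_and_attribution_sums(pr, mapr, rr, sbp, temp, spo2, gcs, age):
    vit = v(
        pulse_rate=pr,
        mean_arterial_pressure=mapr,
        respiratory_rate=rr,
        systolic_bp=sbp,
        temperature=temp,
        spo2=spo2,
        gcs=gcs,
    )
    crit = MedsCriteria(age=age, platelet_count=200, band_percent=3)
    for breakdown, hi in (
        (raps_score(vit), 16),
        (rems_score(vit, age), 26),
        (mews_score(vit), 14),
        (meds_score(vit, crit), 27),
    ):
        assert 0 <= breakdown.total <= hi
        assert breakdown.total == sum(breakdown.components.values())


def test_vitals_validation():
    with pytest.raises(ValueError):
        Vitals(gcs=17)
    with pytest.raises(ValueError):
        Vitals(spo2=101)
    with pytest.raises(ValueError):
        Vitals(pulse_rate=-1)
    with pytest.raises(ValueError):
        Vitals(pulse_rate=math.nan)
    with pytest.raises(ValueError):
        MedsCriteria(age=17)
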