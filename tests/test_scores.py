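"""Scoring functions: worked examples, boundaries, and brute-force enumeration."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st
from pydantic import ValidationError

from mblater.records import PatientRecord
from mblater.scores import (
    SCORE_RANGES,
    ScoreResult,
    alarmc,
    apple,
    base_af2,
    cha2ds2_vasc,
    chads2,
    hatch,
    mb_later,
    score_cohort,
)

from conftest import make_record


@pytest.mark.parametrize(
    "overrides, expected",
    [
        # all components absent
        (dict(sex="F", bbb=False, lad=40, af_type="paroxysmal", eraf=False), 0),
        # male gender alone scores one point
        (dict(sex="M", bbb=False, lad=45, af_type="paroxysmal", eraf=False), 1),
        # every component at maximum: 1+1+1+2+1
        (dict(sex="M", bbb=True, lad=48, af_type="longstanding_persistent", eraf=True), 6),
        # LA boundary is inclusive at 47 mm: 0+0+1+1+1
        (dict(sex="F", bbb=False, lad=47, af_type="persistent", eraf=True), 3),
    ],
)
def test_mb_later_examples(overrides, expected):
    assert mb_later(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(age=50, af_type="paroxysmal", lad=40, lvef=60, egfr_bsa=90), 0),
        (dict(age=70, af_type="persistent", lad=43, lvef=45, egfr_bsa=55), 5),
        # age/LVEF/eGFR are strict, LAD is inclusive: only LAD >= 43 fires
        (dict(age=65, af_type="paroxysmal", lad=44, lvef=50, egfr_bsa=60), 1),
    ],
)
def test_apple_examples(overrides, expected):
    assert apple(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(), 0),
        (dict(af_type="persistent", lad_index=24, egfr=60,
              metabolic_syndrome=True, lvef=45), 5),
        # LA index threshold is strictly greater than 23
        (dict(lad_index=23.0), 0),
    ],
)
def test_alarmc_examples(overrides, expected):
    assert alarmc(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "overrides, expected",
    [
        (dict(), 0),
        (dict(bmi=29, lad=41, smoker=True, eraf=True, af_history=7,
              af_type="persistent"), 6),
        # all three numeric thresholds are strict
        (dict(bmi=28.0, lad=40.0, af_history=6.0), 0),
    ],
)
def test_base_af2_examples(overrides, expected):
    assert base_af2(make_record(**overrides)).total == expected


@pytest.mark.parametrize(
    "score_fn, overrides, expected",
    [
        (chads2, dict(sex="M", age=40), 0),
        (cha2ds2_vasc, dict(sex="M", age=40), 0),
        (hatch, dict(sex="M", age=40), 0),
        (chads2, dict(age=80, stroke_tia=True), 3),
        (cha2ds2_vasc, dict(sex="F", age=76, hypertension=True), 4),
        (hatch, dict(age=80, stroke_tia=True, chf=True), 5),
    ],
)
def test_thromboembolic_score_examples(score_fn, overrides, expected):
    assert score_fn(make_record(**overrides)).total == expected


# brute-force enumeration axes: (field, [(value, points), ...]) per score
_AXES = {
    mb_later: [
        ("sex", [("F", 0), ("M", 1)]),
        ("bbb", [(False, 0), (True, 1)]),
        ("lad", [(40.0, 0), (47.0, 1)]),
        ("af_type", [("paroxysmal", 0), ("persistent", 1),
                     ("longstanding_persistent", 2)]),
        ("eraf", [(False, 0), (True, 1)]),
    ],
    apple: [
        ("age", [(65.0, 0), (66.0, 1)]),
        ("af_type", [("paroxysmal", 0), ("persistent", 1),
                     ("longstanding_persistent", 1)]),
        ("lad", [(42.0, 0), (43.0, 1)]),
        ("lvef", [(50.0, 0), (49.0, 1)]),
        ("egfr_bsa", [(60.0, 0), (59.0, 1)]),
    ],
    alarmc: [
        ("af_type", [("paroxysmal", 0), ("persistent", 1),
                     ("longstanding_persistent", 1)]),
        ("lad_index", [(23.0, 0), (23.5, 1)]),
        ("egfr", [(68.0, 0), (67.0, 1)]),
        ("metabolic_syndrome", [(False, 0), (True, 1)]),
        ("lvef", [(50.0, 0), (45.0, 1)]),
    ],
    base_af2: [
        ("bmi", [(28.0, 0), (29.0, 1)]),
        ("lad", [(40.0, 0), (41.0, 1)]),
        ("smoker", [(False, 0), (True, 1)]),
        ("eraf", [(False, 0), (True, 1)]),
        ("af_history", [(6.0, 0), (7.0, 1)]),
        ("af_type", [("paroxysmal", 0), ("persistent", 1),
                     ("longstanding_persistent", 1)]),
    ],
    chads2: [
        ("chf", [(False, 0), (True, 1)]),
        ("hypertension", [(False, 0), (True, 1)]),
        ("age", [(50.0, 0), (75.0, 1)]),
        ("diabetes", [(False, 0), (True, 1)]),
        ("stroke_tia", [(False, 0), (True, 2)]),
    ],
    cha2ds2_vasc: [
        ("chf", [(False, 0), (True, 1)]),
        ("hypertension", [(False, 0), (True, 1)]),
        ("age", [(50.0, 0), (65.0, 1), (74.9, 1), (75.0, 2), (80.0, 2)]),
        ("diabetes", [(False, 0), (True, 1)]),
        ("stroke_tia", [(False, 0), (True, 2)]),
        ("vascular_disease", [(False, 0), (True, 1)]),
        ("sex", [("M", 0), ("F", 1)]),
    ],
    hatch: [
        ("hypertension", [(False, 0), (True, 1)]),
        ("age", [(50.0, 0), (75.0, 0), (76.0, 1)]),
        ("stroke_tia", [(False, 0), (True, 2)]),
        ("copd", [(False, 0), (True, 1)]),
        ("chf", [(False, 0), (True, 2)]),
    ],
}


@pytest.mark.parametrize("score_fn", list(_AXES), ids=lambda f: f.__name__)
def test_enumeration_matches_component_sum(score_fn):
    """Every predicate combination scores exactly the sum of its points."""
    axes = _AXES[score_fn]
    for combo in itertools.product(*(levels for _, levels in axes)):
        overrides = {f: v for (f, _), (v, _) in zip(axes, combo)}
        expected = sum(p for _, p in combo)
        result = score_fn(make_record(**overrides))
        assert result.total == expected, overrides
        lo, hi = SCORE_RANGES[result.score_name]
        assert lo <= result.total <= hi


@pytest.mark.parametrize("score_fn", list(_AXES), ids=lambda f: f.__name__)
def test_monotone_in_each_component(score_fn):
    """Raising any one component level never lowers the total."""
    axes = _AXES[score_fn]
    for combo in itertools.product(*(range(len(lv)) for _, lv in axes)):
        base = {f: lv[i][0] for (f, lv), i in zip(axes, combo)}
        total = score_fn(make_record(**base)).total
        for k, (f, lv) in enumerate(axes):
            if combo[k] + 1 < len(lv):
                bumped = dict(base, **{f: lv[combo[k] + 1][0]})
                assert score_fn(make_record(**bumped)).total >= total


_IRRELEVANT = {
    mb_later: dict(bmi=33.0, lvef=35.0, egfr=40.0, egfr_bsa=40.0, chf=True,
                   hypertension=True, diabetes=True, age=80.0, smoker=True),
    apple: dict(sex="M", bbb=True, eraf=True, smoker=True, bmi=33.0,
                metabolic_syndrome=True, egfr=40.0),
    alarmc: dict(sex="M", bbb=True, eraf=True, age=80.0, lad=55.0,
                 egfr_bsa=40.0, bmi=33.0),
    base_af2: dict(sex="M", bbb=True, age=80.0, lvef=35.0, egfr=40.0,
                   metabolic_syndrome=True, chf=True),
    chads2: dict(sex="M", bbb=True, lad=55.0, eraf=True, copd=True,
                 vascular_disease=True, smoker=True),
    cha2ds2_vasc: dict(bbb=True, lad=55.0, eraf=True, copd=True, bmi=33.0,
                       smoker=True, metabolic_syndrome=True),
    hatch: dict(sex="M", bbb=True, lad=55.0, eraf=True, diabetes=True,
                vascular_disease=True, bmi=33.0),
}


@pytest.mark.parametrize("score_fn", list(_IRRELEVANT), ids=lambda f: f.__name__)
def test_invariant_to_unrelated_fields(score_fn):
    base = make_record()
    perturbed = make_record(**_IRRELEVANT[score_fn])
    assert score_fn(base).total == score_fn(perturbed).total


def test_score_result_rejects_inconsistent_total():
    with pytest.raises(ValueError):
        ScoreResult("MB-LATER", 3, (("male", 1),))


def test_missing_field_rejected_by_name():
    payload = dict(id="x", age=50, sex="M")
    with pytest.raises(ValidationError) as exc:
        PatientRecord(**payload)
    assert "bbb" in str(exc.value)


@given(
    bmi=st.floats(16, 45), lvef=st.floats(20, 80), egfr=st.floats(15, 140),
    age=st.floats(18, 95),
)
def test_mb_later_depends_only_on_its_five_components(bmi, lvef, egfr, age):
    a = mb_later(make_record(sex="M", lad=48.0, eraf=True))
    b = mb_later(make_record(sex="M", lad=48.0, eraf=True,
                             bmi=bmi, lvef=lvef, egfr=egfr, age=age))
    assert a.total == b.total == 3
    assert dict(a.components) == dict(b.components)


def test_score_cohort_matches_per_record_path(record_factory):
    from mblater.records import frame_from_records, Outcome

    records = [
        record_factory(id="a", sex="M", lad=48, af_type="persistent"),
        record_factory(id="b", bbb=True, eraf=True, age=78, stroke_tia=True),
    ]
    outs = [Outcome(followup_months=30, vlraf_event=True),
            Outcome(followup_months=24, vlraf_event=False)]
    frame = frame_from_records(records, outs)
    totals = score_cohort(frame)
    for i, rec in enumerate(records):
        assert totals.loc[i, "MB-LATER"] == mb_later(rec).total
        assert totals.loc[i, "HATCH"] == hatch(rec).total


def test_unknown_score_name_rejected(record_factory):
    from mblater.records import frame_from_records, Outcome

    frame = frame_from_records(
        [record_factory()], [Outcome(followup_months=20, vlraf_event=False)]
    )
    with pytest.raises(KeyError):
        score_cohort(frame, ["NOPE"])
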