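"""Threshold criteria mapping raw measurements to MetS components."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsmarkov import (
    ComponentMeasurements,
    MetabolicState,
    ThresholdPolicy,
    classify,
    evaluate_components,
)
from metsmarkov.classification import read_measurement_panel
from metsmarkov.states import COMPONENT_NAMES


def measurements(**overrides):
    base = dict(
        sex="male",
        waist_cm=80.0,
        triglycerides_mg_dl=100.0,
        hdl_mg_dl=55.0,
        systolic_mmHg=115.0,
        diastolic_mmHg=75.0,
        fpg_mg_dl=88.0,
    )
    base.update(overrides)
    return ComponentMeasurements(**base)


@pytest.mark.parametrize(
    "overrides, expected_active",
    [
        # waist cutoff is sex-specific and strictly > 90 (men) / 80 (women)
        (dict(waist_cm=92.0, triglycerides_mg_dl=120.0, hdl_mg_dl=45.0,
              systolic_mmHg=118.0, diastolic_mmHg=76.0, fpg_mg_dl=90.0),
         ("abdominal_obesity",)),
        (dict(waist_cm=90.0), ()),
        (dict(sex="female", waist_cm=81.0, hdl_mg_dl=55.0), ("abdominal_obesity",)),
        # all-normal woman
        (dict(sex="female", waist_cm=75.0, triglycerides_mg_dl=80.0,
              hdl_mg_dl=60.0, systolic_mmHg=110.0, diastolic_mmHg=70.0,
              fpg_mg_dl=85.0), ()),
        # inclusive >= boundaries for TG, BP, FPG by default
        (dict(triglycerides_mg_dl=150.0), ("high_tg",)),
        (dict(systolic_mmHg=130.0), ("high_bp",)),
        (dict(systolic_mmHg=120.0, diastolic_mmHg=85.0), ("high_bp",)),
        (dict(fpg_mg_dl=100.0), ("high_fpg",)),
        # HDL strictly below its sex-specific cutoff
        (dict(hdl_mg_dl=40.0), ()),
        (dict(hdl_mg_dl=39.9), ("low_hdl",)),
        (dict(sex="female", hdl_mg_dl=49.0), ("low_hdl",)),
    ],
)
def test_threshold_examples(overrides, expected_active):
    profile = evaluate_components(measurements(**overrides))
    assert profile.active() == tuple(expected_active)


def test_medication_flags_force_components():
    """Treated hypertension / diabetes count even with normal readings."""
    p = evaluate_components(
        measurements(systolic_mmHg=120.0, diastolic_mmHg=80.0,
                     on_antihypertensives=True)
    )
    assert p.high_bp and not p.high_fpg
    p = evaluate_components(measurements(on_antidiabetics=True))
    assert p.high_fpg


def test_strict_policy_flips_boundary_cases_only():
    strict = ThresholdPolicy(strict=True)
    at_cut = measurements(triglycerides_mg_dl=150.0, systolic_mmHg=130.0,
                          fpg_mg_dl=100.0)
    assert evaluate_components(at_cut).count == 3
    assert evaluate_components(at_cut, strict).count == 0
    above = measurements(triglycerides_mg_dl=150.5, systolic_mmHg=130.5,
                         fpg_mg_dl=100.5)
    assert evaluate_components(above, strict).count == 3


def test_classify_collapses_to_state():
    m = measurements(waist_cm=95.0, triglycerides_mg_dl=200.0, hdl_mg_dl=35.0)
    assert classify(m) is MetabolicState.METS


@pytest.mark.parametrize(
    "bad",
    [
        dict(sex="other"),
        dict(waist_cm=-1.0),
        dict(waist_cm=float("nan")),
        dict(systolic_mmHg=70.0, diastolic_mmHg=75.0),
    ],
)
def test_invalid_measurements_rejected(bad):
    with pytest.raises((ValueError, TypeError)):
        measurements(**bad)


RISK_FIELDS = ("waist_cm", "triglycerides_mg_dl", "systolic_mmHg",
               "diastolic_mmHg", "fpg_mg_dl")


@given(
    waist=st.floats(50, 140), tg=st.floats(40, 400), hdl=st.floats(20, 100),
    sbp=st.floats(90, 200), dbp_frac=st.floats(0.4, 0.95),
    fpg=st.floats(60, 250), delta=st.floats(0.01, 50),
    sex=st.sampled_from(["male", "female"]),
)
@settings(max_examples=200, deadline=None)
def test_components_monotone_in_risk(waist, tg, hdl, sbp, dbp_frac, fpg,
                                     delta, sex):
    """Raising any risk measurement (or lowering HDL) never clears a component."""
    m = ComponentMeasurements(sex=sex, waist_cm=waist, triglycerides_mg_dl=tg,
                              hdl_mg_dl=hdl, systolic_mmHg=sbp,
                              diastolic_mmHg=sbp * dbp_frac, fpg_mg_dl=fpg)
    before = evaluate_components(m)
    for f in RISK_FIELDS:
        if f == "diastolic_mmHg" and m.diastolic_mmHg + delta >= m.systolic_mmHg:
            continue  # would violate the systolic > diastolic invariant
        worse = dataclasses.replace(m, **{f: getattr(m, f) + delta})
        after = evaluate_components(worse)
        for c in COMPONENT_NAMES:
            assert getattr(after, c) >= getattr(before, c)
    lower_hdl = dataclasses.replace(m, hdl_mg_dl=max(m.hdl_mg_dl - delta, 1.0))
    assert evaluate_components(lower_hdl).low_hdl >= before.low_hdl


def test_measurement_panel_reader(tmp_path):
    path = tmp_path / "panel.csv"
    path.write_text(
        "subject_id,wave,sex,waist_cm,triglycerides_mg_dl,hdl_mg_dl,"
        "systolic_mmHg,diastolic_mmHg,fpg_mg_dl,on_antihypertensives,"
        "on_antidiabetics\n"
        "s1,2002,male,95,200,35,120,80,90,False,False\n"
        "s2,2002,female,70,90,60,110,70,85,False,False\n"
    )
    df = read_measurement_panel(path)
    assert list(df["state"]) == ["METS", "NO_COMPONENT"]
    with pytest.raises(ValueError, match="missing required columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("subject_id,sex\ns1,male\n")
        read_measurement_panel(bad)
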