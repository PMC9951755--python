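"""Schema validation, unit conversions, and the study-stratified split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from munmeta import (
    DietType, SplitSpec, StudyTable, TreatmentRecord,
    bw_from_dmi_fraction, convert_milk_urea_to_mun, cp_from_n_intake,
    read_treatment_table, stratified_split,
)
from munmeta.data_model import RowValidationError, SchemaError


# -- unit conversions -------------------------------------------------------

@pytest.mark.parametrize("value,unit,expected", [
    (1.0, "milk_urea_mmol_l", 1.0 / 0.357),      # ~2.80 mg/dL per mmol/L
    (10.0, "milk_urea_mg_dl", 4.67),             # urea is 46.7% N
    (13.2, "mun_mg_dl", 13.2),                   # identity
    (0.0, "milk_urea_mmol_l", 0.0),
    (0.0, "milk_urea_mg_dl", 0.0),
])
def test_milk_urea_conversions(value, unit, expected):
    assert convert_milk_urea_to_mun(value, unit) == pytest.approx(expected, abs=1e-12)


def test_conversion_rejects_unknown_unit_and_negative():
    with pytest.raises(ValueError, match="unknown"):
        convert_milk_urea_to_mun(1.0, "mol/L")
    with pytest.raises(ValueError):
        convert_milk_urea_to_mun(-1.0, "mun_mg_dl")


@given(st.floats(min_value=0.1, max_value=60.0))
def test_mun_mmol_round_trip(mun):
    """MUN -> milk urea mmol/L (x0.357) -> MUN recovers the input."""
    milk_urea = mun * 0.357
    back = convert_milk_urea_to_mun(milk_urea, "milk_urea_mmol_l")
    assert back == pytest.approx(mun, rel=1e-9)


@pytest.mark.parametrize("n_intake,dmi,expected", [
    (594.6, 22.2, 16.74),   # reproduces the TMR stratum CP from its N intake and DMI
    (160.0, 10.0, 10.0),
])
def test_cp_from_n_intake(n_intake, dmi, expected):
    assert cp_from_n_intake(n_intake, dmi) == pytest.approx(expected, abs=0.005)


@given(st.floats(min_value=50, max_value=900), st.floats(min_value=5, max_value=35),
       st.floats(min_value=0.1, max_value=10))
def test_cp_is_scale_free(n_intake, dmi, c):
    """Scaling N intake and DMI together leaves CP% unchanged."""
    assert cp_from_n_intake(c * n_intake, c * dmi) == pytest.approx(
        cp_from_n_intake(n_intake, dmi), rel=1e-9)


@pytest.mark.parametrize("dmi,pct,expected", [(18.0, 3.0, 600.0), (22.0, 4.0, 550.0)])
def test_bw_from_dmi_fraction(dmi, pct, expected):
    assert bw_from_dmi_fraction(dmi, pct) == pytest.approx(expected)


@pytest.mark.parametrize("fn,args", [
    (cp_from_n_intake, (0.0, 10.0)),
    (cp_from_n_intake, (100.0, 0.0)),
    (bw_from_dmi_fraction, (18.0, 0.0)),
    (bw_from_dmi_fraction, (0.0, 3.0)),
])
def test_derived_covariates_reject_nonpositive(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


# -- reading and validation -------------------------------------------------

def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "study_id,diet,un_gd,un_sem,mun_mgdl,bw_kg,dmi_kg,cp_pct\n"


def test_read_round_trip(tmp_path):
    p = _write(tmp_path, HEADER +
               "10.1/a,TMR,180,8,12,640,22,16.5\n"
               "10.2/b,pasture,210,11,18,500,17,20\n")
    t = read_treatment_table(p)
    assert t.n_records == 2
    assert t.df["diet"].tolist() == [DietType.TMR, DietType.PASTURE]


def test_read_missing_mandatory_column_names_it(tmp_path):
    p = _write(tmp_path, "study_id,diet,un_gd,bw_kg,dmi_kg,cp_pct\n10.1/a,TMR,180,640,22,16.5\n")
    with pytest.raises(SchemaError, match="mun_mgdl"):
        read_treatment_table(p)


def test_read_column_mapping(tmp_path):
    p = _write(tmp_path, "doi,system,UN,MUN,weight,intake,protein\n"
                         "10.1/a,TMR,180,12,640,22,16.5\n")
    t = read_treatment_table(p, schema={
        "study_id": "doi", "diet": "system", "un_gd": "UN", "mun_mgdl": "MUN",
        "bw_kg": "weight", "dmi_kg": "intake", "cp_pct": "protein"})
    assert t.n_records == 1


def test_read_unparsable_numeric_is_row_indexed(tmp_path):
    p = _write(tmp_path, HEADER + "10.1/a,TMR,180,8,12,640,22,16.5\n"
                                  "10.1/a,TMR,abc,8,12,640,22,16.5\n")
    with pytest.raises(RowValidationError) as exc:
        read_treatment_table(p)
    assert exc.value.errors[0][0] == 1
    assert "un_gd" in exc.value.errors[0][1]


def test_zero_sem_flagged_only_when_weighting_requested(tmp_path):
    body = HEADER + "10.1/a,TMR,180,0,12,640,22,16.5\n"
    p = _write(tmp_path, body)
    with pytest.raises(RowValidationError, match="un_sem"):
        read_treatment_table(p, require_sem=True)
    # without weighting, a zero SEm is still invalid if present
    with pytest.raises(RowValidationError):
        read_treatment_table(p)


def test_absent_sem_allowed_without_weighting(tmp_path):
    p = _write(tmp_path, HEADER + "10.1/a,TMR,180,,12,640,22,16.5\n")
    t = read_treatment_table(p)
    assert t.records()[0].un_sem is None


def test_study_with_two_diets_rejected():
    df = pd.DataFrame({
        "study_id": ["10.1/a", "10.1/a"], "diet": ["TMR", "PASTURE"],
        "un_gd": [180, 200], "un_sem": [8, 9], "mun_mgdl": [12, 13],
        "bw_kg": [640, 650], "dmi_kg": [22, 23], "cp_pct": [16, 17]})
    with pytest.raises(RowValidationError, match="more than one diet"):
        StudyTable(df).validate()


def test_canonical_sort_is_stable_and_permutation_proof(tiny_table):
    shuffled = StudyTable(tiny_table.df.sample(frac=1, random_state=4))
    a = tiny_table.canonical_sort().df
    b = shuffled.canonical_sort().df
    pd.testing.assert_frame_equal(
        a.sort_values(list(a.columns.drop("diet"))).reset_index(drop=True),
        b.sort_values(list(b.columns.drop("diet"))).reset_index(drop=True))


# -- stratified split -------------------------------------------------------

def _many_studies(n_tmr=41, n_pasture=10, per_study=3):
    rows = []
    rng = np.random.default_rng(5)
    for diet, n in ((DietType.TMR, n_tmr), (DietType.PASTURE, n_pasture)):
        for i in range(n):
            sid = f"10.5/{diet.value.lower()}{i:02d}"
            for _ in range(per_study):
                rows.append({"study_id": sid, "diet": diet,
                             "un_gd": rng.uniform(120, 260), "un_sem": rng.uniform(5, 15),
                             "mun_mgdl": rng.uniform(8, 20), "bw_kg": rng.uniform(450, 700),
                             "dmi_kg": rng.uniform(14, 25), "cp_pct": rng.uniform(14, 22)})
    return StudyTable(pd.DataFrame(rows))


def test_split_counts_match_design():
    """41 TMR + 10 pasture studies with 3 held out per diet -> 38/7 train, 3/3 test."""
    table = _many_studies()
    train, test = stratified_split(table, SplitSpec(seed=11, n_test_per_diet=3))
    train_diets = train.diet_of_study()
    test_diets = test.diet_of_study()
    assert sum(d is DietType.TMR for d in train_diets.values()) == 38
    assert sum(d is DietType.PASTURE for d in train_diets.values()) == 7
    assert sum(d is DietType.TMR for d in test_diets.values()) == 3
    assert sum(d is DietType.PASTURE for d in test_diets.values()) == 3
    assert set(train_diets) | set(test_diets) == set(table.study_ids)
    assert not (set(train_diets) & set(test_diets))
    assert train.n_records + test.n_records == table.n_records


def test_split_deterministic_and_order_invariant():
    table = _many_studies()
    spec = SplitSpec(seed=3, n_test_per_diet=3)
    t1 = stratified_split(table, spec)[1].study_ids
    t2 = stratified_split(table, spec)[1].study_ids
    shuffled = StudyTable(table.df.sample(frac=1, random_state=9))
    t3 = stratified_split(shuffled, spec)[1].study_ids
    assert t1 == t2
    assert sorted(t1) == sorted(t3)


def test_split_degenerate_and_error_cases():
    table = _many_studies(n_tmr=4, n_pasture=4)
    train, test = stratified_split(table, SplitSpec(seed=0, n_test_per_diet=0))
    assert test.n_records == 0 and train.n_records == table.n_records
    with pytest.raises(ValueError, match="stratum"):
        stratified_split(table, SplitSpec(seed=0, n_test_per_diet=4))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_split_stratum_sizes_independent_of_seed(seed):
    table = _many_studies()
    _, test = stratified_split(table, SplitSpec(seed=seed, n_test_per_diet=3))
    diets = list(test.diet_of_study().values())
    assert sum(d is DietType.TMR for d in diets) == 3
    assert sum(d is DietType.PASTURE for d in diets) == 3
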