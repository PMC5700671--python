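import numpy as np
import pandas as pd
import pytest

from dysnat import (
    CohortOptions,
    SodiumCategory,
    SynthConfig,
    admission_sodium,
    assign_patient_group,
    build_cohort,
    eligible_stays,
    generate_ehr,
)
from dysnat.cohort import read_cohort, write_cohort
from dysnat.errors import InputError

from conftest import make_tables
from oracles import oracle_cohort, oracle_ladder


def test_admission_sodium_first_of_day():
    """Two same-day values: the chronologically first one wins."""
    stay = pd.Series({"stay_id": "S1", "admit_date": "2011-06-01"})
    labs = pd.DataFrame({
        "stay_id": ["S1", "S1"],
        "timestamp": ["2011-06-01T14:00:00", "2011-06-01T08:00:00"],
        "analyte": ["sodium", "sodium"],
        "value": [136.0, 128.0],
    })
    assert admission_sodium(stay, labs) == 128.0


def test_admission_sodium_absent_when_only_day_two():
    stay = pd.Series({"stay_id": "S9", "admit_date": "2013-11-01"})
    labs = pd.DataFrame({
        "stay_id": ["S9"], "timestamp": ["2013-11-02T08:00:00"],
        "analyte": ["sodium"], "value": [120.0],
    })
    assert admission_sodium(stay, labs) is None


def test_admission_sodium_single_value():
    stay = pd.Series({"stay_id": "S1", "admit_date": "2011-01-01"})
    labs = pd.DataFrame({
        "stay_id": ["S1"], "timestamp": ["2011-01-01T10:00:00"],
        "analyte": ["sodium"], "value": [140.0],
    })
    assert admission_sodium(stay, labs) == 140.0


def test_eligible_stays_rules(ladder_tables):
    """1-day stay excluded; no-admission-sodium stay excluded; 2-day included."""
    elig = eligible_stays(ladder_tables)
    ids = set(elig["stay_id"])
    assert "S6" not in ids  # 1-day stay, sodium present
    assert "S9" not in ids  # 7-day stay, sodium only on day 2
    assert "S7" in ids      # exactly 2 days with admission sodium
    excl = elig.attrs["exclusions"]
    assert excl["n_stays_no_admission_sodium"] == 1
    assert excl["n_stays_short"] == 1


def test_eligible_stays_strict_rule(ladder_tables):
    """The configurable strict (> 2 days) variant also drops 2-day stays."""
    elig = eligible_stays(ladder_tables, CohortOptions(strict_greater=True))
    assert "S7" not in set(elig["stay_id"])
    assert "S8" in set(elig["stay_id"])


@pytest.mark.parametrize("cats,expected_cat,expected_idx", [
    (["normal", "borderline_hypo", "mild_hypo"], "mild_hypo", 2),
    (["borderline_hyper", "severe_hypo"], "borderline_hyper", 0),
    (["normal", "normal"], "normal", 0),
    (["severe_hyper", "mild_hyper", "severe_hypo"], "severe_hyper", 0),
    (["borderline_hypo", "borderline_hypo"], "borderline_hypo", 0),
])
def test_priority_ladder_examples(cats, expected_cat, expected_idx):
    stays = pd.DataFrame({
        "stay_id": [f"S{i}" for i in range(len(cats))],
        "admit_date": [f"2011-0{i + 1}-01" for i in range(len(cats))],
        "category": cats,
    })
    cat, idx = assign_patient_group(stays)
    assert cat is SodiumCategory(expected_cat)
    assert idx == f"S{expected_idx}"


def test_ladder_empty_input_rejected():
    with pytest.raises(InputError):
        assign_patient_group(pd.DataFrame(columns=["stay_id", "admit_date", "category"]))


def test_ladder_matches_bruteforce_on_random_populations():
    """Severity-priority assignment equals a nested-loop oracle on 1,000
    randomised patients with shuffled admission order."""
    rng = np.random.default_rng(42)
    cats = [c.value for c in SodiumCategory]
    for _ in range(1000):
        k = rng.integers(1, 7)
        chosen = rng.choice(cats, size=k)
        days = rng.choice(28, size=k, replace=False) + 1
        stays = pd.DataFrame({
            "stay_id": [f"S{i}" for i in range(k)],
            "admit_date": [f"2011-01-{d:02d}" for d in days],
            "category": chosen,
        })
        cat, idx = assign_patient_group(stays)
        ocat, oidx = oracle_ladder(list(stays.itertuples(index=False, name=None)))
        assert (cat.value, idx) == (ocat, oidx)


def test_build_cohort_handmade_fixture(ladder_tables):
    cohort, excl = build_cohort(ladder_tables)
    rows = cohort.set_index("patient_id")
    assert len(cohort) == 3
    assert rows.loc["P1", "category"] == "mild_hypo"
    assert rows.loc["P1", "index_stay_id"] == "S3"
    assert bool(rows.loc["P1", "death"]) is True
    assert rows.loc["P1", "charlson_raw"] == 2  # I21 + I50, I21.9 deduplicated
    assert rows.loc["P1", "n_codes"] == 3
    assert sorted(rows.loc["P1", "codes"]) == ["I21", "I50"]
    assert rows.loc["P2", "category"] == "borderline_hyper"
    assert bool(rows.loc["P2", "dementia"]) is True  # F03 on index stay
    assert rows.loc["P3", "category"] == "normal"
    assert rows.loc["P3", "index_stay_id"] == "S7"  # first eligible encounter
    assert rows.loc["P3", "los_band"] == "<=7"
    # age at index admission, floor of years: born 1985-12-31, admitted 2013-04-01
    assert rows.loc["P3", "age"] == 27
    assert rows.loc["P3", "age_band"] == "<30"
    assert excl["n_patients_included"] == 3


def test_build_cohort_empty_when_nothing_eligible():
    tables = make_tables(
        [{"patient_id": "P1", "sex": "F", "birth_date": "1950-01-01"}],
        [{"stay_id": "S1", "patient_id": "P1", "admit_date": "2011-01-01",
          "discharge_date": "2011-01-02"}],
        [("S1", "2011-01-01T08:00:00", "sodium", 140.0)],
        [],
    )
    cohort, excl = build_cohort(tables)
    assert cohort.empty
    assert excl["n_patients_included"] == 0


def test_build_cohort_rejects_orphan_rows():
    tables = make_tables(
        [{"patient_id": "P1", "sex": "F", "birth_date": "1950-01-01"}],
        [{"stay_id": "S1", "patient_id": "P1", "admit_date": "2011-01-01",
          "discharge_date": "2011-01-05"}],
        [("S999", "2011-01-01T08:00:00", "sodium", 140.0)],
        [],
    )
    with pytest.raises(InputError, match="S999"):
        build_cohort(tables)


def test_build_cohort_matches_bruteforce_oracle():
    """On a small synthetic population the vectorised extraction equals an
    independent nested-loop reimplementation exactly."""
    tables = generate_ehr(SynthConfig(n_patients=180, mean_stays_per_patient=2.2, seed=9))
    cohort, _ = build_cohort(tables)
    expected = oracle_cohort(tables)
    got = cohort[["patient_id", "category", "index_stay_id"]].reset_index(drop=True)
    pd.testing.assert_frame_equal(got, expected)
    assert not cohort["patient_id"].duplicated().any()


def test_priority_consistency_property(default_cohort):
    """Each patient's assigned category outranks (or equals) every eligible
    stay category and is attained by the index stay."""
    cohort, _ = default_cohort
    prio = {c.value: c.priority for c in SodiumCategory}
    assigned = cohort.set_index("patient_id")["category"].map(prio)
    assert (assigned >= 0).all()
    # the index stay's own category must equal the assigned category; verified
    # implicitly by the oracle test; here check uniqueness + banding coherence
    assert not cohort["patient_id"].duplicated().any()
    assert (cohort.loc[cohort["age"] >= 90, "age_band"] == ">=90").all()
    assert (cohort.loc[cohort["charlson_raw"] == 0, "charlson_band"] == "0").all()


def test_cohort_csv_roundtrip(tmp_path, default_cohort):
    cohort, excl = default_cohort
    path = write_cohort(cohort, excl, tmp_path)
    back = read_cohort(path)
    assert len(back) == len(cohort)
    assert list(back.loc[0, "codes"]) == list(cohort.loc[0, "codes"])
    assert back["death"].sum() == cohort["death"].sum()
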