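import numpy as np
import pandas as pd
import pytest

from dysnat import EhrTables, SynthConfig, build_cohort, generate_ehr


def make_tables(patients, stays, labs, diagnoses) -> EhrTables:
    """Build EhrTables from lists of dicts, filling defaults for stay flags."""
    stay_defaults = dict(ed_admission=0, icu=0, surgery=0, palliative=0, dialysis=0, death=0)
    return EhrTables(
        patients=pd.DataFrame(patients),
        stays=pd.DataFrame([{**stay_defaults, **s} for s in stays]),
        labs=pd.DataFrame(labs, columns=["stay_id", "timestamp", "analyte", "value"]),
        diagnoses=pd.DataFrame(diagnoses, columns=["stay_id", "icd10_code"]),
    )


@pytest.fixture
def ladder_tables() -> EhrTables:
    """Three hand-built patients hitting three ladder branches.

    P1: stays normal, borderline_hypo, mild_hypo  -> mild_hypo (its stay)
    P2: stays borderline_hyper, severe_hypo       -> borderline_hyper
    P3: stays normal, normal                      -> normal (first stay)
    Plus eligibility edge cases: a 1-day stay and a stay without an
    admission-day sodium, both to be excluded.
    """
    patients = [
        {"patient_id": "P1", "sex": "F", "birth_date": "1950-06-01"},
        {"patient_id": "P2", "sex": "M", "birth_date": "1940-01-15"},
        {"patient_id": "P3", "sex": "M", "birth_date": "1985-12-31"},
    ]
    stays = [
        {"stay_id": "S1", "patient_id": "P1", "admit_date": "2011-01-01", "discharge_date": "2011-01-05"},
        {"stay_id": "S2", "patient_id": "P1", "admit_date": "2011-03-01", "discharge_date": "2011-03-06"},
        {"stay_id": "S3", "patient_id": "P1", "admit_date": "2011-06-01", "discharge_date": "2011-06-09", "death": 1},
        {"stay_id": "S4", "patient_id": "P2", "admit_date": "2012-02-01", "discharge_date": "2012-02-04"},
        {"stay_id": "S5", "patient_id": "P2", "admit_date": "2012-05-01", "discharge_date": "2012-05-10"},
        # 1-day stay: excluded by duration even though sodium present
        {"stay_id": "S6", "patient_id": "P3", "admit_date": "2013-01-01", "discharge_date": "2013-01-02"},
        {"stay_id": "S7", "patient_id": "P3", "admit_date": "2013-04-01", "discharge_date": "2013-04-03"},
        {"stay_id": "S8", "patient_id": "P3", "admit_date": "2013-08-01", "discharge_date": "2013-08-06"},
        # no admission-day sodium: excluded
        {"stay_id": "S9", "patient_id": "P3", "admit_date": "2013-11-01", "discharge_date": "2013-11-08"},
    ]
    labs = [
        ("S1", "2011-01-01T08:00:00", "sodium", 140.0),
        ("S2", "2011-03-01T09:30:00", "sodium", 131.0),  # borderline_hypo
        # two same-day values: the 08:00 one (128, mild_hypo) must win
        ("S3", "2011-06-01T14:00:00", "sodium", 136.0),
        ("S3", "2011-06-01T08:00:00", "sodium", 128.0),
        ("S4", "2012-02-01T10:00:00", "sodium", 147.0),  # borderline_hyper
        ("S5", "2012-05-01T07:45:00", "sodium", 121.0),  # severe_hypo
        ("S6", "2013-01-01T08:00:00", "sodium", 138.0),
        ("S7", "2013-04-01T08:00:00", "sodium", 139.0),
        ("S8", "2013-08-01T12:00:00", "sodium", 141.0),
        ("S9", "2013-11-02T08:00:00", "sodium", 120.0),  # day 2 only
    ]
    diagnoses = [
        ("S3", "I21"), ("S3", "I50"), ("S3", "I21.9"),
        ("S4", "F03"),
        ("S7", "E11"),
    ]
    return make_tables(patients, stays, labs, diagnoses)


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort from the default generating model."""
    tables = generate_ehr(SynthConfig(n_patients=6000, seed=11))
    cohort, exclusions = build_cohort(tables)
    return cohort, exclusions


def null_cohort_frame(rng, n, death_rate=0.2, n_codes=50, code_prev=0.2) -> pd.DataFrame:
    """A minimal cohort frame with codes independent of death (global null)."""
    codes = np.array([f"Q{i:02d}" for i in range(n_codes)], dtype=object)
    incidence = rng.random((n, n_codes)) < code_prev
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "category": "normal",
        "death": rng.random(n) < death_rate,
        "codes": [list(codes[incidence[i]]) for i in range(n)],
    })
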