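"""One-row-per-patient analysis cohort from raw EHR tables.

Pipeline: eligibility filtering (admission-day sodium and a stay of at least
two days), seven-bin sodium categorisation, severity-priority patient
deduplication (hypernatremia before hyponatremia, severe before mild before
borderline, normals last at their first encounter), covariate banding,
Charlson comorbidity index and the death flag of the index stay.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .charlson import CharlsonMap, default_charlson_map, default_dementia_prefixes, normalize_code
from .errors import InputError
from .sodium import PRIORITY_LADDER, SodiumCategory, categorize_sodium, categorize_sodium_array
from .synthetic import EhrTables, STAY_FLAGS

log = logging.getLogger(__name__)

AGE_BANDS = ["<30", "[30;40)", "[40;50)", "[50;60)", "[60;70)", "[70;80)", "[80;90)", ">=90"]
LOS_BANDS = ["<=7", "(7;14]", "(14;21]", "(21;42]", ">42"]
NCODES_BANDS = ["<=1", "(1;4]", "(4;7]", "(7;10]", "(10;15]", "(15;20]", ">20"]
CHARLSON_BANDS = ["0", "1", "2", "3-4", "5-9", ">=10"]

#: Reference level of each banded covariate (used in univariate tables and models).
REFERENCE_LEVELS = {
    "age_band": "<30",
    "los_band": "<=7",
    "n_codes_band": "<=1",
    "charlson_band": "0",
    "sex": "F",
}


def age_band(age: float) -> str:
    if age < 30:
        return "<30"
    if age >= 90:
        return ">=90"
    lo = int(age // 10) * 10
    return f"[{lo};{lo + 10})"


def los_band(days: float) -> str:
    for hi, lab in ((7, "<=7"), (14, "(7;14]"), (21, "(14;21]"), (42, "(21;42]")):
        if days <= hi:
            return lab
    return ">42"


def n_codes_band(n: int) -> str:
    for hi, lab in ((1, "<=1"), (4, "(1;4]"), (7, "(4;7]"), (10, "(7;10]"),
                    (15, "(10;15]"), (20, "(15;20]")):
        if n <= hi:
            return lab
    return ">20"


def charlson_band(idx: int) -> str:
    if idx <= 2:
        return str(idx)
    if idx <= 4:
        return "3-4"
    if idx <= 9:
        return "5-9"
    return ">=10"


@dataclass
class CohortOptions:
    """Tunable extraction rules (paper-faithful defaults)."""

    min_duration_days: int = 2
    strict_greater: bool = False  # True: duration > min, False: duration >= min
    dementia_prefixes: list[str] = field(default_factory=default_dementia_prefixes)
    charlson_map: CharlsonMap = field(default_factory=default_charlson_map)
    sodium_analyte: str = "sodium"


def admission_sodium(stay: pd.Series, labs: pd.DataFrame, analyte: str = "sodium") -> float | None:
    """Chronologically first sodium on the admission calendar date, else None.

    Ties on the timestamp are broken by lab-table row order (deterministic).
    """
    if labs.empty:
        return None
    labs = labs[labs["analyte"].str.lower() == analyte.lower()]
    ts = pd.to_datetime(labs["timestamp"])
    admit_day = pd.to_datetime(stay["admit_date"]).normalize()
    on_day = labs[ts.dt.normalize() == admit_day]
    if on_day.empty:
        return None
    order = pd.to_datetime(on_day["timestamp"])
    return float(on_day.loc[order.sort_values(kind="stable").index[0], "value"])


def _admission_sodium_bulk(stays: pd.DataFrame, labs: pd.DataFrame, analyte: str) -> pd.Series:
    """Admission-day first sodium per stay_id (vectorised)."""
    na = labs[labs["analyte"].str.lower() == analyte.lower()].copy()
    if na.empty:
        return pd.Series(dtype=float)
    na["timestamp"] = pd.to_datetime(na["timestamp"])
    na = na.merge(
        stays[["stay_id", "admit_date"]].assign(
            admit_date=lambda d: pd.to_datetime(d["admit_date"]).dt.normalize()
        ),
        on="stay_id",
        how="left",
    )
    na = na[na["timestamp"].dt.normalize() == na["admit_date"]]
    na = na.sort_values(["stay_id", "timestamp"], kind="stable")
    first = na.drop_duplicates("stay_id", keep="first")
    return first.set_index("stay_id")["value"].astype(float)


def eligible_stays(tables: EhrTables, options: CohortOptions | None = None) -> pd.DataFrame:
    """Stays with an admission-day sodium and a qualifying duration.

    Returns the stay rows augmented with ``admission_na``, ``duration_days``
    and ``category`` columns. Exclusion counts are attached as ``.attrs``.
    """
    options = options or CohortOptions()
    stays = tables.stays.copy()
    stays["admit_date"] = pd.to_datetime(stays["admit_date"])
    stays["discharge_date"] = pd.to_datetime(stays["discharge_date"])
    stays["duration_days"] = (stays["discharge_date"] - stays["admit_date"]).dt.days

    adm_na = _admission_sodium_bulk(tables.stays, tables.labs, options.sodium_analyte)
    stays["admission_na"] = stays["stay_id"].map(adm_na)

    has_na = stays["admission_na"].notna()
    if options.strict_greater:
        long_enough = stays["duration_days"] > options.min_duration_days
    else:
        long_enough = stays["duration_days"] >= options.min_duration_days

    out = stays[has_na & long_enough].copy()
    out["category"] = [c.value for c in categorize_sodium_array(out["admission_na"].to_numpy())] if len(out) else []
    out.attrs["exclusions"] = {
        "n_stays_total": int(len(stays)),
        "n_stays_no_admission_sodium": int((~has_na).sum()),
        "n_stays_short": int((has_na & ~long_enough).sum()),
        "n_stays_eligible": int(len(out)),
    }
    return out


def assign_patient_group(stays: pd.DataFrame) -> tuple[SodiumCategory, str]:
    """Severity-priority group assignment for one patient's eligible stays.

    The ladder is severe_hyper > mild_hyper > borderline_hyper > severe_hypo
    > mild_hypo > borderline_hypo > normal; the index stay is the earliest
    stay exhibiting the chosen category (for all-normal patients, the first
    encounter).

    Parameters
    ----------
    stays : DataFrame with ``stay_id``, ``admit_date`` and ``category`` columns.
    """
    if len(stays) == 0:
        raise InputError("assign_patient_group requires at least one eligible stay")
    cats = {SodiumCategory(c) for c in stays["category"]}
    chosen = next(c for c in PRIORITY_LADDER if c in cats)
    sub = stays[stays["category"] == chosen.value]
    order = pd.to_datetime(sub["admit_date"])
    idx = order.sort_values(kind="stable").index[0]
    return chosen, str(sub.loc[idx, "stay_id"])


def build_cohort(
    tables: EhrTables, options: CohortOptions | None = None
) -> tuple[pd.DataFrame, dict]:
    """Compose the full extraction into a one-row-per-patient cohort table.

    Returns ``(cohort, exclusions)``. Covariates (stay flags, codes, length
    of stay, Charlson, dementia, death) are taken from the index stay.
    """
    options = options or CohortOptions()
    tables.validate()
    elig = eligible_stays(tables, options)
    exclusions = dict(elig.attrs["exclusions"])
    exclusions["n_patients_total"] = int(tables.patients["patient_id"].nunique())

    if elig.empty:
        cols = ["patient_id", "category", "index_stay_id", "age", "age_band", "sex",
                "los_days", "los_band", "n_codes", "n_codes_band",
                *STAY_FLAGS, "dementia", "charlson_raw", "charlson_band",
                "death", "codes"]
        exclusions["n_patients_included"] = 0
        return pd.DataFrame(columns=cols), exclusions

    # vectorised ladder: sort by (patient, priority desc, admit asc, row order)
    prio = {c.value: c.priority for c in SodiumCategory}
    elig = elig.assign(_prio=elig["category"].map(prio), _row=np.arange(len(elig)))
    elig = elig.sort_values(
        ["patient_id", "_prio", "admit_date", "_row"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    index_stays = elig.drop_duplicates("patient_id", keep="first").copy()

    # codes on the index stay
    diag = tables.diagnoses.copy()
    diag["icd10_code"] = diag["icd10_code"].map(normalize_code)
    code_lists = diag.groupby("stay_id")["icd10_code"].agg(lambda s: sorted(set(s)))
    index_stays["full_codes"] = index_stays["stay_id"].map(code_lists)
    index_stays["full_codes"] = index_stays["full_codes"].apply(
        lambda v: v if isinstance(v, list) else []
    )

    # Charlson: categorise each distinct code once, then union per patient
    cmap = options.charlson_map
    distinct = sorted({c for lst in index_stays["full_codes"] for c in lst})
    cat_of = {c: cmap.categories_for([c]) for c in distinct}

    def _charlson(codes: list[str]) -> int:
        cats = set().union(*(cat_of[c] for c in codes)) if codes else set()
        for winner, loser in cmap.supersedes.items():
            if winner in cats:
                cats.discard(loser)
        return sum(cmap.weights[c] for c in cats)

    dem_pref = tuple(options.dementia_prefixes)
    patients = tables.patients.set_index("patient_id")
    birth = pd.to_datetime(patients["birth_date"])

    rows = index_stays
    age = ((rows["admit_date"] - rows["patient_id"].map(birth)).dt.days / 365.25).apply(np.floor)
    n_codes = rows["full_codes"].apply(len)
    charl = rows["full_codes"].apply(_charlson)
    cohort = pd.DataFrame({
        "patient_id": rows["patient_id"].to_numpy(),
        "category": rows["category"].to_numpy(),
        "index_stay_id": rows["stay_id"].to_numpy(),
        "age": age.to_numpy(),
        "age_band": age.apply(age_band).to_numpy(),
        "sex": rows["patient_id"].map(patients["sex"]).to_numpy(),
        "los_days": rows["duration_days"].to_numpy(),
        "los_band": rows["duration_days"].apply(los_band).to_numpy(),
        "n_codes": n_codes.to_numpy(),
        "n_codes_band": n_codes.apply(n_codes_band).to_numpy(),
        **{f: rows[f].astype(bool).to_numpy() for f in STAY_FLAGS},
        "dementia": rows["full_codes"].apply(
            lambda codes: any(c.startswith(dem_pref) for c in codes)
        ).to_numpy(),
        "charlson_raw": charl.to_numpy(),
        "charlson_band": charl.apply(charlson_band).to_numpy(),
        "death": rows["death"].astype(bool).to_numpy(),
        "codes": rows["full_codes"].apply(
            lambda codes: sorted({c[:3] for c in codes})
        ).to_numpy(),
    })
    cohort = cohort.sort_values("patient_id", kind="stable").reset_index(drop=True)
    if cohort["patient_id"].duplicated().any():  # pragma: no cover - defensive
        raise InputError("duplicate patient_id in cohort")
    exclusions["n_patients_included"] = int(len(cohort))
    return cohort, exclusions


def write_cohort(cohort: pd.DataFrame, exclusions: dict, out_dir: str | Path) -> Path:
    """CSV + sidecar JSON of exclusion counts; ``codes`` serialised ';'-joined."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flat = cohort.copy()
    flat["codes"] = flat["codes"].apply(";".join)
    path = out_dir / "cohort.csv"
    flat.to_csv(path, index=False)
    (out_dir / "exclusions.json").write_text(json.dumps(exclusions, indent=2, sort_keys=True))
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "index_stay_id": str})
    df["codes"] = df["codes"].fillna("").apply(lambda s: [c for c in s.split(";") if c])
    for f in (*STAY_FLAGS, "dementia", "death"):
        df[f] = df[f].astype(bool)
    return df
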