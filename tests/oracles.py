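"""Independent brute-force reimplementations used as test oracles.

Deliberately written as plain nested loops over raw rows, sharing no code
with the package's vectorised implementations.
"""

from __future__ import annotations

import pandas as pd

LADDER = [
    "severe_hyper", "mild_hyper", "borderline_hyper",
    "severe_hypo", "mild_hypo", "borderline_hypo", "normal",
]


def oracle_categorize(v: float) -> str:
    if v < 125:
        return "severe_hypo"
    elif v < 130:
        return "mild_hypo"
    elif v < 135:
        return "borderline_hypo"
    elif v <= 145:
        return "normal"
    elif v <= 150:
        return "borderline_hyper"
    elif v <= 155:
        return "mild_hyper"
    return "severe_hyper"


def oracle_ladder(stays: list[tuple[str, str, str]]) -> tuple[str, str]:
    """(category, index_stay_id) from [(stay_id, admit_date, category), ...]."""
    for cat in LADDER:
        hits = [s for s in stays if s[2] == cat]
        if hits:
            best = min(hits, key=lambda s: (s[1], [x[0] for x in stays].index(s[0])))
            return cat, best[0]
    raise AssertionError("empty stay list")


def oracle_cohort(tables, min_days: int = 2) -> pd.DataFrame:
    """Straight-line nested-loop cohort extraction (patient, category, index stay)."""
    stays = tables.stays.to_dict("records")
    labs = tables.labs.to_dict("records")
    rows = []
    for pat in tables.patients.to_dict("records"):
        eligible = []
        for stay in stays:
            if stay["patient_id"] != pat["patient_id"]:
                continue
            admit = pd.Timestamp(stay["admit_date"])
            disch = pd.Timestamp(stay["discharge_date"])
            if (disch - admit).days < min_days:
                continue
            best_ts, best_val = None, None
            for lab in labs:
                if lab["stay_id"] != stay["stay_id"]:
                    continue
                if str(lab["analyte"]).lower() != "sodium":
                    continue
                ts = pd.Timestamp(lab["timestamp"])
                if ts.date() != admit.date():
                    continue
                if best_ts is None or ts < best_ts:
                    best_ts, best_val = ts, float(lab["value"])
            if best_val is None:
                continue
            eligible.append((stay["stay_id"], str(admit.date()), oracle_categorize(best_val)))
        if not eligible:
            continue
        cat, idx = oracle_ladder(eligible)
        rows.append({"patient_id": pat["patient_id"], "category": cat, "index_stay_id": idx})
    return pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)


def oracle_log_or(a: int, b: int, c: int, d: int) -> float:
    import math

    return math.log((a * d) / (b * c))
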