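"""End-to-end orchestration: simulate -> cohort -> describe -> phewas -> models.

Every stage writes plain-text artefacts (CSV/TSV/JSON) into the output
directory and the run ends with a manifest recording the seed, stage row
counts and a SHA-256 hash of every artefact, so reruns under the same
configuration can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .charlson import CharlsonMap, default_dementia_prefixes, normalize_code
from .cohort import CohortOptions, build_cohort, write_cohort
from .config import RunConfig
from .descriptive import or_table_frame, summarize_by_category, univariate_or_table
from .errors import DysnatError, InputError
from .models import standard_model_suite
from .phewas import manhattan_table, plot_manhattan, run_phewas, select_confounders
from .synthetic import EhrTables, generate_ehr, write_truth

log = logging.getLogger(__name__)

OR_FACTORS = ["category", "age_band", "sex", "los_band", "n_codes_band",
              "ed_admission", "surgery", "icu", "palliative", "dialysis",
              "dementia", "charlson_band"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    On a stage failure the partial outputs are kept, a ``FAILED`` marker file
    naming the stage is written, and the error is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "artifacts": {}}
    stage = "setup"
    try:
        # --- stage 1: tables ------------------------------------------------
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            tables = generate_ehr(config.simulate)
            tdir = out / "tables"
            tables.to_csv(tdir)
            write_truth(config.simulate, tdir / "truth.json")
        else:
            tables = EhrTables.from_csv(config.input_dir)
        report = validate_tables_frame(tables)
        if report["violations"]:
            raise InputError(f"input tables invalid: {report['violations'][:5]}")
        manifest["stages"][stage] = {
            "status": "complete",
            "n_patients": int(len(tables.patients)),
            "n_stays": int(len(tables.stays)),
        }

        # --- stage 2: cohort --------------------------------------------------
        stage = "cohort"
        opts = CohortOptions(
            min_duration_days=config.min_duration_days,
            strict_greater=config.strict_greater,
        )
        if config.charlson_map_path:
            opts.charlson_map = CharlsonMap.from_csv(config.charlson_map_path)
        if config.dementia_codes_path:
            opts.dementia_prefixes = [
                normalize_code(x)
                for x in pd.read_csv(config.dementia_codes_path, dtype=str)["prefix"]
            ]
        cohort, exclusions = build_cohort(tables, opts)
        write_cohort(cohort, exclusions, out)
        manifest["stages"]["cohort"] = {"status": "complete", "n_rows": int(len(cohort)),
                                        **exclusions}

        # --- stage 3: descriptive --------------------------------------------
        stage = "descriptive"
        summary = summarize_by_category(cohort)
        summary.to_frame().to_csv(out / "table1.tsv", sep="\t")
        ors = pd.concat(
            [or_table_frame(univariate_or_table(cohort, f)) for f in OR_FACTORS],
            ignore_index=True,
        )
        ors.to_csv(out / "table2.tsv", sep="\t", index=False)
        manifest["stages"]["descriptive"] = {"status": "complete",
                                             "n_or_rows": int(len(ors))}

        # --- stage 4: phewas --------------------------------------------------
        stage = "phewas"
        screens = {}
        for trait in ("death", "borderline_hypo", "borderline_hyper"):
            s = run_phewas(cohort, trait, config.alpha_family, config.phewas_comparison)
            screens[trait] = s
            s.results.to_csv(out / f"phewas_{trait}.tsv", sep="\t", index=False)
            manhattan_table(s).to_csv(out / f"manhattan_{trait}.tsv", sep="\t", index=False)
            if config.render_plots:
                plot_manhattan(s, out / f"manhattan_{trait}.png")
        confounders = {
            "borderline_hypo": sorted(select_confounders(screens["death"], screens["borderline_hypo"])),
            "borderline_hyper": sorted(select_confounders(screens["death"], screens["borderline_hyper"])),
        }
        (out / "confounders.json").write_text(json.dumps({
            "alpha_family": config.alpha_family,
            "m": {t: screens[t].m for t in screens},
            "threshold": {t: screens[t].threshold for t in screens},
            "confounders": confounders,
        }, indent=2, sort_keys=True))
        manifest["stages"]["phewas"] = {
            "status": "complete",
            "m": {t: screens[t].m for t in screens},
            "n_confounders": {k: len(v) for k, v in confounders.items()},
        }

        # --- stage 5: models --------------------------------------------------
        stage = "models"
        comparison_rows = []
        for exposure in ("borderline_hypo", "borderline_hyper"):
            fits = standard_model_suite(
                cohort, exposure, set(confounders[exposure]),
                classical=config.classical_covariates,
            )
            term = f"category[{exposure}]"
            for name in ("classical", "phewas", "combined", "final"):
                f = fits[name]
                row = f.odds_ratios().loc[term]
                comparison_rows.append({
                    "exposure": exposure, "model": name,
                    "odds_ratio": row["odds_ratio"], "ci_low": row["ci_low"],
                    "ci_high": row["ci_high"], "p_value": row["p_value"],
                    "aic": f.aic, "log_likelihood": f.llf, "k": f.k, "n": f.n,
                    "chosen_by_aic": f.spec.name == fits["chosen"].spec.name,
                })
                f.odds_ratios().assign(coef=f.params, se=f.bse).to_csv(
                    out / f"model_{exposure}_{name}.tsv", sep="\t")
        pd.DataFrame(comparison_rows).to_csv(out / "table4.tsv", sep="\t", index=False)
        manifest["stages"]["models"] = {"status": "complete",
                                        "n_rows": len(comparison_rows)}

    except Exception as e:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {e}\n")
        manifest["stages"][stage] = {"status": "failed", "error": str(e)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise DysnatError(f"pipeline failed at stage {stage!r}: {e}") from e

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json",):
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


SODIUM_PLAUSIBLE = (80.0, 200.0)  # mmol/L; outside this is almost surely a unit slip

REQUIRED_COLUMNS = {
    "patients": ["patient_id", "sex", "birth_date"],
    "stays": ["stay_id", "patient_id", "admit_date", "discharge_date",
              "ed_admission", "icu", "surgery", "palliative", "dialysis", "death"],
    "labs": ["stay_id", "timestamp", "analyte", "value"],
    "diagnoses": ["stay_id", "icd10_code"],
}


def validate_tables_frame(tables: EhrTables) -> dict:
    """Schema, referential-integrity and unit checks on in-memory tables."""
    violations: list[str] = []
    warnings: list[str] = []
    for name, cols in REQUIRED_COLUMNS.items():
        df = getattr(tables, name)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            violations.append(f"{name}: missing columns {missing}")
    if violations:
        return {"violations": violations, "warnings": warnings}

    pids = set(tables.patients["patient_id"])
    sids = set(tables.stays["stay_id"])
    for pid in sorted(set(tables.stays["patient_id"]) - pids)[:20]:
        violations.append(f"stays: unknown patient_id {pid}")
    for name in ("labs", "diagnoses"):
        for sid in sorted(set(getattr(tables, name)["stay_id"]) - sids)[:20]:
            violations.append(f"{name}: unknown stay_id {sid}")

    try:
        admit = pd.to_datetime(tables.stays["admit_date"])
        disch = pd.to_datetime(tables.stays["discharge_date"])
        for sid in tables.stays.loc[disch < admit, "stay_id"][:20]:
            violations.append(f"stays: discharge before admission for {sid}")
    except (ValueError, TypeError) as e:
        violations.append(f"stays: unparseable dates ({e})")

    na = tables.labs[tables.labs["analyte"].str.lower() == "sodium"]
    bad = na[(na["value"] < SODIUM_PLAUSIBLE[0]) | (na["value"] > SODIUM_PLAUSIBLE[1])]
    for _, row in bad.head(20).iterrows():
        warnings.append(
            f"labs: implausible sodium {row['value']} mmol/L for stay {row['stay_id']}"
        )

    death_stays = tables.stays[tables.stays["death"].astype(bool)]
    multi = death_stays["patient_id"].value_counts()
    for pid in multi[multi > 1].index[:20]:
        warnings.append(f"stays: patient {pid} has more than one death stay")
    return {"violations": violations, "warnings": warnings}


def validate_tables(in_dir: str | Path) -> dict:
    """Read the four CSVs and validate; I/O errors name the offending path."""
    tables = EhrTables.from_csv(in_dir)
    return validate_tables_frame(tables)
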