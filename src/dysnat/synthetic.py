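"""Synthetic multi-admission hospital EHR with known ground truth.

The generator emits the four relational tables the pipeline consumes
(patients, stays, labs, diagnoses) from an explicit generating model:

* each stay draws an admission serum sodium from a Gaussian (default
  138.3 +/- 3.9 mmol/L), so one patient can occupy different sodium
  categories across stays — exactly the situation the severity-priority
  deduplication has to resolve;
* in-hospital death follows a logistic model
  ``logit P(death) = b0 + b_cat(category) + sum_i b_i x_i`` in the stay's
  sodium category and binary stay covariates (plus optional age and sex
  terms); after a death stay no further stays are generated, so at most one
  death per patient and always the last stay;
* each ICD-10 billing code in the panel is assigned to a stay by one of two
  mechanisms. The default (``code_mechanism="outcome_conditional"``) samples
  codes with probability ``expit(logit(p0) + b_e * exposed + b_d * death)``
  where ``exposed`` indicates the configured exposure category — sampling
  conditionally on the realised death outcome gives closed-form target odds
  ratios, so planted marginal effects can be recovered from 2x2 tables.
  The alternative (``"causal"``) draws codes from exposure alone
  (``expit(logit(p0) + b_e * exposed)``) and adds ``b_d * code`` to the death
  linear predictor, making planted codes genuine confounders: the
  code-adjusted exposure coefficient then targets the configured ``b_cat``,
  which is what adjustment-recovery simulations need.

All ground-truth parameters are reported by :func:`ground_truth` for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError, InputError
from .sodium import SodiumCategory, categorize_sodium_array

EPOCH = pd.Timestamp("2010-01-01")
STAY_FLAGS = ("ed_admission", "icu", "surgery", "palliative", "dialysis")


@dataclass(frozen=True)
class CodeSpec:
    """One panel code: baseline prevalence and planted log odds ratios."""

    code: str
    baseline_prevalence: float
    log_or_vs_exposure: float = 0.0
    log_or_vs_death: float = 0.0


def _default_code_panel() -> list[CodeSpec]:
    """Thirteen dual-associated codes (sepsis, cardiac, respiratory, shock,
    aftercare ...) at their published-scale odds ratios, padded with null
    codes so screens have a realistic multiplicity burden."""
    ln = np.log
    planted = [
        CodeSpec("A41", 0.030, ln(5.83), ln(4.70)),
        CodeSpec("I20", 0.040, ln(0.67), ln(0.23)),
        CodeSpec("I25", 0.060, ln(0.53), ln(0.47)),
        CodeSpec("I48", 0.050, ln(0.62), ln(0.15)),
        CodeSpec("I71", 0.020, ln(0.66), ln(2.37)),
        CodeSpec("J15", 0.020, ln(2.75), ln(2.90)),
        CodeSpec("J80", 0.008, ln(3.10), ln(30.64)),
        CodeSpec("J96", 0.030, ln(2.29), ln(6.14)),
        CodeSpec("K65", 0.007, ln(3.19), ln(6.53)),
        CodeSpec("R07", 0.020, ln(0.35), ln(0.10)),
        CodeSpec("R57", 0.015, ln(3.56), ln(18.73)),
        CodeSpec("Z48", 0.080, ln(0.62), ln(0.63)),
        CodeSpec("Z51", 0.050, ln(1.95), ln(2.46)),
    ]
    null_codes = [
        "A09", "B96", "C18", "C34", "C50", "C61", "D64", "E03", "E11", "E66",
        "E78", "E87", "F10", "F32", "G40", "G47", "H25", "I10", "I21", "I35",
        "I50", "I63", "I80", "J18", "J44", "K21", "K29", "K57", "K80", "L02",
        "M17", "M54", "N17", "N18", "N39", "R10", "R26", "R50", "S06", "S72",
        "T81", "Z03", "Z08", "Z45", "Z86", "Z92", "Z95",
    ]
    panel = list(planted)
    for i, code in enumerate(null_codes):
        panel.append(CodeSpec(code, 0.005 + 0.012 * (i % 10)))
    return panel


@dataclass
class SynthConfig:
    """Generating model for the synthetic hospital population.

    The defaults emulate the reported study conditions: ~4% pooled
    in-hospital mortality, sodium 138.3 +/- 3.9 mmol/L per stay, 59.3% male,
    age 60.8 +/- 18.5 years, ICU 20.4%, emergency admission 12.1%, dialysis
    4.4%, palliative care 1.1%, and sodium-category mortality effects at the
    published adjusted odds ratios.
    """

    n_patients: int = 20_000
    mean_stays_per_patient: float = 1.3
    sodium_mean: float = 138.3
    sodium_sd: float = 3.9
    baseline_death_log_odds: float = -4.2
    category_death_log_odds: dict = field(default_factory=lambda: {
        "severe_hypo": float(np.log(3.44)),
        "mild_hypo": float(np.log(2.48)),
        "borderline_hypo": float(np.log(1.57)),
        "borderline_hyper": float(np.log(3.47)),
        "mild_hyper": float(np.log(4.42)),
        "severe_hyper": float(np.log(4.07)),
    })
    covariate_effects: dict = field(default_factory=lambda: {
        "icu": float(np.log(3.0)),
        "dialysis": float(np.log(2.5)),
        "palliative": float(np.log(5.0)),
        "ed_admission": float(np.log(1.5)),
        "surgery": 0.0,
        "age_per_decade": float(np.log(1.5)),
        "male": 0.0,
    })
    covariate_prevalence: dict = field(default_factory=lambda: {
        "icu": 0.204,
        "dialysis": 0.044,
        "palliative": 0.011,
        "ed_admission": 0.121,
        "surgery": 0.35,
    })
    code_panel: list = field(default_factory=_default_code_panel)
    exposure_category: str = "borderline_hypo"
    male_fraction: float = 0.593
    age_mean: float = 60.8
    age_sd: float = 18.5
    min_stay_days: int = 1
    stay_length_geom_p: float = 0.2
    p_missing_admission_sodium: float = 0.05
    extra_sodium_rate: float = 0.2
    subcode_rate: float = 0.2
    code_mechanism: str = "outcome_conditional"  # or "causal", see docstring
    seed: int = 0

    def __post_init__(self) -> None:
        self.code_panel = [
            c if isinstance(c, CodeSpec) else CodeSpec(**c) for c in self.code_panel
        ]
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ConfigError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        if self.mean_stays_per_patient < 1:
            raise ConfigError("mean_stays_per_patient must be >= 1")
        if not self.sodium_sd > 0:
            raise ConfigError(f"sodium_sd must be > 0, got {self.sodium_sd!r}")
        if self.min_stay_days < 0 or not isinstance(self.min_stay_days, (int, np.integer)):
            raise ConfigError("min_stay_days must be a non-negative integer")
        if not 0 < self.stay_length_geom_p <= 1:
            raise ConfigError("stay_length_geom_p must be in (0, 1]")
        for name in ("male_fraction", "p_missing_admission_sodium", "extra_sodium_rate", "subcode_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v!r}")
        valid_cats = {c.value for c in SodiumCategory}
        for k in self.category_death_log_odds:
            if k not in valid_cats:
                raise ConfigError(f"category_death_log_odds: unknown category {k!r}")
        if self.exposure_category not in valid_cats:
            raise ConfigError(f"exposure_category: unknown category {self.exposure_category!r}")
        for k, v in self.covariate_prevalence.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"covariate_prevalence[{k}] must be in [0, 1], got {v!r}")
        extras = set(self.covariate_effects) - set(self.covariate_prevalence) - {"age_per_decade", "male"}
        if extras:
            raise ConfigError(f"covariate_effects: unknown covariates {sorted(extras)}")
        seen = set()
        for spec in self.code_panel:
            if len(spec.code) != 3 or not spec.code[0].isalpha() or not spec.code[1:].isdigit():
                raise ConfigError(f"code_panel: code {spec.code!r} must be letter + two digits")
            if spec.code in seen:
                raise ConfigError(f"code_panel: duplicate code {spec.code!r}")
            seen.add(spec.code)
            if not 0 <= spec.baseline_prevalence <= 1:
                raise ConfigError(
                    f"code_panel[{spec.code}].baseline_prevalence must be in [0, 1]"
                )
        if self.code_mechanism not in ("outcome_conditional", "causal"):
            raise ConfigError(
                f"code_mechanism must be 'outcome_conditional' or 'causal', got {self.code_mechanism!r}"
            )
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")


@dataclass
class EhrTables:
    """The four raw relational tables (patients, stays, labs, diagnoses)."""

    patients: pd.DataFrame
    stays: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame

    def validate(self) -> None:
        """Referential integrity and basic invariants; raises ``InputError``."""
        pids = set(self.patients["patient_id"])
        sids = set(self.stays["stay_id"])
        orphan_stays = sorted(set(self.stays["patient_id"]) - pids)
        if orphan_stays:
            raise InputError(f"stays reference unknown patient_id: {orphan_stays[:10]}")
        for name, table in (("labs", self.labs), ("diagnoses", self.diagnoses)):
            orphans = sorted(set(table["stay_id"]) - sids)
            if orphans:
                raise InputError(f"{name} reference unknown stay_id: {orphans[:10]}")
        admit = pd.to_datetime(self.stays["admit_date"])
        disch = pd.to_datetime(self.stays["discharge_date"])
        if (disch < admit).any():
            bad = self.stays.loc[disch < admit, "stay_id"].tolist()[:10]
            raise InputError(f"discharge before admission for stays: {bad}")

    def to_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("patients", "stays", "labs", "diagnoses"):
            p = out_dir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def from_csv(cls, in_dir: str | Path) -> "EhrTables":
        in_dir = Path(in_dir)
        kw = {}
        for name in ("patients", "stays", "labs", "diagnoses"):
            p = in_dir / f"{name}.csv"
            if not p.exists():
                raise InputError(f"missing table file: {p}")
            kw[name] = pd.read_csv(p, dtype={"stay_id": str, "patient_id": str, "icd10_code": str})
        return cls(**kw)


def _exclusive_group_cumsum(values: np.ndarray, first: np.ndarray) -> np.ndarray:
    """Per-group exclusive cumulative sum for groups stored contiguously.

    ``first`` marks the first row of each group. O(n), no Python-level loop.
    """
    cs = np.cumsum(values)
    excl = cs - values
    group_base = excl[first]
    sizes = np.diff(np.append(np.flatnonzero(first), len(values)))
    return excl - np.repeat(group_base, sizes)


def generate_ehr(config: SynthConfig) -> EhrTables:
    """Draw one synthetic hospital population from the configured model.

    Deterministic: identical configs (including ``seed``) give identical
    tables, byte for byte when written as CSV.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # --- patients ---------------------------------------------------------
    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    male = rng.random(n) < config.male_fraction
    age0 = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 100.0)
    n_stays = 1 + rng.poisson(config.mean_stays_per_patient - 1.0, n)

    # --- stays (flat arrays, patients contiguous) -------------------------
    total = int(n_stays.sum())
    pidx = np.repeat(np.arange(n), n_stays)
    first = np.r_[True, pidx[1:] != pidx[:-1]]

    los = config.min_stay_days + rng.geometric(config.stay_length_geom_p, total) - 1
    gaps = rng.integers(14, 365, total)  # days between consecutive admissions
    first_offset = rng.integers(0, 1461, n)  # admissions spread over ~4 years
    # offset of stay k = first_offset + sum_{j<k}(los_j + gap_j)
    admit_offset = np.repeat(first_offset, n_stays) + _exclusive_group_cumsum(
        (los + gaps).astype(np.int64), first
    )

    sodium = rng.normal(config.sodium_mean, config.sodium_sd, total)
    cats = categorize_sodium_array(sodium)
    cat_names = np.array([c.value for c in cats], dtype=object)

    flags = {}
    for name in STAY_FLAGS:
        flags[name] = rng.random(total) < config.covariate_prevalence.get(name, 0.0)

    age_at_stay = np.repeat(age0, n_stays) + admit_offset / 365.25 - np.repeat(
        first_offset, n_stays
    ) / 365.25

    eff = config.covariate_effects
    lp = np.full(total, config.baseline_death_log_odds)
    for cat_name, beta in config.category_death_log_odds.items():
        lp += np.where(cat_names == cat_name, beta, 0.0)
    for name in STAY_FLAGS:
        lp += eff.get(name, 0.0) * flags[name]
    lp += eff.get("age_per_decade", 0.0) * (age_at_stay - config.age_mean) / 10.0
    lp += eff.get("male", 0.0) * np.repeat(male, n_stays)

    exposed = cat_names == config.exposure_category
    code_draws = rng.random((len(config.code_panel), total))
    n_codes = len(config.code_panel)
    hits = np.zeros((n_codes, total), dtype=bool)
    if config.code_mechanism == "causal":
        # codes depend on exposure only and feed the death model (confounders)
        for k, spec in enumerate(config.code_panel):
            p0 = float(np.clip(spec.baseline_prevalence, 1e-9, 1 - 1e-9))
            hits[k] = code_draws[k] < expit(logit(p0) + spec.log_or_vs_exposure * exposed)
            lp += spec.log_or_vs_death * hits[k]
        death = rng.random(total) < expit(lp)
    else:
        # codes sampled conditionally on the realised death outcome
        death = rng.random(total) < expit(lp)
        for k, spec in enumerate(config.code_panel):
            p0 = float(np.clip(spec.baseline_prevalence, 1e-9, 1 - 1e-9))
            hits[k] = code_draws[k] < expit(
                logit(p0) + spec.log_or_vs_exposure * exposed + spec.log_or_vs_death * death
            )

    # keep stays only up to (and including) a patient's first death stay
    deaths_before = _exclusive_group_cumsum(death.astype(np.int64), first)
    keep = deaths_before == 0

    missing_na = rng.random(total) < config.p_missing_admission_sodium
    extra_na = rng.random(total) < config.extra_sodium_rate
    extra_val = rng.normal(config.sodium_mean, config.sodium_sd, total)
    sub9 = rng.random((len(config.code_panel), total)) < config.subcode_rate

    idx = np.flatnonzero(keep)
    pidx, los, admit_offset = pidx[idx], los[idx], admit_offset[idx]
    sodium, cat_names, death = sodium[idx], cat_names[idx], death[idx]
    missing_na, extra_na, extra_val = missing_na[idx], extra_na[idx], extra_val[idx]
    age_at_stay = age_at_stay[idx]
    flags = {k: v[idx] for k, v in flags.items()}
    hits, sub9 = hits[:, idx], sub9[:, idx]
    m = len(idx)

    stay_ids = np.array([f"S{i:07d}" for i in range(m)])
    admit = EPOCH + pd.to_timedelta(admit_offset, unit="D")
    discharge = admit + pd.to_timedelta(los, unit="D")

    stays = pd.DataFrame({
        "stay_id": stay_ids,
        "patient_id": patient_ids[pidx],
        "admit_date": admit.strftime("%Y-%m-%d"),
        "discharge_date": discharge.strftime("%Y-%m-%d"),
        **{name: flags[name].astype(np.int8) for name in STAY_FLAGS},
        "death": death.astype(np.int8),
    })

    birth = EPOCH + pd.to_timedelta(first_offset - np.round(age0 * 365.25).astype(np.int64), unit="D")
    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "sex": np.where(male, "M", "F"),
        "birth_date": birth.strftime("%Y-%m-%d"),
    })

    # --- labs: admission-day sodium (sometimes missing), optional same-day
    # repeat at 14:00, and a day-2 value when the admission draw is missing --
    lab_rows = []
    has_adm = ~missing_na
    lab_rows.append(pd.DataFrame({
        "stay_id": stay_ids[has_adm],
        "timestamp": (admit[has_adm] + pd.Timedelta(hours=8)).strftime("%Y-%m-%dT%H:%M:%S"),
        "analyte": "sodium",
        "value": np.round(sodium[has_adm], 1),
    }))
    rep = has_adm & extra_na
    lab_rows.append(pd.DataFrame({
        "stay_id": stay_ids[rep],
        "timestamp": (admit[rep] + pd.Timedelta(hours=14)).strftime("%Y-%m-%dT%H:%M:%S"),
        "analyte": "sodium",
        "value": np.round(extra_val[rep], 1),
    }))
    late = missing_na & (los >= 1)
    lab_rows.append(pd.DataFrame({
        "stay_id": stay_ids[late],
        "timestamp": (admit[late] + pd.Timedelta(days=1, hours=9)).strftime("%Y-%m-%dT%H:%M:%S"),
        "analyte": "sodium",
        "value": np.round(extra_val[late], 1),
    }))
    labs = pd.concat(lab_rows, ignore_index=True).sort_values(
        ["stay_id", "timestamp"], kind="stable"
    ).reset_index(drop=True)

    # --- diagnoses from the pre-drawn code incidence matrix -----------------
    diag_frames = []
    for k, spec in enumerate(config.code_panel):
        hit = hits[k]
        codes = np.where(sub9[k][hit], spec.code + ".9", spec.code)
        diag_frames.append(pd.DataFrame({"stay_id": stay_ids[hit], "icd10_code": codes}))
    diagnoses = pd.concat(diag_frames, ignore_index=True).sort_values(
        ["stay_id", "icd10_code"], kind="stable"
    ).reset_index(drop=True)

    return EhrTables(patients=patients, stays=stays, labs=labs, diagnoses=diagnoses)


def ground_truth(config: SynthConfig) -> dict:
    """The exact generator parameters, keyed like fitted-model coefficients."""
    config.validate()
    truth: dict[str, object] = {"const": float(config.baseline_death_log_odds)}
    for cat in SodiumCategory:
        if cat is SodiumCategory.normal:
            continue
        truth[f"category[{cat.value}]"] = float(
            config.category_death_log_odds.get(cat.value, 0.0)
        )
    for name, beta in config.covariate_effects.items():
        truth[name] = float(beta)
    for spec in config.code_panel:
        truth[f"code[{spec.code}]:log_or_vs_exposure"] = float(spec.log_or_vs_exposure)
        truth[f"code[{spec.code}]:log_or_vs_death"] = float(spec.log_or_vs_death)
        truth[f"code[{spec.code}]:baseline_prevalence"] = float(spec.baseline_prevalence)
    truth["exposure_category"] = config.exposure_category
    return truth


def write_truth(config: SynthConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ground_truth(config), indent=2, sort_keys=True))


def config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a plain dict (e.g. a YAML ``simulate`` block)."""
    d = dict(d)
    if "code_panel" in d:
        d["code_panel"] = [
            CodeSpec(**c) if isinstance(c, dict) else c for c in d["code_panel"]
        ]
    try:
        return SynthConfig(**d)
    except TypeError as e:
        raise ConfigError(str(e)) from e
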