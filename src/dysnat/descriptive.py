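"""Stratified cohort summaries and univariate mortality odds ratios.

``summarize_by_category`` reproduces the logic of a Table-1-style summary:
counts and percentages for binary covariates (chi-squared across the seven
sodium groups, Fisher's exact for 2x2 tables with small expected cells),
means for age, medians with IQR for skewed variables (Kruskal-Wallis across
groups — a paired signed-rank test cannot compare independent groups, see
docs/methods.md). ``univariate_or_table`` gives per-level 2x2 odds ratios
for in-hospital death against each factor's reference level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_BANDS, CHARLSON_BANDS, LOS_BANDS, NCODES_BANDS, REFERENCE_LEVELS
from .errors import InputError
from .sodium import CATEGORY_ORDER
from .twobytwo import EXPECTED_MIN, odds_ratio_2x2

log = logging.getLogger(__name__)

CATEGORY_LABELS = [c.value for c in CATEGORY_ORDER]
BINARY_VARS = ["male", "icu", "palliative", "dialysis", "dementia", "ed_admission", "surgery"]
MEDIAN_VARS = {"n_codes": "Number of diagnosis codes", "los_days": "Length of stay (days)",
               "charlson_raw": "Charlson Comorbidity Index"}

LEVEL_ORDERS = {
    "category": CATEGORY_LABELS,
    "age_band": AGE_BANDS,
    "sex": ["F", "M"],
    "los_band": LOS_BANDS,
    "n_codes_band": NCODES_BANDS,
    "charlson_band": CHARLSON_BANDS,
}


def percent(count: int, n: int) -> float:
    """Percentage rounded to one decimal, as displayed in report tables."""
    return round(100.0 * count / n, 1)


@dataclass
class GroupSummary:
    """Per-category summary cells plus across-group p-values."""

    n_by_category: pd.Series  # index = category label
    cells: pd.DataFrame  # rows = variables, cols = category labels (display strings)
    p_values: pd.Series  # index = variables (NaN when untestable)

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out["p_value"] = self.p_values.reindex(out.index)
        return out


def _freq_p(cohort: pd.DataFrame, var: str, groups: list[str]) -> float:
    tab = pd.crosstab(cohort["category"], cohort[var]).reindex(groups).fillna(0)
    tab = tab.loc[tab.sum(axis=1) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return np.nan
    obs = tab.to_numpy()
    expected = stats.contingency.expected_freq(obs)
    if obs.shape == (2, 2) and expected.min() < EXPECTED_MIN:
        return float(stats.fisher_exact(obs)[1])
    if expected.min() < EXPECTED_MIN:
        log.warning("small expected cells in %s x category table; chi-squared p kept", var)
    return float(stats.chi2_contingency(obs, correction=False)[1])


def _rank_p(cohort: pd.DataFrame, var: str, groups: list[str]) -> float:
    samples = [g[var].to_numpy() for _, g in cohort.groupby("category") if len(g) > 0]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        return np.nan
    if len(samples) == 2:
        return float(stats.mannwhitneyu(samples[0], samples[1]).pvalue)
    return float(stats.kruskal(*samples).pvalue)


def summarize_by_category(cohort: pd.DataFrame) -> GroupSummary:
    """Table-1-style summary of the cohort stratified by sodium category."""
    if cohort.empty:
        raise InputError("cannot summarise an empty cohort")
    df = cohort.assign(male=cohort["sex"].eq("M"))
    groups = [g for g in CATEGORY_LABELS]
    n_by = df.groupby("category").size().reindex(groups).fillna(0).astype(int)
    single_group = (n_by > 0).sum() < 2
    if single_group:
        log.warning("only one non-empty sodium category; across-group p-values omitted")

    cells: dict[str, dict[str, str]] = {}
    pvals: dict[str, float] = {}

    cells["n"] = {g: str(n_by[g]) for g in groups}

    by = {g: df[df["category"] == g] for g in groups}
    cells["age_mean_sd"] = {
        g: (f"{by[g]['age'].mean():.0f} +/- {by[g]['age'].std():.0f}" if len(by[g]) else "")
        for g in groups
    }
    pvals["age_mean_sd"] = np.nan if single_group else _rank_p(df, "age", groups)

    for var in BINARY_VARS:
        cells[var] = {
            g: (f"{int(by[g][var].sum())} ({percent(int(by[g][var].sum()), len(by[g]))})"
                if len(by[g]) else "")
            for g in groups
        }
        pvals[var] = np.nan if single_group else _freq_p(df, var, groups)

    for var in MEDIAN_VARS:
        def fmt(s):
            if len(s) == 0:
                return ""
            q1, q2, q3 = np.percentile(s, [25, 50, 75])
            return f"{q2:g} ({q1:g}-{q3:g})"
        cells[var] = {g: fmt(by[g][var]) for g in groups}
        pvals[var] = np.nan if single_group else _rank_p(df, var, groups)

    cells["death"] = {
        g: (f"{int(by[g]['death'].sum())} ({percent(int(by[g]['death'].sum()), len(by[g]))})"
            if len(by[g]) else "")
        for g in groups
    }
    pvals["death"] = np.nan if single_group else _freq_p(df, "death", groups)

    cells_df = pd.DataFrame(cells).T.reindex(columns=groups)
    return GroupSummary(n_by_category=n_by, cells=cells_df, p_values=pd.Series(pvals))


@dataclass(frozen=True)
class UnivariateOr:
    """One factor level's 2x2 odds ratio for in-hospital death vs reference."""

    factor: str
    level: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool
    is_reference: bool = False


def _factor_levels(cohort: pd.DataFrame, factor: str) -> tuple[pd.Series, list[str], str]:
    if factor in LEVEL_ORDERS:
        col = cohort[factor].astype(str)
        order = [lv for lv in LEVEL_ORDERS[factor] if lv in set(col)]
        ref = "normal" if factor == "category" else REFERENCE_LEVELS[factor]
    else:  # binary flag
        col = cohort[factor].astype(bool).map({False: "no", True: "yes"})
        order = ["no", "yes"]
        ref = "no"
    return col, order, ref


def univariate_or_table(cohort: pd.DataFrame, factor: str) -> list[UnivariateOr]:
    """Per-level odds ratios of death vs the factor's reference level.

    Zero cells get the Haldane-Anscombe 0.5 correction and are flagged.
    """
    col, order, ref = _factor_levels(cohort, factor)
    death = cohort["death"].astype(bool)
    ref_mask = col == ref
    c = int((ref_mask & death).sum())
    d = int((ref_mask & ~death).sum())
    if c + d == 0:
        raise InputError(f"reference level {ref!r} of {factor!r} is empty")
    if c == 0 or d == 0:
        log.warning("reference level %r of %r has no %s; ORs use the 0.5 correction",
                    ref, factor, "deaths" if c == 0 else "survivors")
    out = [UnivariateOr(factor, ref, 1.0, np.nan, np.nan, np.nan, False, True)]
    for level in order:
        if level == ref:
            continue
        mask = col == level
        a = int((mask & death).sum())
        b = int((mask & ~death).sum())
        r = odds_ratio_2x2(a, b, c, d)
        out.append(UnivariateOr(factor, level, r.odds_ratio, r.ci_low, r.ci_high,
                                r.p_value, r.corrected))
    return out


def or_table_frame(results: list[UnivariateOr]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
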