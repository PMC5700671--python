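"""Phenome-wide screens over 3-character ICD-10 codes.

Three screens are run in the standard analysis: trait = in-hospital death
(whole cohort), trait = borderline hyponatremia and trait = borderline
hypernatremia (each compared against the normal-natremia reference group).
Every observed 3-character code is tested against the trait in a 2x2 table
(chi-squared score test, Fisher's exact when any expected cell is below 5);
the family-wise error is controlled by Bonferroni at ``alpha_family / m``
where m is the number of codes actually tested. Codes significant for both
death and a dysnatremia trait — in either direction — are the newly
identified confounders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .twobytwo import odds_ratio_2x2, odds_ratio_2x2_arrays

log = logging.getLogger(__name__)

TRAITS = ("death", "borderline_hypo", "borderline_hyper")


def truncate_to_three_chars(codes: Iterable[str]) -> set[str]:
    """Distinct 3-character prefixes of the given ICD-10 codes.

    >>> sorted(truncate_to_three_chars({"I21.4", "I21.9", "I50"}))
    ['I21', 'I50']
    """
    out = set()
    for code in codes:
        c = str(code).strip().upper()
        if len(c) < 3:
            raise ValidationError(f"ICD-10 code shorter than 3 characters: {code!r}")
        out.add(c[:3])
    return out


def trait_indicator(
    cohort: pd.DataFrame, trait: str, comparison: str = "normal"
) -> tuple[pd.DataFrame, pd.Series]:
    """Analysis subset and binary trait vector for one screen.

    For the dysnatremia traits the comparison group is the normal category
    (``comparison="normal"``) or the rest of the cohort (``"rest"``); the
    mortality screen uses the whole cohort.
    """
    if trait == "death":
        return cohort, cohort["death"].astype(bool)
    if trait not in TRAITS:
        raise InputError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    if comparison == "normal":
        sub = cohort[cohort["category"].isin([trait, "normal"])]
    elif comparison == "rest":
        sub = cohort
    else:
        raise InputError(f"comparison must be 'normal' or 'rest', got {comparison!r}")
    return sub, sub["category"].eq(trait)


@dataclass(frozen=True)
class AssociationResult:
    """One code x trait 2x2 test (a: code & trait ... d: neither)."""

    code: str
    trait: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool
    undefined: bool


@dataclass
class PhewasScreen:
    """Full screen for one trait with its Bonferroni threshold."""

    trait: str
    m: int
    alpha_family: float
    threshold: float
    results: pd.DataFrame  # one row per code, columns as AssociationResult
    significant: set[str] = field(default_factory=set)


def _counts_for_codes(sub: pd.DataFrame, y: pd.Series) -> pd.DataFrame:
    """Per-code 2x2 counts over the analysis subset (codes = 3-char sets)."""
    y = y.to_numpy(dtype=bool)
    n, n_trait = len(sub), int(y.sum())
    exploded = pd.DataFrame({
        "code": np.concatenate([np.array(c, dtype=object) for c in sub["codes"]])
        if len(sub) else np.array([], dtype=object),
        "trait": np.repeat(y, sub["codes"].apply(len).to_numpy()) if len(sub) else
        np.array([], dtype=bool),
    })
    g = exploded.groupby("code")["trait"].agg(["sum", "count"])
    counts = pd.DataFrame({
        "a": g["sum"].astype(int),
        "b": (g["count"] - g["sum"]).astype(int),
    })
    counts["c"] = n_trait - counts["a"]
    counts["d"] = (n - n_trait) - counts["b"]
    return counts.sort_index()


def code_trait_association(
    cohort: pd.DataFrame, code: str, trait: str,
    comparison: str = "normal", method: str = "chi2",
) -> AssociationResult:
    """Test one 3-character code against one trait.

    ``method="chi2"`` (default) uses the 2x2 score test with Fisher fallback;
    ``method="logit"`` fits a univariate logistic regression instead (same
    log-OR on clean tables, Wald p).
    """
    code = str(code).strip().upper()[:3]
    sub, y = trait_indicator(cohort, trait, comparison)
    has = sub["codes"].apply(lambda cs: code in cs).to_numpy(dtype=bool)
    yv = y.to_numpy(dtype=bool)
    a = int((has & yv).sum()); b = int((has & ~yv).sum())
    c = int((~has & yv).sum()); d = int((~has & ~yv).sum())
    if a + b == 0:
        log.warning("code %s absent from every analysed patient", code)
        return AssociationResult(code, trait, a, b, c, d, np.nan, np.nan, np.nan,
                                 1.0, False, True)
    if method == "logit":
        import statsmodels.api as sm

        X = sm.add_constant(has.astype(float))
        fit = sm.Logit(yv.astype(float), X).fit(disp=0)
        or_ = float(np.exp(fit.params[1]))
        lo, hi = (float(x) for x in np.exp(fit.conf_int()[1]))
        return AssociationResult(code, trait, a, b, c, d, or_, lo, hi,
                                 float(fit.pvalues[1]), False, False)
    r = odds_ratio_2x2(a, b, c, d)
    return AssociationResult(code, trait, a, b, c, d, r.odds_ratio, r.ci_low,
                             r.ci_high, r.p_value, r.corrected, r.undefined)


def run_phewas(
    cohort: pd.DataFrame, trait: str, alpha_family: float = 0.05,
    comparison: str = "normal",
) -> PhewasScreen:
    """Screen every observed 3-character code against one trait.

    m is the number of codes observed in the analysed subset; the Bonferroni
    threshold is ``alpha_family / m`` and significance is strict
    (``p < threshold``).
    """
    if not 0 < alpha_family < 1:
        raise InputError(f"alpha_family must be in (0, 1), got {alpha_family!r}")
    sub, y = trait_indicator(cohort, trait, comparison)
    counts = _counts_for_codes(sub, y)
    if counts.empty:
        log.warning("no ICD-10 codes observed; empty %s screen", trait)
        return PhewasScreen(trait, 0, alpha_family, np.nan,
                            pd.DataFrame(columns=["code", "a", "b", "c", "d"]), set())
    m = int(len(counts))
    threshold = alpha_family / m
    stats_ = odds_ratio_2x2_arrays(counts["a"], counts["b"], counts["c"], counts["d"])
    results = counts.reset_index().rename(columns={"index": "code"})
    for k in ("odds_ratio", "ci_low", "ci_high", "p_value", "corrected", "undefined"):
        results[k] = stats_[k]
    results["trait"] = trait
    results["significant"] = results["p_value"] < threshold
    sig = set(results.loc[results["significant"], "code"])
    return PhewasScreen(trait, m, alpha_family, threshold, results, sig)


def select_confounders(screen_mortality: PhewasScreen, screen_exposure: PhewasScreen) -> set[str]:
    """Codes significant in both screens, regardless of effect direction."""
    return set(screen_mortality.significant) & set(screen_exposure.significant)


def manhattan_table(screen: PhewasScreen) -> pd.DataFrame:
    """Plot-ready table: code, ICD-10 chapter letter, -log10(p), significance."""
    if screen.results.empty:
        return pd.DataFrame(columns=["code", "chapter", "neg_log10_p", "significant"])
    df = screen.results[["code", "p_value", "significant"]].copy()
    df["chapter"] = df["code"].str[0]
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_value"])
    return df[["code", "chapter", "neg_log10_p", "significant"]].sort_values(
        ["chapter", "code"], kind="stable"
    ).reset_index(drop=True)


def plot_manhattan(screen: PhewasScreen, path) -> None:
    """Optional PNG rendering of the Manhattan table (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = manhattan_table(screen)
    fig, ax = plt.subplots(figsize=(10, 4))
    chapters = sorted(tab["chapter"].unique())
    for i, ch in enumerate(chapters):
        sub = tab[tab["chapter"] == ch]
        ax.scatter(sub.index, sub["neg_log10_p"], s=8, label=ch,
                   color=plt.cm.tab20(i % 20))
    if np.isfinite(screen.threshold):
        ax.axhline(-np.log10(screen.threshold), ls="--", color="red", lw=1)
    ax.set_xlabel("ICD-10 code (grouped by chapter)")
    ax.set_ylabel("-log10(p)")
    ax.set_title(f"PheWAS: {screen.trait}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
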