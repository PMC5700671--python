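"""Multivariate logistic models of in-hospital death and AIC model choice.

The model is ``logit P(death) = b0 + b1 * (dysnatremia vs normal) +
sum_i b_i * confounder_i``. Three covariate sets are compared: the classical
set (age, length of stay, number of codes, emergency admission, ICU,
dialysis, palliative care, Charlson index — as categorical bands), the codes
found by the phenome-wide screens, and their union; the model with the lower
AIC wins and non-significant screen covariates are pruned by backward
elimination (classical covariates and the exposure are never removed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import REFERENCE_LEVELS
from .descriptive import LEVEL_ORDERS
from .errors import ComparabilityError, FitError, InputError
from .sodium import CATEGORY_ORDER

log = logging.getLogger(__name__)

#: Default classical confounders (sex and dementia deliberately not included;
#: see docs/methods.md).
CLASSICAL_COVARIATES = [
    "age_band", "los_band", "n_codes_band", "ed_admission", "icu",
    "dialysis", "palliative", "charlson_band",
]

BANDED = set(LEVEL_ORDERS) - {"category"}
BINARY_FLAGS = {"ed_admission", "icu", "surgery", "palliative", "dialysis", "dementia"}


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one mortality model.

    ``exposure`` is either ``"all"`` (one 7-level sodium factor, normal as
    reference) or a single category name (that category vs normal only; the
    cohort is subset to those two groups). Covariates are classical factor
    names and/or 3-character ICD-10 confounder codes.
    """

    name: str
    covariates: tuple = ()
    exposure: str = "all"

    def __post_init__(self):
        if len(set(self.covariates)) != len(self.covariates):
            raise InputError(f"duplicate covariates in model {self.name!r}")

    @property
    def code_covariates(self) -> list[str]:
        return [c for c in self.covariates if _is_code(c)]


def _is_code(name: str) -> bool:
    return len(name) == 3 and name[0].isalpha() and name[1:].isdigit()


@dataclass
class ModelFit:
    """A fitted logistic model with Wald inference."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    n: int
    converged: bool
    dropped_columns: list[str] = field(default_factory=list)
    row_key: int = 0  # hash of the analysed patient ids, for comparability

    @property
    def k(self) -> int:
        return int(len(self.params))

    def odds_ratios(self) -> pd.DataFrame:
        z = 1.959963984540054  # norm.ppf(0.975)
        or_ = np.exp(self.params)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                             "p_value": self.pvalues})


def design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Response, design matrix and the analysed cohort subset for one spec.

    Banded covariates are dummy-coded against their reference level; binary
    flags enter as 0/1; 3-character codes as presence indicators on the index
    stay. Returns ``(X, y, sub)``.
    """
    if spec.exposure == "all":
        sub = cohort
    else:
        if spec.exposure not in {c.value for c in CATEGORY_ORDER}:
            raise InputError(f"unknown exposure category {spec.exposure!r}")
        sub = cohort[cohort["category"].isin([spec.exposure, "normal"])]
    sub = sub.reset_index(drop=True)
    y = sub["death"].astype(float)

    cols: dict[str, np.ndarray] = {}
    cat_levels = [c.value for c in CATEGORY_ORDER if c.value != "normal"]
    if spec.exposure == "all":
        for lv in cat_levels:
            cols[f"category[{lv}]"] = sub["category"].eq(lv).to_numpy(float)
    else:
        cols[f"category[{spec.exposure}]"] = sub["category"].eq(spec.exposure).to_numpy(float)

    for cov in spec.covariates:
        if _is_code(cov):
            cols[f"code[{cov}]"] = sub["codes"].apply(lambda cs: cov in cs).to_numpy(float)
        elif cov in BANDED:
            ref = REFERENCE_LEVELS[cov]
            for lv in LEVEL_ORDERS[cov]:
                if lv != ref:
                    cols[f"{cov}[{lv}]"] = sub[cov].astype(str).eq(lv).to_numpy(float)
        elif cov in BINARY_FLAGS:
            cols[cov] = sub[cov].astype(float).to_numpy()
        elif cov == "sex":
            cols["sex[M]"] = sub["sex"].eq("M").to_numpy(float)
        elif cov in sub.columns:  # raw numeric covariate
            cols[cov] = sub[cov].astype(float).to_numpy()
        else:
            raise InputError(f"unknown covariate {cov!r}")

    X = pd.DataFrame(cols, index=sub.index)
    X.insert(0, "const", 1.0)
    return X, y, sub


def _drop_degenerate(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove constant columns, then complete a full-rank basis greedily."""
    dropped = [c for c in X.columns[1:] if X[c].nunique() <= 1]
    X = X.drop(columns=dropped)
    # greedy QR-style rank check, keeping earlier columns
    keep = ["const"]
    for c in X.columns[1:]:
        trial = X[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(c)
        else:
            dropped.append(c)
    if dropped:
        log.info("dropped degenerate design columns: %s", dropped)
    return X[keep], dropped


def _drop_quasi_separated(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Drop binary dummies whose level has a constant outcome.

    A 0/1 column with all deaths (or all survivors) on one side drives its
    ML coefficient to +/-inf (quasi-complete separation); the standard remedy
    for sparse extreme bands is to drop the term. Exposure terms are
    protected: their separation is an error, not a pruning opportunity.
    """
    yv = y.to_numpy(dtype=bool)
    dropped = []
    for c in X.columns[1:]:
        x = X[c].to_numpy()
        if set(np.unique(x)) <= {0.0, 1.0}:
            on, off = yv[x == 1.0], yv[x == 0.0]
            if len(on) and len(off) and (on.all() or (~on).all() or off.all() or (~off).all()):
                if c.startswith("category["):
                    raise FitError(f"exposure term {c} is completely separated")
                dropped.append(c)
    if dropped:
        log.info("dropped quasi-separated design columns: %s", dropped)
    return X.drop(columns=dropped), dropped


def _fix_reference_cells(X: pd.DataFrame, y: pd.Series, dropped: list[str]) -> pd.DataFrame:
    """Merge band levels into the reference while its outcome is constant.

    If every patient in a banded covariate's reference cell has the same
    outcome, the whole dummy block separates jointly (all coefficients drift
    to +/-inf together). Merging the lowest remaining level into the
    reference (by dropping its dummy) restores a finite optimum; repeats
    until every reference cell has both outcomes.
    """
    yv = y.to_numpy(dtype=bool)
    changed = True
    while changed:
        changed = False
        groups: dict[str, list[str]] = {}
        for c in X.columns[1:]:
            if "[" in c and not c.startswith(("category[", "code[", "sex[")):
                groups.setdefault(c.split("[")[0], []).append(c)
        for cols in groups.values():
            ref = X[cols].to_numpy().sum(axis=1) == 0
            if ref.any() and (yv[ref].all() or (~yv[ref]).all()):
                drop = cols[0]
                log.info("merging %s into its reference (constant-outcome reference cell)", drop)
                X = X.drop(columns=drop)
                dropped.append(drop)
                changed = True
                break
    return X


def fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood logistic fit of one model spec.

    Raises ``FitError`` naming the offending terms on non-convergence or
    (quasi-)complete separation of the exposure. Rows with any missing
    covariate are dropped with a logged count; degenerate or quasi-separated
    design columns are dropped and reported in ``dropped_columns``.
    """
    X, y, sub = design_matrix(cohort, spec)
    ok = X.notna().all(axis=1) & y.notna()
    n_dropped_rows = int((~ok).sum())
    if n_dropped_rows:
        log.info("dropped %d rows with missing covariates", n_dropped_rows)
        X, y, sub = X[ok], y[ok], sub[ok]
    if y.nunique() < 2:
        raise FitError("outcome has a single class in the analysed rows")
    X, dropped = _drop_degenerate(X)
    X, dropped_sep = _drop_quasi_separated(X, y)
    dropped = dropped + dropped_sep
    X = _fix_reference_cells(X, y, dropped)
    # iterate: a reference cell with a constant outcome separates jointly (all
    # dummies of the band explode together); dropping the worst dummy merges
    # its level into the reference and restores a finite optimum
    for _ in range(len(X.columns)):
        try:
            res = sm.Logit(y.to_numpy(), X).fit(disp=0, maxiter=200)
        except Exception as e:  # statsmodels raises PerfectSeparationError etc.
            raise FitError(f"logistic fit failed for model {spec.name!r}: {e}") from e
        if not res.mle_retvals.get("converged", False):
            raise FitError(f"model {spec.name!r} did not converge")
        big = res.params.drop("const", errors="ignore")
        big = big[np.abs(big) > 15]
        if big.empty:
            break
        exposed_terms = [t for t in big.index if t.startswith("category[")]
        if exposed_terms:
            raise FitError(f"model {spec.name!r}: separation of exposure terms {exposed_terms}")
        worst = big.abs().idxmax()
        log.info("dropping separated design column %s (beta = %.1f)", worst, big[worst])
        X = X.drop(columns=worst)
        dropped.append(worst)
    else:  # pragma: no cover - defensive
        raise FitError(f"model {spec.name!r}: could not resolve separation")
    row_key = int(pd.util.hash_pandas_object(sub["patient_id"]).sum() % (2**63))
    return ModelFit(
        spec=spec,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        aic=float(res.aic),
        n=int(len(y)),
        converged=True,
        dropped_columns=dropped,
        row_key=row_key,
    )


def classical_confounder_screen(cohort: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Classical factors associated with both sodium category and death.

    Association with the seven-level category uses one-way ANOVA for numeric
    factors and a chi-squared test for binary ones; association with death
    uses a univariate logistic regression (likelihood-ratio p). Factors
    passing both at ``p < alpha`` are returned (as the banded names used in
    model specs, where applicable).
    """
    from scipy import stats as sps

    numeric = {"age": "age_band", "los_days": "los_band", "n_codes": "n_codes_band",
               "charlson_raw": "charlson_band"}
    binary = {"sex": "sex", "ed_admission": "ed_admission", "icu": "icu",
              "surgery": "surgery", "palliative": "palliative",
              "dialysis": "dialysis", "dementia": "dementia"}
    selected = []
    y = cohort["death"].astype(float).to_numpy()
    for raw, model_name in {**numeric, **binary}.items():
        x = cohort[raw]
        if raw in numeric:
            groups = [g.to_numpy(float) for _, g in x.groupby(cohort["category"]) if len(g) > 1]
            p_cat = sps.f_oneway(*groups).pvalue if len(groups) > 1 else np.nan
            xnum = x.to_numpy(float)
        else:
            xb = x.eq("M") if raw == "sex" else x.astype(bool)
            tab = pd.crosstab(cohort["category"], xb)
            p_cat = (sps.chi2_contingency(tab, correction=False)[1]
                     if tab.shape[0] > 1 and tab.shape[1] > 1 else np.nan)
            xnum = xb.to_numpy(float)
        if np.std(xnum) == 0:
            continue
        X = sm.add_constant(xnum)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
            p_death = float(fit.llr_pvalue)
        except Exception:
            p_death = np.nan
        if np.isfinite(p_cat) and np.isfinite(p_death) and p_cat < alpha and p_death < alpha:
            selected.append(model_name)
    return selected


def compare_models(fits: list[ModelFit]) -> ModelFit:
    """The fit with minimal AIC; exact ties go to the fewer-parameter model."""
    fits = [f for f in fits if f.converged]
    if len(fits) < 2:
        raise InputError("compare_models needs at least two converged fits")
    if len({f.row_key for f in fits}) > 1 or len({f.n for f in fits}) > 1:
        raise ComparabilityError("model fits were not estimated on the same cohort rows")
    best = min(fits, key=lambda f: (f.aic, f.k))
    ties = [f for f in fits if f is not best and np.isclose(f.aic, best.aic, atol=1e-9)]
    if ties:
        log.warning("AIC tie between %s and %s; chose the fewer-parameter fit",
                    best.spec.name, [f.spec.name for f in ties])
    return best


def prune_to_final(cohort: pd.DataFrame, spec: ModelSpec, alpha: float = 0.05) -> ModelFit:
    """Backward-eliminate non-significant screen codes from a combined model.

    One code per iteration (the largest Wald p above ``alpha``) is removed
    and the model refit, until every remaining code has p <= alpha. Classical
    covariates and the exposure term are never candidates. Deterministic.
    """
    current = spec
    fit = fit_logistic(cohort, current)
    while True:
        code_terms = {f"code[{c}]": c for c in current.code_covariates
                      if f"code[{c}]" in fit.params.index}
        ps = {c: fit.pvalues[t] for t, c in code_terms.items()}
        over = {c: p for c, p in ps.items() if p > alpha}
        if not over:
            return fit
        worst = max(sorted(over), key=lambda c: over[c])
        log.info("pruning %s (p = %.3g)", worst, over[worst])
        current = ModelSpec(
            name="final",
            covariates=tuple(c for c in current.covariates if c != worst),
            exposure=current.exposure,
        )
        fit = fit_logistic(cohort, current)


def adjusted_or_report(fit: ModelFit, terms: list[str] | None = None) -> pd.DataFrame:
    """Per-term ORs with 95% CI and p, rounded to report precision (2 dp).

    Raises ``KeyError`` for a term not in the fit.
    """
    ors = fit.odds_ratios()
    if terms is not None:
        missing = [t for t in terms if t not in ors.index]
        if missing:
            raise KeyError(f"terms not in model {fit.spec.name!r}: {missing}")
        ors = ors.loc[terms]
    out = ors.copy()
    for col in ("odds_ratio", "ci_low", "ci_high"):
        out[col] = out[col].round(2)
    return out


def standard_model_suite(
    cohort: pd.DataFrame,
    exposure: str,
    phewas_codes: set[str],
    classical: list[str] | None = None,
) -> dict[str, ModelFit]:
    """Classical / PheWAS / combined fits, the AIC choice, and the pruned final.

    Returns a dict with keys ``classical``, ``phewas``, ``combined``,
    ``chosen`` (AIC winner among the first three) and ``final`` (combined
    model after significance pruning of screen codes).
    """
    classical = list(classical) if classical is not None else list(CLASSICAL_COVARIATES)
    codes = tuple(sorted(phewas_codes))
    fits = {
        "classical": fit_logistic(cohort, ModelSpec("classical", tuple(classical), exposure)),
        "phewas": fit_logistic(cohort, ModelSpec("phewas", codes, exposure)),
        "combined": fit_logistic(cohort, ModelSpec("combined", tuple(classical) + codes, exposure)),
    }
    fits["chosen"] = compare_models(list(fits.values()))
    fits["final"] = prune_to_final(
        cohort, ModelSpec("final", tuple(classical) + codes, exposure)
    )
    return fits
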