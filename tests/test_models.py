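import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from dysnat import (
    CodeSpec,
    ModelFit,
    ModelSpec,
    SynthConfig,
    adjusted_or_report,
    build_cohort,
    classical_confounder_screen,
    compare_models,
    fit_logistic,
    generate_ehr,
    prune_to_final,
)
from dysnat.errors import ComparabilityError, FitError, InputError

from oracles import oracle_log_or


def cohort_from_2x2(a, b, c, d, flag="icu") -> pd.DataFrame:
    """Cohort frame realising a single binary covariate x death 2x2 table."""
    n = a + b + c + d
    rows = {
        "patient_id": [f"P{i}" for i in range(n)],
        "category": ["normal"] * n,
        "death": [True] * a + [False] * b + [True] * c + [False] * d,
        flag: [True] * (a + b) + [False] * (c + d),
        "codes": [[] for _ in range(n)],
    }
    return pd.DataFrame(rows)


def test_intercept_only_closed_form():
    """On an all-normal cohort with 4% deaths the intercept is logit(0.04)."""
    cohort = cohort_from_2x2(2, 48, 2, 48)
    fit = fit_logistic(cohort, ModelSpec("null"))
    assert list(fit.params.index) == ["const"]  # category dummies dropped as constant
    assert fit.params["const"] == pytest.approx(float(logit(0.04)), abs=1e-6)
    assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf, abs=1e-8)


def test_single_binary_covariate_equals_cross_product():
    """One binary covariate: the ML coefficient equals the 2x2 log cross-product OR."""
    for a, b, c, d in [(12, 30, 7, 51), (20, 20, 10, 40), (5, 45, 25, 25)]:
        cohort = cohort_from_2x2(a, b, c, d)
        fit = fit_logistic(cohort, ModelSpec("uni", ("icu",)))
        assert fit.params["icu"] == pytest.approx(oracle_log_or(a, b, c, d), abs=1e-6)


def test_aic_identity_on_real_fits(default_cohort):
    cohort, _ = default_cohort
    for spec in (ModelSpec("m1", ("icu",), "borderline_hypo"),
                 ModelSpec("m2", ("icu", "age_band"), "borderline_hypo")):
        fit = fit_logistic(cohort, spec)
        assert fit.aic - (2 * fit.k - 2 * fit.llf) == pytest.approx(0.0, abs=1e-8)
        ors = fit.odds_ratios()
        assert np.allclose(ors["odds_ratio"], np.exp(fit.params))


def test_exposure_recovery_with_planted_confounders():
    """With b1 = log(2) for borderline hyponatremia and causal confounder
    codes in the spec, the fitted exposure coefficient lands within 3 SE."""
    panel = [
        CodeSpec("A41", 0.04, np.log(3.0), np.log(4.0)),
        CodeSpec("R57", 0.03, np.log(3.0), np.log(6.0)),
        CodeSpec("E11", 0.05),
    ]
    cfg = SynthConfig(
        n_patients=30_000, mean_stays_per_patient=1.0,
        category_death_log_odds={"borderline_hypo": float(np.log(2))},
        covariate_effects={}, code_panel=panel,
        code_mechanism="causal", seed=21,
    )
    cohort, _ = build_cohort(generate_ehr(cfg))
    fit = fit_logistic(cohort, ModelSpec("adj", ("A41", "R57"), "borderline_hypo"))
    term = "category[borderline_hypo]"
    assert abs(fit.params[term] - np.log(2)) < 3 * fit.bse[term]
    # unadjusted estimate is inflated by the positive confounding
    un = fit_logistic(cohort, ModelSpec("crude", (), "borderline_hypo"))
    assert un.params[term] > fit.params[term]


def _dummy_fit(name, aic, k, row_key=1) -> ModelFit:
    idx = [f"x{i}" for i in range(k)]
    s = pd.Series(np.zeros(k), index=idx)
    return ModelFit(ModelSpec(name), s, s, s, llf=-(aic - 2 * k) / 2, aic=aic,
                    n=100, converged=True, row_key=row_key)


def test_compare_models_minimal_aic():
    """AICs {8098.4, 11002, 7585.5} select the 7585.5 model."""
    fits = [_dummy_fit("classical", 8098.4, 3),
            _dummy_fit("phewas", 11002.0, 3),
            _dummy_fit("final", 7585.5, 3)]
    assert compare_models(fits).spec.name == "final"


def test_compare_models_tie_and_comparability():
    tie = [_dummy_fit("big", 100.0, 5), _dummy_fit("small", 100.0, 3)]
    assert compare_models(tie).spec.name == "small"
    with pytest.raises(ComparabilityError):
        compare_models([_dummy_fit("a", 10, 2, row_key=1), _dummy_fit("b", 12, 2, row_key=2)])
    with pytest.raises(InputError):
        compare_models([_dummy_fit("a", 10, 2)])


def test_pruning_removes_noise_code_and_is_deterministic():
    panel = [
        CodeSpec("A41", 0.05, np.log(3.0), np.log(5.0)),
        CodeSpec("E11", 0.10),  # pure noise
    ]
    cfg = SynthConfig(
        n_patients=20_000, mean_stays_per_patient=1.0,
        category_death_log_odds={"borderline_hypo": float(np.log(2))},
        covariate_effects={}, code_panel=panel, code_mechanism="causal", seed=22,
    )
    cohort, _ = build_cohort(generate_ehr(cfg))
    spec = ModelSpec("combined", ("A41", "E11"), "borderline_hypo")
    fit1 = prune_to_final(cohort, spec)
    assert "code[E11]" not in fit1.params.index
    assert "code[A41]" in fit1.params.index
    fit2 = prune_to_final(cohort, spec)
    pd.testing.assert_series_equal(fit1.params, fit2.params)
    # fixed point: pruning an already-clean model returns it unchanged
    clean = ModelSpec("combined", ("A41",), "borderline_hypo")
    direct = fit_logistic(cohort, clean)
    pruned = prune_to_final(cohort, clean)
    pd.testing.assert_series_equal(direct.params, pruned.params)


def test_classical_covariates_never_pruned():
    cfg = SynthConfig(n_patients=8_000, seed=23)
    cohort, _ = build_cohort(generate_ehr(cfg))
    spec = ModelSpec("combined", ("surgery", "icu"), "borderline_hypo")
    fit = prune_to_final(cohort, spec)
    # surgery has no mortality effect in the generator yet survives pruning
    assert "surgery" in fit.params.index


def test_adjusted_or_report_formatting():
    s = pd.Series({"const": -3.0, "category[borderline_hypo]": np.log(2), "icu": 0.0})
    se = pd.Series({"const": 0.2, "category[borderline_hypo]": 0.1, "icu": 0.05})
    fit = ModelFit(ModelSpec("m"), s, se, s * 0, llf=-10, aic=26, n=100, converged=True)
    rep = adjusted_or_report(fit, ["category[borderline_hypo]", "icu"])
    row = rep.loc["category[borderline_hypo]"]
    assert (row["odds_ratio"], row["ci_low"], row["ci_high"]) == (2.00, 1.64, 2.43)
    assert rep.loc["icu", "odds_ratio"] == 1.00
    with pytest.raises(KeyError, match="nope"):
        adjusted_or_report(fit, ["nope"])


def test_separated_exposure_raises():
    cohort = cohort_from_2x2(5, 0, 0, 20)
    cohort["category"] = ["borderline_hypo"] * 5 + ["normal"] * 20
    with pytest.raises(FitError):
        fit_logistic(cohort, ModelSpec("sep", (), "borderline_hypo"))


def make_screen_cohort(rng, n=6000):
    """Cohort where dialysis confounds (category-linked + deadly), ICU is
    deadly but category-independent, and surgery is pure noise."""
    cat = rng.choice(["normal", "borderline_hypo"], n, p=[0.8, 0.2])
    expo = cat == "borderline_hypo"
    dialysis = rng.random(n) < np.where(expo, 0.30, 0.05)
    icu = rng.random(n) < 0.2
    surgery = rng.random(n) < 0.35
    lp = -3.0 + 1.2 * dialysis + 1.0 * icu
    death = rng.random(n) < 1 / (1 + np.exp(-lp))
    age = rng.normal(60, 15, n)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)], "category": cat,
        "age": age, "sex": rng.choice(["M", "F"], n),
        "los_days": rng.integers(2, 30, n), "n_codes": rng.integers(0, 12, n),
        "charlson_raw": rng.integers(0, 6, n),
        "ed_admission": rng.random(n) < 0.12, "icu": icu, "surgery": surgery,
        "palliative": rng.random(n) < 0.01, "dialysis": dialysis,
        "dementia": rng.random(n) < 0.02, "death": death,
        "codes": [[] for _ in range(n)],
    })


def test_classical_confounder_screen_selects_dual_factors():
    """A factor linked to both category and death (dialysis) is selected; a
    factor linked to death only (ICU) or to nothing (surgery) is not —
    matching the role of surgery as the canonical exclusion example."""
    rng = np.random.default_rng(31)
    cohort = make_screen_cohort(rng)
    selected = classical_confounder_screen(cohort)
    assert "dialysis" in selected
    assert "icu" not in selected
    assert "surgery" not in selected
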