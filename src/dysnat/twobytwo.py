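"""2x2 contingency-table statistics.

The screen and the univariate tables both reduce to 2x2 tables of the form

    =========  ======  =========
               event   no event
    exposed      a        b
    unexposed    c        d
    =========  ======  =========

with OR = (a d) / (b c), Wald 95% CI on the log scale, a chi-squared score
test (no continuity correction) and Fisher's exact test whenever any
expected cell is below 5. Zero cells are handled with the Haldane-Anscombe
correction (add 0.5 to every cell) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_Z95 = stats.norm.ppf(0.975)
EXPECTED_MIN = 5.0


@dataclass(frozen=True)
class TwoByTwoResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # Haldane-Anscombe 0.5 applied
    test: str  # "chi2" or "fisher"
    undefined: bool  # no information (an entire margin empty)

    @property
    def log_or(self) -> float:
        return float(np.log(self.odds_ratio))

    @property
    def log_or_se(self) -> float:
        h = 0.5 if self.corrected else 0.0
        return float(np.sqrt(sum(1.0 / (x + h) for x in (self.a, self.b, self.c, self.d))))


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """OR, Wald 95% CI and p-value for one 2x2 table of non-negative counts."""
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 cell counts must be non-negative")
    n = a + b + c + d
    undefined = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if undefined:
        return TwoByTwoResult(a, b, c, d, np.nan, np.nan, np.nan, 1.0, False, "none", True)

    corrected = min(a, b, c, d) == 0
    h = 0.5 if corrected else 0.0
    aa, bb, cc, dd = a + h, b + h, c + h, d + h
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo, hi = np.exp(np.log(or_) - _Z95 * se), np.exp(np.log(or_) + _Z95 * se)

    expected = np.outer([a + b, c + d], [a + c, b + d]) / n
    if expected.min() < EXPECTED_MIN:
        p = stats.fisher_exact([[a, b], [c, d]])[1]
        test = "fisher"
    else:
        p = stats.chi2_contingency([[a, b], [c, d]], correction=False)[1]
        test = "chi2"
    return TwoByTwoResult(a, b, c, d, float(or_), float(lo), float(hi), float(p), corrected, test, False)


def odds_ratio_2x2_arrays(a, b, c, d):
    """Vectorised version over parallel count arrays.

    Returns a dict of arrays (odds_ratio, ci_low, ci_high, p_value, corrected,
    test, undefined). The chi-squared score p is computed in closed form; rows
    with any expected cell < 5 are recomputed with Fisher's exact test.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    undefined = ((a + b) == 0) | ((c + d) == 0) | ((a + c) == 0) | ((b + d) == 0)
    corrected = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0) & ~undefined

    h = np.where(corrected, 0.5, 0.0)
    aa, bb, cc, dd = a + h, b + h, c + h, d + h
    with np.errstate(divide="ignore", invalid="ignore"):
        or_ = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        log_or = np.log(or_)
        lo = np.exp(log_or - _Z95 * se)
        hi = np.exp(log_or + _Z95 * se)
        # Pearson chi-squared statistic without continuity correction.
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = np.where(undefined, 1.0, stats.chi2.sf(np.where(undefined, 0.0, chi2), df=1))
    test = np.where(undefined, "none", "chi2").astype(object)

    with np.errstate(divide="ignore", invalid="ignore"):
        emin = np.minimum.reduce([
            (a + b) * (a + c) / n,
            (a + b) * (b + d) / n,
            (c + d) * (a + c) / n,
            (c + d) * (b + d) / n,
        ])
    small = ~undefined & (emin < EXPECTED_MIN)
    for i in np.flatnonzero(small):
        p[i] = stats.fisher_exact([[a[i], b[i]], [c[i], d[i]]])[1]
        test[i] = "fisher"

    or_ = np.where(undefined, np.nan, or_)
    lo = np.where(undefined, np.nan, lo)
    hi = np.where(undefined, np.nan, hi)
    return {
        "odds_ratio": or_,
        "ci_low": lo,
        "ci_high": hi,
        "p_value": p,
        "corrected": corrected,
        "test": test,
        "undefined": undefined,
    }
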