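"""Serum-sodium categorisation.

Seven bins partition the positive real line. Normal natremia is
135 <= [Na] <= 145 mmol/L; hyponatremia is split into borderline
[130, 135), mild [125, 130) and severe (< 125); hypernatremia into
borderline (145, 150], mild (150, 155] and severe (> 155). The severity
ladder used for patient deduplication treats hypernatremia as higher
priority than hyponatremia, and within each arm severe > mild > borderline.
"""

from __future__ import annotations

import enum
import math

import numpy as np

from .errors import ValidationError


class SodiumCategory(enum.Enum):
    """Ordered sodium categories; ``priority`` drives cohort deduplication."""

    severe_hypo = "severe_hypo"
    mild_hypo = "mild_hypo"
    borderline_hypo = "borderline_hypo"
    normal = "normal"
    borderline_hyper = "borderline_hyper"
    mild_hyper = "mild_hyper"
    severe_hyper = "severe_hyper"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def priority(self) -> int:
        """Extraction priority: hyper arm first, then hypo arm, normal last."""
        return _PRIORITY[self]


#: Display/column order used in Table-1 style outputs (hypo -> hyper).
CATEGORY_ORDER = [
    SodiumCategory.severe_hypo,
    SodiumCategory.mild_hypo,
    SodiumCategory.borderline_hypo,
    SodiumCategory.normal,
    SodiumCategory.borderline_hyper,
    SodiumCategory.mild_hyper,
    SodiumCategory.severe_hyper,
]

_PRIORITY = {
    SodiumCategory.severe_hyper: 6,
    SodiumCategory.mild_hyper: 5,
    SodiumCategory.borderline_hyper: 4,
    SodiumCategory.severe_hypo: 3,
    SodiumCategory.mild_hypo: 2,
    SodiumCategory.borderline_hypo: 1,
    SodiumCategory.normal: 0,
}

#: Categories in decreasing extraction priority.
PRIORITY_LADDER = sorted(_PRIORITY, key=_PRIORITY.get, reverse=True)

# Bin edges for vectorised categorisation; right edges are inclusive for the
# hyper arm and the normal upper bound, exclusive for the hypo arm.
_EDGES = np.array([125.0, 130.0, 135.0, 145.0, 150.0, 155.0])


def categorize_sodium(value: float) -> SodiumCategory:
    """Map one serum sodium value (mmol/L) to its category.

    Boundaries: 135 and 145 are normal, 150 is borderline_hyper and 155 is
    mild_hyper; values below 125 are severe_hypo and above 155 severe_hyper.

    Raises
    ------
    ValidationError
        If ``value`` is missing, non-finite or not strictly positive.
    """
    if value is None or not isinstance(value, (int, float, np.floating, np.integer)):
        raise ValidationError(f"sodium value must be a finite positive number, got {value!r}")
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise ValidationError(f"sodium value must be a finite positive number, got {value!r}")
    if v < 125.0:
        return SodiumCategory.severe_hypo
    if v < 130.0:
        return SodiumCategory.mild_hypo
    if v < 135.0:
        return SodiumCategory.borderline_hypo
    if v <= 145.0:
        return SodiumCategory.normal
    if v <= 150.0:
        return SodiumCategory.borderline_hyper
    if v <= 155.0:
        return SodiumCategory.mild_hyper
    return SodiumCategory.severe_hyper


def categorize_sodium_array(values: np.ndarray) -> np.ndarray:
    """Vectorised :func:`categorize_sodium`; returns an object array of categories."""
    values = np.asarray(values, dtype=float)
    if values.size and (not np.all(np.isfinite(values)) or np.any(values <= 0)):
        bad = values[~(np.isfinite(values) & (values > 0))][:5]
        raise ValidationError(f"sodium values must be finite and positive; offenders include {bad.tolist()}")
    # searchsorted with side='right' makes each left edge belong to the upper
    # bin, which matches the hypo-arm half-open bins; the hyper arm needs its
    # right edges inclusive, so shift exact hits on 145/150/155 down one bin.
    idx = np.searchsorted(_EDGES, values, side="right")
    for edge, take_lower in ((145.0, 3), (150.0, 4), (155.0, 5)):
        idx[values == edge] = take_lower
    cats = np.array(CATEGORY_ORDER, dtype=object)
    return cats[idx]
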