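"""Charlson comorbidity index from ICD-10 diagnosis codes.

The index is the sum of the original Charlson weights over the distinct
comorbidity categories a patient's codes match, each category counted once.
Categories are matched by ICD-10 prefix using the mapping shipped in
``data/charlson_icd10.csv`` (an editable file, so sites can substitute their
own adaptation or updated weightings). A ``supersedes`` column encodes the
usual hierarchy: metastatic disease absorbs any-malignancy, moderate/severe
liver disease absorbs mild, diabetes with complications absorbs diabetes
without.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ValidationError

#: Letter + two digits, optionally a dot and up to four alphanumerics.
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[0-9A-Z]{1,4})?$", re.IGNORECASE)


def normalize_code(code: str) -> str:
    """Upper-case and strip the dot: ``'i21.9' -> 'I219'``."""
    return str(code).strip().upper().replace(".", "")


def validate_codes(codes: Iterable[str]) -> list[str]:
    """Return normalised codes; raise listing every malformed offender."""
    codes = [str(c) for c in codes]
    bad = [c for c in codes if not ICD10_RE.match(c.strip())]
    if bad:
        raise ValidationError(f"malformed ICD-10 codes: {sorted(set(bad))}")
    return [normalize_code(c) for c in codes]


@dataclass(frozen=True)
class CharlsonMap:
    """Prefix -> (category, weight) mapping plus the category hierarchy."""

    weights: dict[str, int]  # category -> weight
    prefixes: list[tuple[str, str]]  # (icd10 prefix, category), longest first
    supersedes: dict[str, str]  # category -> category it absorbs

    @classmethod
    def from_csv(cls, path: str | Path) -> "CharlsonMap":
        df = pd.read_csv(path, dtype=str).fillna("")
        weights, pref, sup = {}, [], {}
        for row in df.itertuples(index=False):
            weights[row.category] = int(row.weight)
            if row.supersedes:
                sup[row.category] = row.supersedes
            for p in str(row.prefixes).split(";"):
                p = normalize_code(p)
                if p:
                    pref.append((p, row.category))
        pref.sort(key=lambda t: len(t[0]), reverse=True)
        return cls(weights=weights, prefixes=pref, supersedes=sup)

    def categories_for(self, codes: Iterable[str]) -> set[str]:
        norm = validate_codes(codes)
        cats = {cat for code in norm for p, cat in self.prefixes if code.startswith(p)}
        for winner, loser in self.supersedes.items():
            if winner in cats:
                cats.discard(loser)
        return cats


def default_charlson_map() -> CharlsonMap:
    with resources.as_file(resources.files("dysnat.data") / "charlson_icd10.csv") as p:
        return CharlsonMap.from_csv(p)


def default_dementia_prefixes() -> list[str]:
    with resources.as_file(resources.files("dysnat.data") / "dementia_codes.csv") as p:
        return [normalize_code(x) for x in pd.read_csv(p, dtype=str)["prefix"]]


def charlson_index(codes: Iterable[str], mapping: CharlsonMap | None = None) -> int:
    """Charlson comorbidity index for one patient's set of ICD-10 codes.

    >>> charlson_index({"I21", "I50"})
    2
    >>> charlson_index({"I21", "I21.9"})
    1
    """
    mapping = mapping or default_charlson_map()
    cats = mapping.categories_for(codes)
    return sum(mapping.weights[c] for c in cats)
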