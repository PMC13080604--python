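"""Zung Self-Rating Depression (SDS) and Anxiety (SAS) scale scoring.

Both scales have 20 items rated 1–4.  Reverse-keyed items contribute
``5 − response``; the raw total (20–80) is multiplied by 1.25 and
rounded half-up to give the standard score, which the Chinese norms cut
into severity bands:

* SDS: <53 none, 53–62 mild, 63–72 moderate-to-severe, >72 severe
* SAS: <50 none, 50–59 mild, 60–69 moderate, >=70 severe

The canonical Zung reverse keys ship as defaults (SDS: items 2, 5, 6,
11, 12, 14, 16, 17, 18, 20; SAS: items 5, 9, 13, 17, 19) and can be
overridden per :class:`ScaleDefinition`.  A screen is positive at or
above the first category cut (53 for SDS, 50 for SAS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScaleDefinition", "ScaleResult", "SDS", "SAS",
    "score_scale", "scale_positive", "ScaleScorer",
]


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    reverse_items: frozenset[int]  # 1-based item indices
    category_cuts: tuple[int, int, int]  # ascending standard-score breakpoints
    category_names: tuple[str, str, str, str]
    n_items: int = 20
    multiplier: float = 1.25

    def __post_init__(self):
        if not self.reverse_items <= set(range(1, self.n_items + 1)):
            raise ValueError("reverse_items must be item indices in 1..n_items")
        if list(self.category_cuts) != sorted(set(self.category_cuts)):
            raise ValueError("category_cuts must be strictly increasing")


SDS = ScaleDefinition(
    name="SDS",
    reverse_items=frozenset({2, 5, 6, 11, 12, 14, 16, 17, 18, 20}),
    category_cuts=(53, 63, 73),
    category_names=("none", "mild", "moderate-to-severe", "severe"),
)

SAS = ScaleDefinition(
    name="SAS",
    reverse_items=frozenset({5, 9, 13, 17, 19}),
    category_cuts=(50, 60, 70),
    category_names=("none", "mild", "moderate", "severe"),
)


@dataclass(frozen=True)
class ScaleResult:
    raw: int
    standard: int
    standard_exact: float  # raw × 1.25 before rounding
    category: str
    positive: bool


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def score_scale(items, definition: ScaleDefinition) -> ScaleResult:
    """Score one subject's 20 responses.

    Reverse-keyed items contribute ``5 − v``; raw = sum of contributions;
    standard = round-half-up(raw × 1.25); the category comes from the
    definition's cuts, with intervals left-closed at each cut.
    """
    items = list(items)
    if len(items) != definition.n_items:
        raise ValueError(
            f"{definition.name} needs exactly {definition.n_items} responses, "
            f"got {len(items)}"
        )
    raw = 0
    for idx, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{definition.name} item {idx} is missing")
        v = int(v)
        if not (1 <= v <= 4):
            raise ValueError(
                f"{definition.name} item {idx} out of range 1–4: {v}"
            )
        raw += (5 - v) if idx in definition.reverse_items else v
    exact = raw * definition.multiplier
    standard = _round_half_up(exact)
    category = definition.category_names[
        int(np.searchsorted(definition.category_cuts, standard, side="right"))
    ]
    return ScaleResult(
        raw=raw,
        standard=standard,
        standard_exact=exact,
        category=category,
        positive=standard >= definition.category_cuts[0],
    )


def scale_positive(result: ScaleResult, definition: ScaleDefinition) -> bool:
    """Binary screen: positive iff standard >= the first category cut."""
    return result.standard >= definition.category_cuts[0]


class ScaleScorer(BaseEstimator, TransformerMixin):
    """Score a table of item responses into raw/standard/category columns.

    A stateless sklearn transformer over a DataFrame whose item columns
    are ``{prefix}1 .. {prefix}20`` (default prefix matches the
    synthetic cohort tables, e.g. ``sds_item_``).

    Parameters
    ----------
    definition : ScaleDefinition, default SDS
    item_prefix : str, optional
        Defaults to ``"{name.lower()}_item_"``.
    """

    def __init__(self, definition: ScaleDefinition = SDS, item_prefix: str | None = None):
        self.definition = definition
        self.item_prefix = item_prefix

    def _columns(self) -> list[str]:
        prefix = self.item_prefix or f"{self.definition.name.lower()}_item_"
        return [f"{prefix}{i}" for i in range(1, self.definition.n_items + 1)]

    def fit(self, X, y=None):
        missing = [c for c in self._columns() if c not in X.columns]
        if missing:
            raise ValueError(f"missing item columns: {missing}")
        self.columns_ = self._columns()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = self._columns()
        name = self.definition.name.lower()
        out = []
        for _, row in X[cols].iterrows():
            r = score_scale(row.tolist(), self.definition)
            out.append({f"{name}_raw": r.raw, f"{name}_standard": r.standard,
                        f"{name}_category": r.category,
                        f"{name}_positive": int(r.positive)})
        return pd.DataFrame(out, index=X.index)
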