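"""Feature strength scoring from occurrence counts and encoded data.

Three quantities make up an item's strength:

* ``W(n)`` — a feature's occurrence count normalised over the included
  feature set,
* ``W(value)`` — the empirical frequency of one of its levels in the
  encoded dataset,
* ``W(t) = W(n) * W(value)`` — the total item weight used by the miner.

All weights are kept at full float precision; two-decimal rounding exists
only for display (:func:`round2`, round-half-up).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .data_io import OccurrenceTable
from .preprocessing import EncodedRecord
from .vocab import FEATURES

__all__ = [
    "WeightTable",
    "select_significant",
    "feature_weight",
    "value_weight",
    "total_weight",
    "build_weight_table",
    "round2",
    "DEFAULT_THRESHOLD",
]

#: Occurrence-count threshold ("appeared more than N times") for significance.
DEFAULT_THRESHOLD = 10


class WeightDomainError(ValueError):
    """Weights requested from an empty or inconsistent basis."""


def round2(x: float) -> float:
    """Round half-up to two decimals — display only, never fed back in."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def select_significant(counts: OccurrenceTable, threshold: int = DEFAULT_THRESHOLD) -> list[str]:
    """Features whose count is strictly greater than *threshold*, canonical order."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [f for f in FEATURES if counts[f] > threshold]


def feature_weight(counts: OccurrenceTable, included: Sequence[str], feature: str) -> float:
    """Normalised occurrence weight of *feature* over the *included* set."""
    if feature not in included:
        raise WeightDomainError(f"{feature!r} is not in the included feature set")
    denom = counts.total(included)
    if denom <= 0:
        raise WeightDomainError("total occurrence count over included features is zero")
    return counts[feature] / denom


def value_weight(dataset: Sequence[EncodedRecord], feature: str, level: str) -> float:
    """Fraction of records whose *feature* takes *level*."""
    if not dataset:
        raise WeightDomainError("cannot compute value weights on an empty dataset")
    if feature not in dataset[0].features:
        raise WeightDomainError(f"{feature!r} absent from the encoded dataset")
    hits = sum(1 for r in dataset if r.features[feature] == level)
    return hits / len(dataset)


def total_weight(w_n: float, w_value: float) -> float:
    """Total item weight: the product of the two component weights."""
    if not (0.0 <= w_n <= 1.0 and 0.0 <= w_value <= 1.0):
        raise WeightDomainError("component weights must lie in [0, 1]")
    return w_n * w_value


@dataclass(frozen=True)
class WeightTable:
    """Item strength weights over an included feature set.

    ``feature_weights`` sum to 1 over the included features and, per
    feature, ``value_weights`` sum to 1 over its observed levels.
    """

    feature_weights: Mapping[str, float]
    value_weights: Mapping[tuple[str, str], float]

    def item_weight(self, feature: str, level: str) -> float:
        """``W(t)`` for one (feature, level) item."""
        try:
            return total_weight(
                self.feature_weights[feature], self.value_weights[(feature, level)]
            )
        except KeyError:
            raise KeyError(f"item ({feature!r}, {level!r}) not in weight table") from None

    def __contains__(self, item: tuple[str, str]) -> bool:
        return tuple(item) in self.value_weights

    @property
    def features(self) -> list[str]:
        return [f for f in FEATURES if f in self.feature_weights]

    def max_item_weight(self) -> float:
        return max(self.item_weight(f, lv) for f, lv in self.value_weights)


def build_weight_table(
    counts: OccurrenceTable,
    included: Sequence[str],
    dataset: Sequence[EncodedRecord],
) -> WeightTable:
    """Assemble the full weight table for *included* features.

    Value weights are computed from the (cleaned, encoded) dataset; only
    levels actually observed get an entry, so per-feature value weights
    always sum to 1.
    """
    if not dataset:
        raise WeightDomainError("cannot build a weight table from an empty dataset")
    missing = [f for f in included if f not in dataset[0].features]
    if missing:
        raise WeightDomainError(f"dataset not encoded over included features: {missing}")
    fw = {f: feature_weight(counts, included, f) for f in included}
    vw: dict[tuple[str, str], float] = {}
    for f in included:
        levels = sorted({r.features[f] for r in dataset})
        for lv in levels:
            vw[(f, lv)] = value_weight(dataset, f, lv)
    return WeightTable(feature_weights=fw, value_weights=vw)
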