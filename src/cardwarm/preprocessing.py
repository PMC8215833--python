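"""Record cleaning, outcome binarisation and clinical discretisation.

Numeric attributes are mapped onto fixed clinical bins and coded attributes
onto named levels, producing purely categorical records suitable for
association mining.  The bundled default scheme resolves the printed range
overlaps with a half-open convention: each numeric bin is ``[lo, hi)``
except where a strict ``> cut`` is part of the published vocabulary
(maximum heart rate and ST depression), which use ``(lo, hi]``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .vocab import CLASS_FEATURE, FEATURES, HEART_DISEASE, NO_HEART_DISEASE
from .data_io import RawRecord

__all__ = [
    "NumericBinning",
    "DiscretizationScheme",
    "EncodedRecord",
    "default_scheme",
    "drop_incomplete",
    "binarize_goal",
    "discretize",
    "encode_dataset",
    "canonical_level",
]


class DomainError(ValueError):
    """A value falls outside a feature's legal domain."""


@dataclass(frozen=True)
class NumericBinning:
    """Ordered bins over the real line.

    ``cuts`` are the interior boundaries; ``labels`` has one more entry than
    ``cuts``.  With ``right=False`` bins are ``[lo, hi)`` so a value equal to
    a cut belongs to the bin above it; with ``right=True`` bins are
    ``(lo, hi]`` and the value stays below.  The outermost bins extend to
    +/- infinity so every real number has a label.
    """

    cuts: tuple[float, ...]
    labels: tuple[str, ...]
    right: bool = False

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly len(cuts) + 1 labels")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cuts must be strictly increasing")

    def label_for(self, x: float) -> str:
        if self.right:
            return self.labels[bisect.bisect_left(self.cuts, x)]
        return self.labels[bisect.bisect_right(self.cuts, x)]


# Alternate spellings seen in the wild, folded to the canonical vocabulary.
_LEVEL_ALIASES = {"reversable": "reversible", "very high": "veryHigh"}


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-feature binning/coding plus the binary outcome map."""

    numeric: Mapping[str, NumericBinning]
    coded: Mapping[str, Mapping[int, str]]

    def __post_init__(self) -> None:
        covered = set(self.numeric) | set(self.coded)
        both = set(self.numeric) & set(self.coded)
        if both:
            raise ValueError(f"features both numeric and coded: {sorted(both)}")
        missing = set(FEATURES) - covered
        if missing:
            raise ValueError(f"scheme does not cover: {sorted(missing)}")
        extra = covered - set(FEATURES)
        if extra:
            raise ValueError(f"scheme names unknown features: {sorted(extra)}")

    def levels(self, feature: str) -> tuple[str, ...]:
        """Legal level labels for *feature*, in scheme order."""
        if feature == CLASS_FEATURE:
            return (NO_HEART_DISEASE, HEART_DISEASE)
        if feature in self.numeric:
            return self.numeric[feature].labels
        if feature in self.coded:
            return tuple(self.coded[feature].values())
        raise KeyError(f"unknown feature: {feature!r}")

    def label_for(self, feature: str, value: float) -> str:
        if feature in self.numeric:
            return self.numeric[feature].label_for(value)
        codes = self.coded[feature]
        code = int(value)
        if code != value or code not in codes:
            raise DomainError(f"{feature}: code {value!r} not in {sorted(codes)}")
        return codes[code]

    def to_dict(self) -> dict:
        """Plain-data form, round-trippable through YAML/JSON."""
        return {
            "numeric": {
                f: {"cuts": list(b.cuts), "labels": list(b.labels), "right": b.right}
                for f, b in self.numeric.items()
            },
            "coded": {f: {str(k): v for k, v in m.items()} for f, m in self.coded.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DiscretizationScheme":
        numeric = {
            f: NumericBinning(tuple(s["cuts"]), tuple(s["labels"]), bool(s.get("right", False)))
            for f, s in d.get("numeric", {}).items()
        }
        coded = {f: {int(k): str(v) for k, v in m.items()} for f, m in d.get("coded", {}).items()}
        return cls(numeric=numeric, coded=coded)


def default_scheme() -> DiscretizationScheme:
    """The bundled clinical discretisation scheme."""
    numeric = {
        "age": NumericBinning(
            (41.0, 65.0), ("lessThanForty", "betweenAge", "greaterThanSixtyFour")
        ),
        "trestbps": NumericBinning(
            (120.0, 140.0, 160.0), ("normal", "unusual", "high", "veryHigh")
        ),
        "chol": NumericBinning(
            (200.0, 240.0, 250.0), ("normal", "borderline_high", "high", "veryHigh")
        ),
        "thalach": NumericBinning((100.0,), ("Normal", "Tachycardia"), right=True),
        "oldpeak": NumericBinning((0.0,), ("Zero", "greaterThanZero"), right=True),
    }
    coded = {
        "sex": {0: "Female", 1: "Male"},
        "cp": {1: "typicalAngina", 2: "atypicalAngina", 3: "nonAnginalPain", 4: "asymptomatic"},
        "fbs": {0: "FALSE", 1: "TRUE"},
        "restecg": {0: "normal", 1: "STTWaveAbnormality", 2: "showingProbable"},
        "exang": {0: "No", 1: "Yes"},
        "slope": {1: "Upsloping", 2: "Flat", 3: "Downsloping"},
        "ca": {0: "zero", 1: "one", 2: "two", 3: "three"},
        "thal": {3: "normal", 6: "fixed", 7: "reversible"},
    }
    return DiscretizationScheme(numeric=numeric, coded=coded)


def canonical_level(feature: str, label: str, scheme: DiscretizationScheme | None = None) -> str:
    """Fold an externally written level label onto the canonical spelling.

    Accepts the canonical label, a case variant of it, or a known alias
    (``reversable`` -> ``reversible``).  Raises :class:`DomainError` for
    anything else.
    """
    scheme = scheme or default_scheme()
    label = _LEVEL_ALIASES.get(label.lower(), label)
    legal = scheme.levels(feature)
    if label in legal:
        return label
    lowered = {lv.lower(): lv for lv in legal}
    if label.lower() in lowered:
        return lowered[label.lower()]
    raise DomainError(f"{feature}: unknown level {label!r}; legal: {legal}")


@dataclass(frozen=True)
class EncodedRecord:
    """One patient as categorical (feature, level) pairs plus a binary class."""

    features: Mapping[str, str]
    label: str

    def __post_init__(self) -> None:
        if self.label not in (HEART_DISEASE, NO_HEART_DISEASE):
            raise DomainError(f"illegal class label: {self.label!r}")

    def level(self, feature: str) -> str:
        return self.features[feature]


def drop_incomplete(records: Iterable[RawRecord]) -> list[RawRecord]:
    """Keep only records with no missing field, preserving order."""
    return [r for r in records if not r.has_missing()]


def binarize_goal(goal: int) -> str:
    """Collapse the 0-4 diagnosis code to a binary class label."""
    if goal not in (0, 1, 2, 3, 4):
        raise DomainError(f"goal must be in 0..4, got {goal!r}")
    return NO_HEART_DISEASE if goal == 0 else HEART_DISEASE


def discretize(record: RawRecord, scheme: DiscretizationScheme | None = None) -> EncodedRecord:
    """Map a complete raw record onto categorical levels plus binary class."""
    scheme = scheme or default_scheme()
    if record.has_missing():
        raise DomainError("cannot discretize a record with missing values")
    features = {f: scheme.label_for(f, getattr(record, f)) for f in FEATURES}
    return EncodedRecord(features=features, label=binarize_goal(record.goal))


def encode_dataset(
    records: Iterable[RawRecord],
    scheme: DiscretizationScheme | None = None,
    feature_subset: Sequence[str] | None = None,
) -> list[EncodedRecord]:
    """Clean, discretize and project a raw dataset.

    ``feature_subset`` selects which attributes to keep (class is always
    implicit and may not be listed).  Defaults to all thirteen.
    """
    scheme = scheme or default_scheme()
    if feature_subset is None:
        keep = list(FEATURES)
    else:
        bad = [f for f in feature_subset if f not in FEATURES]
        if bad:
            raise DomainError(f"not attribute names: {bad} (class is implicit)")
        if len(set(feature_subset)) != len(feature_subset):
            raise DomainError("feature_subset contains duplicates")
        keep = [f for f in FEATURES if f in set(feature_subset)]
    out = []
    for raw in drop_incomplete(records):
        enc = discretize(raw, scheme)
        out.append(EncodedRecord({f: enc.features[f] for f in keep}, enc.label))
    return out
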