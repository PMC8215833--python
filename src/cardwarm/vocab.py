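"""Canonical feature names and class labels shared by every module.

The thirteen clinical attributes use the lowercase UCI short names; the
binary outcome lives under the reserved pseudo-feature ``class`` and never
appears as an ordinary attribute.
"""

from __future__ import annotations

#: Canonical order of the thirteen clinical attributes.
FEATURES: tuple[str, ...] = (
    "age",
    "sex",
    "cp",
    "trestbps",
    "chol",
    "fbs",
    "restecg",
    "thalach",
    "exang",
    "oldpeak",
    "slope",
    "ca",
    "thal",
)

#: Raw-file column carrying the 0-4 diagnosis code.
GOAL = "goal"

#: Reserved feature name for the binary outcome item.
CLASS_FEATURE = "class"

HEART_DISEASE = "Heart Disease"
NO_HEART_DISEASE = "No Heart Disease"
CLASS_LABELS: tuple[str, str] = (HEART_DISEASE, NO_HEART_DISEASE)

_FEATURE_INDEX = {name: i for i, name in enumerate(FEATURES)}


def feature_order(name: str) -> int:
    """Position of *name* in the canonical attribute order (class sorts last)."""
    if name == CLASS_FEATURE:
        return len(FEATURES)
    try:
        return _FEATURE_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown feature: {name!r}") from None


def is_feature(name: str) -> bool:
    return name in _FEATURE_INDEX
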