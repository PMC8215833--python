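"""Synthetic categorical datasets with controlled marginals and planted rules.

The generator draws each feature independently from per-level marginals and
the class from a Bernoulli prevalence, then overrides a disjoint slice of
records for every planted rule: those records carry the rule's antecedent
items verbatim and take the rule's class label with the target confidence.
Records outside a rule's slice are nudged off the full antecedent (one
antecedent feature is redrawn from the remaining levels) so that empirical
rule confidence is governed by the planted slice alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .preprocessing import EncodedRecord, default_scheme
from .vocab import FEATURES, HEART_DISEASE, NO_HEART_DISEASE
from .warm_miner import Item
from .data_io import RawRecord

__all__ = ["PlantedRule", "SyntheticSpec", "generate", "cleveland_like_spec", "to_raw_records"]


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRule:
    antecedent: tuple[Item, ...]
    label: str
    confidence: float
    coverage: float

    def __post_init__(self) -> None:
        # canonical item order so equal rules compare equal
        object.__setattr__(self, "antecedent", tuple(sorted(self.antecedent)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Marginals, prevalence, planted rules and a seed."""

    n: int
    marginals: Mapping[str, Mapping[str, float]]
    class_prevalence: float  # P(label = Heart Disease)
    planted: tuple[PlantedRule, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError("n must be >= 1")
        if not (0.0 <= self.class_prevalence <= 1.0):
            raise SpecError("class_prevalence must be in [0, 1]")
        for f, dist in self.marginals.items():
            if f not in FEATURES:
                raise SpecError(f"unknown feature in marginals: {f!r}")
            if any(p < 0 for p in dist.values()):
                raise SpecError(f"negative probability for {f!r}")
            if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
                raise SpecError(f"marginal for {f!r} does not sum to 1")
        total_cov = 0.0
        for rule in self.planted:
            if rule.label not in (HEART_DISEASE, NO_HEART_DISEASE):
                raise SpecError(f"planted label {rule.label!r} is not a class label")
            if not (0.0 <= rule.confidence <= 1.0 and 0.0 <= rule.coverage <= 1.0):
                raise SpecError("planted confidence and coverage must be in [0, 1]")
            feats = [it.feature for it in rule.antecedent]
            if len(set(feats)) != len(feats):
                raise SpecError("planted antecedent assigns two levels to one feature")
            for it in rule.antecedent:
                if it.feature not in self.marginals:
                    raise SpecError(f"planted item on unknown feature {it.feature!r}")
                if it.level not in self.marginals[it.feature]:
                    raise SpecError(f"planted item level {it!r} not in marginals")
            total_cov += rule.coverage
        if total_cov > 1.0 + 1e-9:
            raise SpecError("planted coverages exceed the dataset")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "marginals": {f: dict(d) for f, d in self.marginals.items()},
            "class_prevalence": self.class_prevalence,
            "planted": [
                {
                    "antecedent": {it.feature: it.level for it in r.antecedent},
                    "label": r.label,
                    "confidence": r.confidence,
                    "coverage": r.coverage,
                }
                for r in self.planted
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        planted = tuple(
            PlantedRule(
                antecedent=tuple(
                    Item(f, lv) for f, lv in sorted(r["antecedent"].items())
                ),
                label=r["label"],
                confidence=float(r["confidence"]),
                coverage=float(r["coverage"]),
            )
            for r in d.get("planted", ())
        )
        return cls(
            n=int(d["n"]),
            marginals={f: dict(m) for f, m in d["marginals"].items()},
            class_prevalence=float(d["class_prevalence"]),
            planted=planted,
            seed=int(d.get("seed", 0)),
        )


def _redraw_off(level_names, probs, banned_level, rng) -> str:
    """Draw a level != banned_level from the renormalised remaining mass."""
    rest = [(lv, p) for lv, p in zip(level_names, probs) if lv != banned_level and p > 0]
    if not rest:
        # degenerate marginal: nothing else to draw, keep the banned level
        return banned_level
    levels, ps = zip(*rest)
    ps = np.asarray(ps) / sum(ps)
    return str(rng.choice(levels, p=ps))


def generate(spec: SyntheticSpec) -> list[EncodedRecord]:
    """Draw the dataset described by *spec*; same spec + seed => same output."""
    rng = np.random.default_rng(spec.seed)
    ordered = [f for f in FEATURES if f in spec.marginals]

    columns: dict[str, list[str]] = {}
    for f in ordered:
        levels = list(spec.marginals[f])
        probs = np.asarray([spec.marginals[f][lv] for lv in levels])
        columns[f] = [str(v) for v in rng.choice(levels, size=spec.n, p=probs)]
    labels = [
        HEART_DISEASE if u < spec.class_prevalence else NO_HEART_DISEASE
        for u in rng.random(spec.n)
    ]

    # assign each planted rule a disjoint slice of record indices
    free = list(rng.permutation(spec.n))
    slices: list[tuple[PlantedRule, list[int]]] = []
    for rule in spec.planted:
        take = math.ceil(rule.coverage * spec.n)
        slices.append((rule, sorted(free[:take])))
        free = free[take:]

    planted_idx: set[int] = set()
    for rule, idx in slices:
        planted_idx.update(idx)
        for i in idx:
            for it in rule.antecedent:
                columns[it.feature][i] = it.level
            hit = rng.random() < rule.confidence
            other = NO_HEART_DISEASE if rule.label == HEART_DISEASE else HEART_DISEASE
            labels[i] = rule.label if hit else other

    # break accidental full-antecedent matches outside each rule's slice
    for rule, idx in slices:
        idx_set = set(idx)
        first = rule.antecedent[0]
        levels = list(spec.marginals[first.feature])
        probs = [spec.marginals[first.feature][lv] for lv in levels]
        for i in range(spec.n):
            if i in idx_set or i in planted_idx:
                continue
            if all(columns[it.feature][i] == it.level for it in rule.antecedent):
                columns[first.feature][i] = _redraw_off(levels, probs, first.level, rng)

    return [
        EncodedRecord({f: columns[f][i] for f in ordered}, labels[i])
        for i in range(spec.n)
    ]


# Marginals loosely shaped on the cleaned 297-record clinical encoding.
_CLEVELAND_MARGINALS: dict[str, dict[str, float]] = {
    "age": {"lessThanForty": 25 / 297, "betweenAge": 241 / 297, "greaterThanSixtyFour": 31 / 297},
    "sex": {"Male": 203 / 297, "Female": 94 / 297},
    "cp": {
        "typicalAngina": 23 / 297,
        "atypicalAngina": 49 / 297,
        "nonAnginalPain": 83 / 297,
        "asymptomatic": 142 / 297,
    },
    "trestbps": {"normal": 93 / 297, "unusual": 117 / 297, "high": 58 / 297, "veryHigh": 29 / 297},
    "chol": {
        "normal": 49 / 297,
        "borderline_high": 109 / 297,
        "high": 25 / 297,
        "veryHigh": 114 / 297,
    },
    "fbs": {"TRUE": 43 / 297, "FALSE": 254 / 297},
    "restecg": {"normal": 147 / 297, "STTWaveAbnormality": 4 / 297, "showingProbable": 146 / 297},
    "thalach": {"Normal": 26 / 297, "Tachycardia": 271 / 297},
    "exang": {"Yes": 97 / 297, "No": 200 / 297},
    "oldpeak": {"Zero": 96 / 297, "greaterThanZero": 201 / 297},
    "slope": {"Upsloping": 139 / 297, "Flat": 137 / 297, "Downsloping": 21 / 297},
    "ca": {"zero": 174 / 297, "one": 65 / 297, "two": 38 / 297, "three": 20 / 297},
    "thal": {"normal": 164 / 297, "fixed": 18 / 297, "reversible": 115 / 297},
}


def cleveland_like_spec(seed: int = 7) -> SyntheticSpec:
    """Default 297-record spec with one planted sick and one healthy rule."""
    sick = PlantedRule(
        antecedent=(
            Item("cp", "asymptomatic"),
            Item("exang", "Yes"),
            Item("oldpeak", "greaterThanZero"),
            Item("thal", "reversible"),
        ),
        label=HEART_DISEASE,
        confidence=0.98,
        coverage=0.25,
    )
    healthy = PlantedRule(
        antecedent=(
            Item("sex", "Female"),
            Item("cp", "nonAnginalPain"),
            Item("thal", "normal"),
        ),
        label=NO_HEART_DISEASE,
        confidence=1.0,
        coverage=0.1,
    )
    return SyntheticSpec(
        n=297,
        marginals=_CLEVELAND_MARGINALS,
        class_prevalence=137 / 297,
        planted=(sick, healthy),
        seed=seed,
    )


# Representative numeric value for each bin, used to re-numerify encoded
# records into the raw 14-column dialect.
_BIN_REPRESENTATIVE: dict[str, dict[str, float]] = {
    "age": {"lessThanForty": 35, "betweenAge": 52, "greaterThanSixtyFour": 70},
    "trestbps": {"normal": 110, "unusual": 130, "high": 150, "veryHigh": 170},
    "chol": {"normal": 180, "borderline_high": 220, "high": 245, "veryHigh": 280},
    "thalach": {"Normal": 90, "Tachycardia": 150},
    "oldpeak": {"Zero": 0.0, "greaterThanZero": 1.5},
}


def to_raw_records(records: Sequence[EncodedRecord]) -> list[RawRecord]:
    """Inverse-map encoded records onto the raw dialect.

    Coded features invert exactly; numeric bins use a fixed in-bin
    representative, so ``encode(to_raw(x))`` reproduces the levels of ``x``.
    Requires all thirteen features to be present.
    """
    scheme = default_scheme()
    inverse_codes = {
        f: {lv: code for code, lv in codes.items()} for f, codes in scheme.coded.items()
    }
    out = []
    for r in records:
        missing = set(FEATURES) - set(r.features)
        if missing:
            raise SpecError(f"record lacks features {sorted(missing)}; cannot re-numerify")
        values: dict[str, float] = {}
        for f in FEATURES:
            lv = r.features[f]
            if f in inverse_codes:
                values[f] = float(inverse_codes[f][lv])
            else:
                values[f] = float(_BIN_REPRESENTATIVE[f][lv])
        goal = 0 if r.label == NO_HEART_DISEASE else 1
        out.append(RawRecord(**values, goal=goal))
    return out
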