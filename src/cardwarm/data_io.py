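"""Readers and writers for the raw record dialect, occurrence counts,
encoded datasets, weight tables and rule files.

The raw dialect is the processed 14-column comma-separated form: thirteen
attributes plus the 0-4 diagnosis code, with ``?`` marking a missing value.
Rules round-trip through JSON (one object per rule) or CSV at full float
precision; antecedent items are always serialized in lexicographic
(feature, level) order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

from .vocab import CLASS_FEATURE, FEATURES

Source = Union[str, Path, IO[str]]

__all__ = [
    "RawRecord",
    "OccurrenceTable",
    "ParseError",
    "SchemaError",
    "read_cleveland",
    "write_cleveland",
    "load_occurrence_table",
    "write_occurrence_table",
    "read_encoded",
    "write_encoded",
    "write_rules",
    "read_rules",
    "write_weight_table",
    "bundled_path",
]


class ParseError(ValueError):
    """Malformed row in a raw data file."""


class SchemaError(ValueError):
    """A tabular input violates its declared schema."""


# Attributes that are integer codes in the dialect (floats like "3.0" accepted).
_CODED = {"sex", "cp", "fbs", "restecg", "exang", "slope", "ca", "thal"}


@dataclass(frozen=True)
class RawRecord:
    """One row of the 14-column dialect; ``None`` marks a missing value."""

    age: float | None
    sex: float | None
    cp: float | None
    trestbps: float | None
    chol: float | None
    fbs: float | None
    restecg: float | None
    thalach: float | None
    exang: float | None
    oldpeak: float | None
    slope: float | None
    ca: float | None
    thal: float | None
    goal: int

    def has_missing(self) -> bool:
        return any(getattr(self, f) is None for f in FEATURES)

    def to_row(self) -> list[str]:
        out = []
        for f in FEATURES:
            v = getattr(self, f)
            if v is None:
                out.append("?")
            elif f in _CODED or float(v).is_integer():
                out.append(f"{v:.1f}")
            else:
                out.append(repr(float(v)))
        out.append(str(self.goal))
        return out


def _open(source: Source, mode: str = "r") -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, mode, newline=""), True
    return source, False


def read_cleveland(source: Source) -> list[RawRecord]:
    """Parse the 14-column dialect into :class:`RawRecord` rows.

    ``?`` maps to the missing marker; any other non-numeric token is a
    :class:`ParseError` naming the 1-based row.
    """
    handle, close = _open(source)
    try:
        records: list[RawRecord] = []
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # ignore blank lines (the UCI file ends with one)
            if len(row) != 14:
                raise ParseError(f"row {lineno}: expected 14 columns, got {len(row)}")
            values: list[float | None] = []
            for name, token in zip(FEATURES, row):
                token = token.strip()
                if token == "?":
                    values.append(None)
                    continue
                try:
                    values.append(float(token))
                except ValueError:
                    raise ParseError(
                        f"row {lineno}: non-numeric value {token!r} for {name}"
                    ) from None
            try:
                goal = float(row[13].strip())
            except ValueError:
                raise ParseError(f"row {lineno}: non-numeric goal {row[13]!r}") from None
            if not goal.is_integer():
                raise ParseError(f"row {lineno}: goal must be an integer, got {goal}")
            records.append(RawRecord(*values, goal=int(goal)))
        return records
    finally:
        if close:
            handle.close()


def write_cleveland(records: Iterable[RawRecord], sink: Source) -> None:
    handle, close = _open(sink, "w")
    try:
        writer = csv.writer(handle)
        for r in records:
            writer.writerow(r.to_row())
    finally:
        if close:
            handle.close()


@dataclass(frozen=True)
class OccurrenceTable:
    """Per-feature non-negative occurrence counts used as strength inputs."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(FEATURES) - set(self.counts)
        if missing:
            raise SchemaError(f"occurrence table missing features: {sorted(missing)}")
        extra = set(self.counts) - set(FEATURES)
        if extra:
            raise SchemaError(f"occurrence table has unknown features: {sorted(extra)}")
        for f, c in self.counts.items():
            if not isinstance(c, int) or c < 0:
                raise SchemaError(f"count for {f!r} must be a non-negative integer, got {c!r}")

    def __getitem__(self, feature: str) -> int:
        return self.counts[feature]

    def total(self, features: Sequence[str] | None = None) -> int:
        return sum(self.counts[f] for f in (features or FEATURES))


def bundled_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("cardwarm.data").joinpath(name)))


def load_occurrence_table(source: Source = "bundled") -> OccurrenceTable:
    """Load a ``feature,count`` CSV; ``"bundled"`` loads the packaged table."""
    if source == "bundled":
        source = bundled_path("occurrence_counts.csv")
    handle, close = _open(source)
    try:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or set(reader.fieldnames) != {"feature", "count"}:
            raise SchemaError("occurrence table must have columns feature,count")
        counts: dict[str, int] = {}
        for row in reader:
            f = row["feature"].strip().lower()
            if f in counts:
                raise SchemaError(f"duplicate feature {f!r} in occurrence table")
            try:
                counts[f] = int(row["count"])
            except (TypeError, ValueError):
                raise SchemaError(f"non-integer count for {f!r}: {row['count']!r}") from None
        return OccurrenceTable(counts)
    finally:
        if close:
            handle.close()


def write_occurrence_table(table: OccurrenceTable, sink: Source) -> None:
    handle, close = _open(sink, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(["feature", "count"])
        for f in FEATURES:
            writer.writerow([f, table[f]])
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Encoded datasets


def write_encoded(records: Sequence, sink: Source) -> None:
    """Write encoded records as CSV with one column per feature plus ``class``."""
    if not records:
        handle, close = _open(sink, "w")
        try:
            csv.writer(handle).writerow([CLASS_FEATURE])
        finally:
            if close:
                handle.close()
        return
    keep = [f for f in FEATURES if f in records[0].features]
    handle, close = _open(sink, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(keep + [CLASS_FEATURE])
        for r in records:
            writer.writerow([r.features[f] for f in keep] + [r.label])
    finally:
        if close:
            handle.close()


def read_encoded(source: Source) -> list:
    """Read an encoded-dataset CSV back into :class:`EncodedRecord` rows."""
    from .preprocessing import EncodedRecord, canonical_level

    handle, close = _open(source)
    try:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is None or header[-1] != CLASS_FEATURE:
            raise SchemaError("encoded CSV must end with a 'class' column")
        feats = header[:-1]
        bad = [f for f in feats if f not in FEATURES]
        if bad:
            raise SchemaError(f"unknown features in encoded CSV header: {bad}")
        out = []
        for row in reader:
            if len(row) != len(header):
                raise ParseError(f"encoded CSV row has {len(row)} fields, expected {len(header)}")
            features = {f: canonical_level(f, v) for f, v in zip(feats, row[:-1])}
            out.append(EncodedRecord(features, row[-1]))
        return out
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Rules

_RULE_COLUMNS = [
    "antecedent",
    "consequent",
    "support",
    "antecedent_support",
    "weighted_support",
    "antecedent_weighted_support",
    "confidence",
]


def _rule_to_obj(rule) -> dict:
    items = sorted((it.feature, it.level) for it in rule.antecedent)
    return {
        "antecedent": [{"feature": f, "level": lv} for f, lv in items],
        "consequent": rule.consequent.level,
        "support": rule.support,
        "antecedent_support": rule.antecedent_support,
        "weighted_support": rule.weighted_support,
        "antecedent_weighted_support": rule.antecedent_weighted_support,
        "confidence": rule.confidence,
    }


def write_rules(rules: Sequence, sink: Source, format: str = "json") -> None:
    """Serialize rules to ``json`` or ``csv`` preserving full precision."""
    if format not in ("json", "csv"):
        raise ValueError(f"format must be 'json' or 'csv', got {format!r}")
    handle, close = _open(sink, "w")
    try:
        if format == "json":
            json.dump([_rule_to_obj(r) for r in rules], handle, indent=1)
            handle.write("\n")
        else:
            writer = csv.writer(handle)
            writer.writerow(_RULE_COLUMNS)
            for r in rules:
                obj = _rule_to_obj(r)
                ant = ";".join(f"{i['feature']}={i['level']}" for i in obj["antecedent"])
                writer.writerow(
                    [ant, obj["consequent"]]
                    + [repr(obj[c]) for c in _RULE_COLUMNS[2:]]
                )
    finally:
        if close:
            handle.close()


def read_rules(source: Source, format: str = "json") -> list:
    from .warm_miner import Item, WeightedRule

    handle, close = _open(source)
    try:
        rules = []
        if format == "json":
            for obj in json.load(handle):
                ant = tuple(
                    Item(i["feature"], i["level"]) for i in obj["antecedent"]
                )
                rules.append(
                    WeightedRule(
                        antecedent=ant,
                        consequent=Item(CLASS_FEATURE, obj["consequent"]),
                        support=obj["support"],
                        antecedent_support=obj["antecedent_support"],
                        weighted_support=obj["weighted_support"],
                        antecedent_weighted_support=obj["antecedent_weighted_support"],
                        confidence=obj["confidence"],
                    )
                )
        elif format == "csv":
            reader = csv.DictReader(handle)
            if reader.fieldnames != _RULE_COLUMNS:
                raise SchemaError(f"rule CSV must have columns {_RULE_COLUMNS}")
            for row in reader:
                ant = tuple(
                    Item(*pair.split("=", 1))
                    for pair in row["antecedent"].split(";")
                    if pair
                )
                rules.append(
                    WeightedRule(
                        antecedent=ant,
                        consequent=Item(CLASS_FEATURE, row["consequent"]),
                        **{c: float(row[c]) for c in _RULE_COLUMNS[2:]},
                    )
                )
        else:
            raise ValueError(f"format must be 'json' or 'csv', got {format!r}")
        return rules
    finally:
        if close:
            handle.close()


def write_weight_table(table, sink: Source) -> None:
    """Weight table CSV: one row per (feature, level) item, full precision
    plus a 2-dp display column for each weight."""
    from .strength_scores import round2

    handle, close = _open(sink, "w")
    try:
        writer = csv.writer(handle)
        writer.writerow(
            ["feature", "level", "w_n", "w_value", "w_t", "w_n_2dp", "w_value_2dp", "w_t_2dp"]
        )
        for (f, lv) in sorted(table.value_weights):
            wn = table.feature_weights[f]
            wv = table.value_weights[(f, lv)]
            wt = table.item_weight(f, lv)
            writer.writerow(
                [f, lv, repr(wn), repr(wv), repr(wt), round2(wn), round2(wv), round2(wt)]
            )
    finally:
        if close:
            handle.close()
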