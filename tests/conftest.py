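from __future__ import annotations

import random

import pytest

from cardwarm.data_io import OccurrenceTable, load_occurrence_table
from cardwarm.preprocessing import EncodedRecord
from cardwarm.strength_scores import WeightTable
from cardwarm.vocab import HEART_DISEASE, NO_HEART_DISEASE


@pytest.fixture(scope="session")
def counts() -> OccurrenceTable:
    return load_occurrence_table("bundled")


@pytest.fixture(scope="session")
def sex_split_dataset() -> list[EncodedRecord]:
    """297 single-feature records with the documented 203/94 sex split."""
    return [EncodedRecord({"sex": "Male"}, HEART_DISEASE) for _ in range(203)] + [
        EncodedRecord({"sex": "Female"}, NO_HEART_DISEASE) for _ in range(94)
    ]


def random_toy(rng: random.Random, max_records: int = 8, max_features: int = 4):
    """A tiny random categorical dataset plus a consistent weight table."""
    n_feat = rng.randint(1, max_features)
    feats = [f"f{i}" for i in range(n_feat)]
    levels = {f: [f"v{j}" for j in range(rng.randint(1, 3))] for f in feats}
    n = rng.randint(1, max_records)
    records = [
        EncodedRecord(
            {f: rng.choice(levels[f]) for f in feats},
            rng.choice([HEART_DISEASE, NO_HEART_DISEASE]),
        )
        for _ in range(n)
    ]
    raw_fw = {f: rng.random() + 0.05 for f in feats}
    z = sum(raw_fw.values())
    fw = {f: w / z for f, w in raw_fw.items()}
    vw = {}
    for f in feats:
        raw = {lv: rng.random() + 0.05 for lv in levels[f]}
        zz = sum(raw.values())
        for lv, w in raw.items():
            vw[(f, lv)] = w / zz
    return records, WeightTable(feature_weights=fw, value_weights=vw)
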