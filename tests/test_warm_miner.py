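import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import enumerate_frequent, enumerate_rules
from cardwarm.preprocessing import EncodedRecord
from cardwarm.strength_scores import WeightTable
from cardwarm.vocab import CLASS_FEATURE, HEART_DISEASE, NO_HEART_DISEASE
from cardwarm.warm_miner import (
    Item,
    MiningConfig,
    MiningError,
    generate_class_rules,
    itemset_weight,
    mine_frequent_itemsets,
    support,
    weighted_confidence,
    weighted_support,
)
from conftest import random_toy

HD = Item(CLASS_FEATURE, HEART_DISEASE)
NHD = Item(CLASS_FEATURE, NO_HEART_DISEASE)


def toy4():
    """Four records; {sex=Male} in three of them, {sex=Male, class=HD} in two."""
    return [
        EncodedRecord({"sex": "Male", "ca": "three"}, HEART_DISEASE),
        EncodedRecord({"sex": "Male", "ca": "zero"}, HEART_DISEASE),
        EncodedRecord({"sex": "Male", "ca": "zero"}, NO_HEART_DISEASE),
        EncodedRecord({"sex": "Female", "ca": "zero"}, NO_HEART_DISEASE),
    ]


def toy_weights():
    return WeightTable(
        feature_weights={"sex": 0.5, "ca": 0.5},
        value_weights={
            ("sex", "Male"): 0.4,
            ("sex", "Female"): 0.6,
            ("ca", "zero"): 0.75,
            ("ca", "three"): 0.25,
        },
    )


class TestSupport:
    def test_empty_itemset_is_one(self):
        assert support((), toy4()) == 1.0

    def test_absent_item_is_zero(self):
        assert support((Item("sex", "Other"),), toy4()) == 0.0

    def test_three_of_four(self):
        assert support((Item("sex", "Male"),), toy4()) == 0.75

    def test_class_item_matches_label(self):
        assert support((Item("sex", "Male"), HD), toy4()) == 0.5

    def test_empty_dataset_rejected(self):
        with pytest.raises(MiningError):
            support((), [])


class TestItemsetWeight:
    def test_class_only_is_one(self):
        assert itemset_weight((HD,), toy_weights()) == 1.0

    def test_single_item(self):
        w = WeightTable(feature_weights={"sex": 0.14}, value_weights={("sex", "Male"): 0.68})
        assert itemset_weight((Item("sex", "Male"),), w) == 0.14 * 0.68

    def test_mean_of_two(self):
        w = WeightTable(
            feature_weights={"a": 1.0, "b": 1.0},
            value_weights={("a", "x"): 0.10, ("b", "y"): 0.20},
        )
        assert itemset_weight((Item("a", "x"), Item("b", "y")), w) == pytest.approx(0.15)

    def test_class_item_excluded_from_mean(self):
        w = toy_weights()
        items = (Item("sex", "Male"), HD)
        assert itemset_weight(items, w) == itemset_weight((Item("sex", "Male"),), w)

    def test_unknown_item_raises(self):
        with pytest.raises(KeyError):
            itemset_weight((Item("sex", "Other"),), toy_weights())


class TestWeightedSupport:
    def test_zero_support_stays_zero(self):
        absent = (Item("sex", "Female"), Item("ca", "three"))  # never co-occur
        assert weighted_support(absent, toy4(), toy_weights()) == 0.0

    def test_class_only_equals_raw_support(self):
        assert weighted_support((HD,), toy4(), toy_weights()) == support((HD,), toy4())

    def test_product_form(self):
        w = WeightTable(feature_weights={"sex": 0.5}, value_weights={("sex", "Male"): 0.4})
        # support 0.75, W(t) = 0.2 -> 0.15
        assert weighted_support((Item("sex", "Male"),), toy4(), w) == pytest.approx(0.15)


class TestWeightedConfidence:
    def test_equal_supports_give_one(self):
        dataset = [EncodedRecord({"sex": "Male", "ca": "three"}, HEART_DISEASE)] * 2 + [
            EncodedRecord({"sex": "Female", "ca": "zero"}, NO_HEART_DISEASE)
        ] * 8
        ant = (Item("sex", "Male"), Item("ca", "three"))
        w = toy_weights()
        assert weighted_support(ant, dataset, w) == pytest.approx(
            weighted_support(ant + (HD,), dataset, w)
        )
        assert weighted_confidence(ant, HD, dataset, w) == 1.0

    def test_never_cooccurring_consequent_is_zero(self):
        assert weighted_confidence((Item("sex", "Female"),), HD, toy4(), toy_weights()) == 0.0

    def test_weight_cancels_for_class_consequents(self):
        rng = random.Random(5)
        for _ in range(25):
            records, weights = random_toy(rng)
            universe = sorted({Item(f, lv) for r in records for f, lv in r.features.items()})
            for it in universe:
                ant = (it,)
                if support(ant, records) == 0:
                    continue
                raw_conf = support(ant + (HD,), records) / support(ant, records)
                assert weighted_confidence(ant, HD, records, weights) == pytest.approx(raw_conf)

    def test_zero_denominator_raises(self):
        absent = (Item("sex", "Female"), Item("ca", "three"))
        with pytest.raises(MiningError):
            weighted_confidence(absent, HD, toy4(), toy_weights())


DEFAULT = MiningConfig(min_weighted_support=0.0, min_confidence=0.0, max_antecedent=4)


class TestMineFrequentItemsets:
    def test_threshold_zero_matches_powerset(self):
        records = [
            EncodedRecord({"a": "x", "b": "y"}, HEART_DISEASE),
            EncodedRecord({"a": "x", "b": "z"}, NO_HEART_DISEASE),
            EncodedRecord({"a": "w", "b": "y"}, HEART_DISEASE),
        ]
        w = WeightTable(
            feature_weights={"a": 0.5, "b": 0.5},
            value_weights={("a", "x"): 0.6, ("a", "w"): 0.4, ("b", "y"): 0.7, ("b", "z"): 0.3},
        )
        assert mine_frequent_itemsets(records, w, DEFAULT) == enumerate_frequent(
            records, w, DEFAULT
        )

    def test_threshold_above_one_gives_nothing(self):
        cfg = MiningConfig(min_weighted_support=1.1)
        assert mine_frequent_itemsets(toy4(), toy_weights(), cfg) == []

    def test_planted_universal_pair_present(self):
        records = [
            EncodedRecord({"a": "x", "b": "y", "c": f"v{i % 2}"}, HEART_DISEASE)
            for i in range(6)
        ]
        w = WeightTable(
            feature_weights={"a": 1 / 3, "b": 1 / 3, "c": 1 / 3},
            value_weights={
                ("a", "x"): 1.0, ("b", "y"): 1.0, ("c", "v0"): 0.5, ("c", "v1"): 0.5,
            },
        )
        mined = mine_frequent_itemsets(records, w, DEFAULT)
        pair = (Item("a", "x"), Item("b", "y"))
        assert any(s.items == pair for s in mined)

    def test_empty_dataset_rejected(self):
        with pytest.raises(MiningError):
            mine_frequent_itemsets([], toy_weights(), DEFAULT)

    def test_output_sorted_and_unique(self):
        rng = random.Random(17)
        records, weights = random_toy(rng, max_records=8, max_features=4)
        mined = mine_frequent_itemsets(records, weights, DEFAULT)
        keys = [(len(s.items), s.items) for s in mined]
        assert keys == sorted(keys)
        assert len(set(keys)) == len(keys)

    def test_anti_monotone_raw_support(self):
        rng = random.Random(23)
        for _ in range(10):
            records, weights = random_toy(rng)
            mined = mine_frequent_itemsets(records, weights, DEFAULT)
            sup = {s.items: s.support for s in mined}
            for s in mined:
                for drop in range(len(s.items)):
                    sub = s.items[:drop] + s.items[drop + 1 :]
                    if sub:
                        assert support(sub, records) >= s.support

    def test_weight_gating_monotone(self):
        records = toy4()
        base = toy_weights()
        lowered = WeightTable(
            feature_weights=base.feature_weights,
            value_weights={**base.value_weights, ("sex", "Male"): 0.1},
        )
        target = (Item("sex", "Male"), Item("ca", "zero"))
        assert weighted_support(target, records, lowered) <= weighted_support(
            target, records, base
        )

    def test_max_antecedent_caps_itemset_size(self):
        rng = random.Random(3)
        records, weights = random_toy(rng, max_records=8, max_features=4)
        cfg = MiningConfig(min_weighted_support=0.0, min_confidence=0.0, max_antecedent=1)
        mined = mine_frequent_itemsets(records, weights, cfg)
        for s in mined:
            plain = [it for it in s.items if not it.is_class]
            assert len(plain) <= 1
            assert len(s.items) - len(plain) <= 1


class TestGenerateClassRules:
    def test_planted_deterministic_rule(self):
        records = [
            EncodedRecord({"f1": "a", "f2": "b"}, HEART_DISEASE),
            EncodedRecord({"f1": "a", "f2": "b"}, HEART_DISEASE),
            EncodedRecord({"f1": "c", "f2": "b"}, NO_HEART_DISEASE),
        ]
        w = WeightTable(
            feature_weights={"f1": 0.5, "f2": 0.5},
            value_weights={("f1", "a"): 0.7, ("f1", "c"): 0.3, ("f2", "b"): 1.0},
        )
        cfg = MiningConfig(min_weighted_support=0.0, min_confidence=0.9, max_antecedent=2)
        rules = generate_class_rules(mine_frequent_itemsets(records, w, cfg), records, w, cfg)
        target = (Item("f1", "a"), Item("f2", "b"))
        match = [r for r in rules if r.antecedent == target and r.consequent == HD]
        assert len(match) == 1
        assert match[0].confidence == 1.0

    def test_min_confidence_above_one_empty(self):
        cfg = MiningConfig(min_weighted_support=0.0, min_confidence=1.01)
        records, weights = random_toy(random.Random(9))
        rules = generate_class_rules(
            mine_frequent_itemsets(records, weights, cfg), records, weights, cfg
        )
        assert rules == []

    def test_five_record_toy_matches_oracle(self):
        rng = random.Random(31)
        records, weights = random_toy(rng, max_records=5, max_features=3)
        cfg = MiningConfig(min_weighted_support=0.0, min_confidence=0.0, max_antecedent=3)
        mined = generate_class_rules(
            mine_frequent_itemsets(records, weights, cfg), records, weights, cfg
        )
        assert sorted(mined, key=repr) == sorted(enumerate_rules(records, weights, cfg), key=repr)

    def test_no_duplicate_rules(self):
        rng = random.Random(41)
        records, weights = random_toy(rng)
        cfg = MiningConfig(min_weighted_support=0.0, min_confidence=0.0, max_antecedent=4)
        rules = generate_class_rules(
            mine_frequent_itemsets(records, weights, cfg), records, weights, cfg
        )
        keys = [(r.antecedent, r.consequent) for r in rules]
        assert len(set(keys)) == len(keys)

    def test_confidence_bounds(self):
        rng = random.Random(43)
        for _ in range(20):
            records, weights = random_toy(rng)
            cfg = MiningConfig(min_weighted_support=0.0, min_confidence=0.0, max_antecedent=4)
            for r in generate_class_rules(
                mine_frequent_itemsets(records, weights, cfg), records, weights, cfg
            ):
                assert 0.0 <= r.confidence <= 1.0 + 1e-12


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000), thr=st.floats(0, 0.3), conf=st.floats(0, 1))
def test_oracle_equivalence_random_toys(seed, thr, conf):
    rng = random.Random(seed)
    records, weights = random_toy(rng)
    cfg = MiningConfig(min_weighted_support=thr, min_confidence=conf, max_antecedent=4)
    assert mine_frequent_itemsets(records, weights, cfg) == enumerate_frequent(
        records, weights, cfg
    )
    mined = generate_class_rules(
        mine_frequent_itemsets(records, weights, cfg), records, weights, cfg
    )
    assert sorted(mined, key=repr) == sorted(enumerate_rules(records, weights, cfg), key=repr)
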