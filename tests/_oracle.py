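"""Brute-force powerset oracle for the miner, kept independent of the
level-wise implementation: containment, support and weights are recomputed
from first principles by exhaustive enumeration."""

from __future__ import annotations

from itertools import combinations

from cardwarm.vocab import CLASS_FEATURE
from cardwarm.warm_miner import Item, Itemset, MiningConfig, WeightedRule


def _contains(record, items) -> bool:
    for it in items:
        if it.feature == CLASS_FEATURE:
            if record.label != it.level:
                return False
        elif record.features.get(it.feature) != it.level:
            return False
    return True


def _mean_weight(items, weights) -> float:
    plain = sorted(it for it in items if it.feature != CLASS_FEATURE)
    if not plain:
        return 1.0
    return sum(weights.item_weight(f, lv) for f, lv in plain) / len(plain)


def enumerate_frequent(dataset, weights, config: MiningConfig) -> list[Itemset]:
    n = len(dataset)
    universe = sorted(
        {Item(f, lv) for r in dataset for f, lv in r.features.items()}
        | {Item(CLASS_FEATURE, r.label) for r in dataset}
    )
    out = []
    for k in range(1, config.max_antecedent + 2):
        for combo in combinations(universe, k):
            feats = [it.feature for it in combo]
            if len(set(feats)) != len(feats):
                continue
            plain = [it for it in combo if it.feature != CLASS_FEATURE]
            if len(plain) > config.max_antecedent:
                continue
            count = sum(1 for r in dataset if _contains(r, combo))
            if count < 1:
                continue
            sup = count / n
            wsup = sup * _mean_weight(combo, weights)
            if wsup >= config.min_weighted_support:
                out.append(Itemset(tuple(combo), count, sup, wsup))
    out.sort(key=lambda s: (len(s.items), s.items))
    return out


def enumerate_rules(dataset, weights, config: MiningConfig) -> list[WeightedRule]:
    rules = []
    for iset in enumerate_frequent(dataset, weights, config):
        classes = [it for it in iset.items if it.feature == CLASS_FEATURE]
        plain = tuple(it for it in iset.items if it.feature != CLASS_FEATURE)
        if len(classes) != 1 or not plain:
            continue
        n = len(dataset)
        ant_count = sum(1 for r in dataset if _contains(r, plain))
        ant_sup = ant_count / n
        ant_wsup = ant_sup * _mean_weight(plain, weights)
        if ant_wsup <= 0.0:
            continue
        conf = iset.weighted_support / ant_wsup
        if conf < config.min_confidence:
            continue
        rules.append(
            WeightedRule(
                antecedent=plain,
                consequent=classes[0],
                support=iset.support,
                antecedent_support=ant_sup,
                weighted_support=iset.weighted_support,
                antecedent_weighted_support=ant_wsup,
                confidence=conf,
            )
        )
    return rules
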