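"""Level-wise frequent-itemset mining and weighted class-association rules.

Items are (feature, level) pairs; the binary outcome participates as a
single item under the reserved feature ``class``.  An itemset's weighted
support is its raw support times the arithmetic mean of the total item
weights ``W(t)`` of its non-class items (class-only itemsets carry weight
1, so their weighted support equals raw support).  Rule confidence is the
ratio of the weighted supports of antecedent-plus-class and antecedent;
because the class item does not enter the weight mean, this ratio equals
the raw confidence for class-consequent rules — weights act by gating
which itemsets are admitted, not by distorting the ratio.

Candidate generation is the classic join-and-prune over sorted item
tuples.  Downward closure holds for raw support only, so the frontier is
pruned on raw support (tightened by the best possible item weight) and the
weighted threshold is applied as a post-filter at each level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .preprocessing import EncodedRecord
from .strength_scores import WeightTable
from .vocab import CLASS_FEATURE

__all__ = [
    "Item",
    "Itemset",
    "WeightedRule",
    "MiningConfig",
    "support",
    "itemset_weight",
    "weighted_support",
    "weighted_confidence",
    "mine_frequent_itemsets",
    "generate_class_rules",
]


class Item(NamedTuple):
    feature: str
    level: str

    @property
    def is_class(self) -> bool:
        return self.feature == CLASS_FEATURE

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.feature}={self.level}"


@dataclass(frozen=True)
class Itemset:
    """A frequent itemset with its raw and weighted support."""

    items: tuple[Item, ...]
    count: int
    support: float
    weighted_support: float

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class WeightedRule:
    """Antecedent itemset -> class consequent with weighted measures."""

    antecedent: tuple[Item, ...]
    consequent: Item
    support: float
    antecedent_support: float
    weighted_support: float
    antecedent_weighted_support: float
    confidence: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ant = ", ".join(map(str, self.antecedent))
        return f"{{{ant}}} => {self.consequent.level} (conf={self.confidence:.2f})"


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and limits for one mining run.

    ``min_weighted_support`` is deliberately small: total item weights on a
    297-record clinical encoding sit around 0.01-0.11, so the weighted
    support of a realistic multi-item rule is an order of magnitude below
    its raw support.
    """

    min_weighted_support: float = 0.005
    min_confidence: float = 0.9
    max_antecedent: int = 6
    top_k: int = 20
    mode: str = "significant"

    def __post_init__(self) -> None:
        # values above 1 are legal and simply admit nothing
        if self.min_weighted_support < 0.0:
            raise ValueError("min_weighted_support must be >= 0")
        if self.min_confidence < 0.0:
            raise ValueError("min_confidence must be >= 0")
        if self.max_antecedent < 1:
            raise ValueError("max_antecedent must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.mode not in ("significant", "all_features"):
            raise ValueError("mode must be 'significant' or 'all_features'")


class MiningError(ValueError):
    pass


def _contains(record: EncodedRecord, items: Iterable[Item]) -> bool:
    for it in items:
        if it.is_class:
            if record.label != it.level:
                return False
        elif record.features.get(it.feature) != it.level:
            return False
    return True


def support(items: Iterable[Item], dataset: Sequence[EncodedRecord]) -> float:
    """Fraction of records containing every item (empty itemset -> 1.0)."""
    if not dataset:
        raise MiningError("support is undefined on an empty dataset")
    items = tuple(items)
    return sum(1 for r in dataset if _contains(r, items)) / len(dataset)


def itemset_weight(items: Iterable[Item], weights: WeightTable) -> float:
    """Mean ``W(t)`` over non-class items; 1.0 when only class items remain."""
    plain = sorted(it for it in items if not it.is_class)
    if not plain:
        return 1.0
    return sum(weights.item_weight(f, lv) for f, lv in plain) / len(plain)


def weighted_support(
    items: Iterable[Item], dataset: Sequence[EncodedRecord], weights: WeightTable
) -> float:
    items = tuple(items)
    return support(items, dataset) * itemset_weight(items, weights)


def weighted_confidence(
    antecedent: Iterable[Item],
    consequent: Item,
    dataset: Sequence[EncodedRecord],
    weights: WeightTable,
) -> float:
    """Ratio of weighted supports of antecedent-plus-consequent and antecedent."""
    antecedent = tuple(antecedent)
    denom = weighted_support(antecedent, dataset, weights)
    if denom <= 0.0:
        raise MiningError("weighted support of the antecedent is zero")
    return weighted_support(antecedent + (consequent,), dataset, weights) / denom


# ---------------------------------------------------------------------------
# Apriori


def _item_universe(dataset: Sequence[EncodedRecord]) -> list[Item]:
    feats: dict[str, set[str]] = {}
    labels: set[str] = set()
    for r in dataset:
        for f, lv in r.features.items():
            feats.setdefault(f, set()).add(lv)
        labels.add(r.label)
    items = [Item(f, lv) for f, lvs in feats.items() for lv in lvs]
    items += [Item(CLASS_FEATURE, lb) for lb in labels]
    return sorted(items)


def _bitmask(item: Item, dataset: Sequence[EncodedRecord]) -> int:
    mask = 0
    for i, r in enumerate(dataset):
        if _contains(r, (item,)):
            mask |= 1 << i
    return mask


def _plain_size(items: tuple[Item, ...]) -> int:
    return sum(1 for it in items if not it.is_class)


def mine_frequent_itemsets(
    dataset: Sequence[EncodedRecord],
    weights: WeightTable,
    config: MiningConfig,
) -> list[Itemset]:
    """All itemsets whose weighted support meets the threshold.

    Itemsets hold at most one item per feature, at most one class item, and
    at most ``max_antecedent`` non-class items.  Output is sorted by (size,
    lexicographic items).  When the threshold is zero, itemsets must still
    occur in at least one record.
    """
    if not dataset:
        raise MiningError("cannot mine an empty dataset")
    n = len(dataset)
    universe = _item_universe(dataset)
    masks = {it: _bitmask(it, dataset) for it in universe}
    wt = {it: (1.0 if it.is_class else weights.item_weight(*it)) for it in universe}

    # Raw-support frontier threshold: weighted support never exceeds raw
    # support times the best achievable mean item weight, so itemsets with a
    # non-class item need raw support >= min_wsup / max W(t).  Class-only
    # itemsets carry weight 1 and need raw support >= min_wsup.
    max_wt = max((wt[it] for it in universe if not it.is_class), default=1.0)
    plain_floor = config.min_weighted_support / max_wt if max_wt > 0 else float("inf")
    class_floor = config.min_weighted_support

    def frontier_ok(items: tuple[Item, ...], count: int) -> bool:
        if count < 1:
            return False
        floor = class_floor if _plain_size(items) == 0 else plain_floor
        return count / n >= floor

    def emit_ok(items: tuple[Item, ...], count: int, wsup: float) -> bool:
        return count >= 1 and wsup >= config.min_weighted_support

    def mean_weight(items: tuple[Item, ...]) -> float:
        plain = [it for it in items if not it.is_class]
        if not plain:
            return 1.0
        return sum(wt[it] for it in plain) / len(plain)

    out: list[Itemset] = []
    frontier: dict[tuple[Item, ...], int] = {}
    for it in universe:
        items = (it,)
        mask = masks[it]
        count = mask.bit_count()
        if frontier_ok(items, count):
            frontier[items] = mask
            wsup = (count / n) * mean_weight(items)
            if emit_ok(items, count, wsup):
                out.append(Itemset(items, count, count / n, wsup))

    max_total = config.max_antecedent + 1  # antecedent items plus one class item
    k = 1
    while frontier and k < max_total:
        k += 1
        keys = sorted(frontier)
        next_frontier: dict[tuple[Item, ...], int] = {}
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                if a[:-1] != b[:-1]:
                    break  # sorted prefixes diverge for all later j too
                cand = a + (b[-1],)
                if a[-1].feature == b[-1].feature:
                    continue  # two levels of one feature (or two class items)
                if _plain_size(cand) > config.max_antecedent:
                    continue
                # downward closure on the frontier
                if any(
                    cand[:m] + cand[m + 1 :] not in frontier for m in range(len(cand) - 2)
                ):
                    continue
                mask = frontier[a] & masks[b[-1]]
                count = mask.bit_count()
                if not frontier_ok(cand, count):
                    continue
                next_frontier[cand] = mask
                wsup = (count / n) * mean_weight(cand)
                if emit_ok(cand, count, wsup):
                    out.append(Itemset(cand, count, count / n, wsup))
        frontier = next_frontier

    out.sort(key=lambda s: (len(s.items), s.items))
    return out


def generate_class_rules(
    itemsets: Sequence[Itemset],
    dataset: Sequence[EncodedRecord],
    weights: WeightTable,
    config: MiningConfig,
) -> list[WeightedRule]:
    """Class-consequent rules from frequent itemsets.

    Every frequent itemset holding exactly one class item and at least one
    attribute item yields one candidate rule; rules whose confidence meets
    ``min_confidence`` are kept.  Antecedents whose weighted support is zero
    are silently skipped.
    """
    n = len(dataset)
    rules: list[WeightedRule] = []
    seen: set[tuple[tuple[Item, ...], Item]] = set()
    for iset in itemsets:
        classes = [it for it in iset.items if it.is_class]
        if len(classes) != 1:
            continue
        antecedent = tuple(it for it in iset.items if not it.is_class)
        if not antecedent:
            continue
        key = (antecedent, classes[0])
        if key in seen:
            continue
        seen.add(key)
        ant_sup = support(antecedent, dataset)
        ant_wsup = ant_sup * itemset_weight(antecedent, weights)
        if ant_wsup <= 0.0:
            continue
        confidence = iset.weighted_support / ant_wsup
        if confidence < config.min_confidence:
            continue
        rules.append(
            WeightedRule(
                antecedent=antecedent,
                consequent=classes[0],
                support=iset.support,
                antecedent_support=ant_sup,
                weighted_support=iset.weighted_support,
                antecedent_weighted_support=ant_wsup,
                confidence=confidence,
            )
        )
    return rules
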