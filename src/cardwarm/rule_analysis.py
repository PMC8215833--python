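"""Ranking, partitioning and summarising of mined class rules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .vocab import CLASS_FEATURE, FEATURES, HEART_DISEASE, NO_HEART_DISEASE
from .warm_miner import WeightedRule

__all__ = [
    "RuleSummary",
    "rank_rules",
    "partition_rules",
    "feature_frequency",
    "best_rule",
    "rules_markdown",
    "summary_markdown",
]


def _rank_key(rule: WeightedRule):
    # total order: confidence desc, raw rule support desc, shorter antecedent
    # first, then lexicographic antecedent and consequent
    return (
        -rule.confidence,
        -rule.support,
        len(rule.antecedent),
        tuple(sorted(rule.antecedent)),
        rule.consequent.level,
    )


def rank_rules(rules: Sequence[WeightedRule], k: int) -> list[WeightedRule]:
    """Top-*k* rules under the deterministic ranking order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(rules, key=_rank_key)[:k]


def partition_rules(
    rules: Sequence[WeightedRule],
) -> tuple[list[WeightedRule], list[WeightedRule]]:
    """Split into (sick, healthy) by consequent, preserving input order."""
    sick, healthy = [], []
    for r in rules:
        if r.consequent.feature != CLASS_FEATURE:
            raise ValueError(f"rule consequent is not a class item: {r.consequent}")
        if r.consequent.level == HEART_DISEASE:
            sick.append(r)
        elif r.consequent.level == NO_HEART_DISEASE:
            healthy.append(r)
        else:
            raise ValueError(f"unknown class label: {r.consequent.level!r}")
    return sick, healthy


@dataclass(frozen=True)
class RuleSummary:
    """How often each feature appears across a rule set's antecedents."""

    counts: Mapping[str, int]
    total_rules: int


def feature_frequency(rules: Sequence[WeightedRule]) -> RuleSummary:
    counts: dict[str, int] = {}
    for r in rules:
        for item in r.antecedent:
            counts[item.feature] = counts.get(item.feature, 0) + 1
    ordered = {f: counts[f] for f in FEATURES if f in counts}
    # non-canonical feature names (synthetic toys) follow, sorted
    ordered.update({f: c for f, c in sorted(counts.items()) if f not in ordered})
    return RuleSummary(counts=ordered, total_rules=len(rules))


def best_rule(rules: Sequence[WeightedRule], consequent: str) -> WeightedRule | None:
    """Rank-1 rule with the given class-label consequent, if any."""
    matching = [r for r in rules if r.consequent.level == consequent]
    if not matching:
        return None
    return rank_rules(matching, 1)[0]


# ---------------------------------------------------------------------------
# Report rendering (confidence shown at 2 dp; full precision lives in the
# serialized rule files)


def _md_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return "\n".join(lines)


def rules_markdown(rules: Sequence[WeightedRule], title: str = "Rules") -> str:
    rows = []
    for i, r in enumerate(rules, start=1):
        ant = ", ".join(f"{it.feature}={it.level}" for it in sorted(r.antecedent))
        rows.append([i, ant, r.consequent.level, f"{r.confidence:.2f}"])
    return f"## {title}\n\n" + _md_table(["#", "antecedent", "consequent", "confidence"], rows)


def summary_markdown(summary: RuleSummary, title: str) -> str:
    rows = [[f, c] for f, c in summary.counts.items()]
    body = _md_table(["feature", "rules mentioning it"], rows)
    return f"## {title}\n\nTotal rules: {summary.total_rules}\n\n" + body
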