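"""Temporal consolidation: intersect per-interval rule sets.

Rules are extracted independently at each sampling interval of a site;
only rules recurring at >= k distinct intervals enter the final list
(k = 3 in the canonical worked example).  Identity is predicate-level:
the canonical antecedent tokens, the polarity flags and the canonical
consequent tokens — support and confidence are excluded, so the same
rule re-extracted with a different support still counts as one key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data_model import AssociationRule, itemset_tokens


@dataclass
class RuleSet:
    """Rules mined at one time interval."""

    interval: int
    rules: list = field(default_factory=list)
    n_transactions: int = 0

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for r in self.rules:
            k = rule_key(r)
            if k not in seen:
                seen.add(k)
                deduped.append(r)
        self.rules = deduped

    def keys(self) -> set:
        return {rule_key(r) for r in self.rules}

    def positive_rules(self) -> list:
        return [r for r in self.rules if not r.is_negative]

    def negative_rules(self) -> list:
        return [r for r in self.rules if r.is_negative]


@dataclass
class ConsolidatedRule:
    """A final rule with its temporal evidence."""

    key: str
    rule: AssociationRule  # representative (earliest contributing interval)
    interval_count: int
    intervals: list
    mean_support: float
    mean_confidence: float
    per_interval: dict  # interval -> (support, confidence)


@dataclass
class FinalRuleSet:
    rules: list
    k: int

    def keys(self) -> set:
        return {cr.key for cr in self.rules}


def rule_key(rule: AssociationRule) -> str:
    """Canonical identity string of a rule, invariant under term reordering."""
    ant = itemset_tokens(rule.antecedent)
    cons = itemset_tokens(rule.consequent)
    ant_sign = "not " if rule.antecedent_negated else ""
    cons_sign = "not " if rule.consequent_negated else ""
    return f"{ant_sign}[{ant}] => {cons_sign}[{cons}]"


def count_intervals(key: str, rulesets) -> int:
    """Number of DISTINCT intervals whose ruleset contains this key; a rule
    appearing twice within one interval counts once."""
    return len({rs.interval for rs in rulesets if key in rs.keys()})


def intersect_rulesets(rulesets, k: int) -> FinalRuleSet:
    """Keep exactly the rule keys extracted at >= k distinct intervals.

    Aggregated support/confidence of a final rule is the mean over its
    contributing intervals; per-interval values are retained alongside.
    Interval order does not affect the result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_key: dict = {}
    for rs in sorted(rulesets, key=lambda r: r.interval):
        for rule in rs.rules:
            key = rule_key(rule)
            entry = by_key.setdefault(key, {})
            entry.setdefault(rs.interval, rule)
    finals = []
    for key, by_interval in by_key.items():
        intervals = sorted(by_interval)
        if len(intervals) < k:
            continue
        rules = [by_interval[i] for i in intervals]
        finals.append(
            ConsolidatedRule(
                key=key,
                rule=rules[0],
                interval_count=len(intervals),
                intervals=intervals,
                mean_support=sum(r.support for r in rules) / len(rules),
                mean_confidence=sum(r.confidence for r in rules) / len(rules),
                per_interval={i: (r.support, r.confidence) for i, r in by_interval.items()},
            )
        )
    finals.sort(key=lambda cr: (-cr.interval_count, -cr.mean_support, cr.key))
    return FinalRuleSet(rules=finals, k=k)


def near_miss_counts(key: str, rulesets) -> dict:
    """Diagnostic: interval counts of keys differing from ``key`` in exactly
    one predicate term (same polarity, one token swapped/added/removed on
    one side).  Surfaces rules that a context anomaly may have distorted
    at the predicate level; near-miss keys are reported, never merged."""
    target = _key_parts(key)
    out = {}
    all_keys = set()
    for rs in rulesets:
        all_keys |= rs.keys()
    for other in all_keys:
        if other == key:
            continue
        parts = _key_parts(other)
        if parts[1] != target[1] or parts[3] != target[3]:
            continue
        d_ant = len(parts[0] ^ target[0])
        d_cons = len(parts[2] ^ target[2])
        # one term changed: swap = symmetric difference 2 on one side,
        # add/remove = symmetric difference 1 on one side
        if (d_ant in (1, 2) and d_cons == 0) or (d_ant == 0 and d_cons in (1, 2)):
            out[other] = count_intervals(other, rulesets)
    return out


def _key_parts(key: str):
    left, right = key.split(" => ")

    def side(s):
        neg = s.startswith("not ")
        body = s[4:] if neg else s
        tokens = frozenset(t.strip() for t in body.strip("[]").split("^") if t.strip())
        return tokens, neg

    at, an = side(left)
    ct, cn = side(right)
    return at, an, ct, cn
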