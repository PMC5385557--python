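"""Shared fixtures: toy transaction builders, the worked-example rule
encoding, and brute-force enumeration oracles independent of the
levelwise/bipartition code paths they check."""

from itertools import chain, combinations

import pytest

from microprospect.consolidate import RuleSet
from microprospect.data_model import AssociationRule, Item, parse_predicate


def item(letter: str) -> Item:
    return Item(letter, "1", "presence")


def tx(*letters_per_transaction):
    """tx('AB','AC') -> [frozenset{A,B}, frozenset{A,C}] of presence items."""
    return [frozenset(item(ch) for ch in s) for s in letters_per_transaction]


def powerset(iterable, max_size=None):
    s = list(iterable)
    top = len(s) if max_size is None else min(max_size, len(s))
    return chain.from_iterable(combinations(s, r) for r in range(1, top + 1))


def brute_frequent(transactions, ms):
    """Oracle: exhaustive powerset counting of every frequent itemset."""
    universe = sorted(set().union(*transactions) | set(), key=lambda i: (i.indicator_id, i.relation, i.level))
    n = len(transactions)
    out = {}
    for combo in powerset(universe):
        iset = frozenset(combo)
        frac = sum(1 for t in transactions if iset <= t) / n
        if frac >= ms:
            out[iset] = frac
    return out


def brute_rules(transactions, th, max_antecedent=4, max_consequent=7):
    """Oracle: direct enumeration of every signed rule over all disjoint
    nonempty itemset pairs, straight from the fipi/iipi definitions.

    Returns a set of (frozenset antecedent, frozenset consequent,
    antecedent_negated, consequent_negated) tuples.
    """
    universe = sorted(set().union(*transactions), key=lambda i: (i.indicator_id, i.relation, i.level))
    n = len(transactions)
    supp = {
        frozenset(c): sum(1 for t in transactions if frozenset(c) <= t) / n
        for c in powerset(universe)
    }
    supp[frozenset()] = 1.0

    ms = th.ms_fraction(n)
    found = set()
    subsets = [s for s in supp if 0 < len(s) <= max(max_antecedent, max_consequent)]
    for a in subsets:
        if len(a) > max_antecedent:
            continue
        for b in subsets:
            if len(b) > max_consequent or (a & b):
                continue
            sa, sb, sab = supp[a], supp[b], supp[a | b]
            # positive: fipi
            if sab >= ms and abs(sab - sa * sb) >= th.mi and sa > 0 and sab / sa >= th.mc:
                found.add((a, b, False, False))
            # negative: iipi on the three signed forms
            if sa >= ms and sb >= ms:
                configs = [
                    (sa - sab, sa, 1 - sb, False, True),
                    (sb - sab, 1 - sa, sb, True, False),
                    (1 - sa - sb + sab, 1 - sa, 1 - sb, True, True),
                ]
                for joint, s_ant, s_cons, aneg, cneg in configs:
                    if (
                        joint >= ms
                        and abs(joint - s_ant * s_cons) >= th.mi
                        and s_ant > 0
                        and joint / s_ant >= th.mc
                    ):
                        found.add((a, b, aneg, cneg))
    return found


def rule_signature(rule: AssociationRule):
    return (rule.antecedent, rule.consequent, rule.antecedent_negated, rule.consequent_negated)


# --- the worked-example rule table (ten per-interval rules) -----------------

RULE1_PREDICATES = [
    "is_a (Apd, >=X1)",
    "is_a (Pheh, >=X2)",
    "diff_of (Aio.Rps, >X3)",
    "color_of (soil, Y1)",
]
RULE2_PREDICATES = RULE1_PREDICATES + ["is_a (Ni, >=X3)"]
RULE3_PREDICATES = [
    "is_a (Apd, >=X1)",
    "is_a (Pheh, <=X2)",
    "diff_of (Aio.Rps, >X3)",
    "color_of (soil, Y1)",
]
RULE4_PREDICATES = [
    "is_a (Apd, >=X1)",
    "is_a (Pheh, <=X2)",
    "is_a (Aio, >X4)",
    "color_of (soil, Y1)",
]
RULE2T3_PREDICATES = RULE3_PREDICATES + ["is_a (Ni, >=X3)"]
RULE1T3_PREDICATES = [
    "is_a (Apd, >=X1)",
    "is_a (An, >=X5)",
    "close_to (Prospect, rock)",
]
CONSEQUENT_PREDICATE = "found (MP, true)"

#: (interval, antecedent predicates, support count, precipitation value)
WORKED_EXAMPLE_ROWS = [
    (1, RULE1_PREDICATES, 8, 250),
    (1, RULE2_PREDICATES, 6, 250),
    (1, RULE3_PREDICATES, 6, 450),
    (1, RULE4_PREDICATES, 8, 370),
    (2, RULE1_PREDICATES, 7, 250),
    (2, RULE2_PREDICATES, 4, 250),
    (2, RULE1_PREDICATES, 4, 250),
    (3, RULE1T3_PREDICATES, 6, 250),
    (3, RULE2T3_PREDICATES, 5, 450),
    (4, RULE1_PREDICATES, 5, 250),
]


def make_worked_rule(predicates, support, interval):
    return AssociationRule(
        antecedent=frozenset(parse_predicate(p) for p in predicates),
        consequent=frozenset({parse_predicate(CONSEQUENT_PREDICATE)}),
        antecedent_negated=False,
        consequent_negated=False,
        support=float(support),
        confidence=1.0,
        interest=0.0,
        interval=interval,
        supp_antecedent=float(support),
        supp_consequent=float(support),
    )


@pytest.fixture
def worked_example_rulesets():
    """The ten per-interval rules of the precipitation worked example as
    parsed rule records (supports are absolute counts, ms = 3)."""
    by_interval = {}
    for interval, preds, s, _prec in WORKED_EXAMPLE_ROWS:
        by_interval.setdefault(interval, []).append(make_worked_rule(preds, s, interval))
    return [RuleSet(interval=t, rules=rs) for t, rs in sorted(by_interval.items())]
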