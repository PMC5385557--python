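"""Positive and negative association rule generation (PNARM).

Rules are admitted through the support–confidence–interestingness
framework.  A positive rule A→B over disjoint nonempty itemsets is a
frequent itemset of potential interest (fipi) when

    supp(A∪B) >= ms,  interest(A, B) >= mi,  conf(A→B) >= mc,

with interest(A, B) = |supp(A∪B) − supp(A)·supp(B)|, the departure from
statistical independence.  A negated configuration (A→¬B, ¬A→B, ¬A→¬B)
is an infrequent itemset of potential interest (iipi) when additionally
both plain parts are individually frequent (supp(A) >= ms, supp(B) >= ms)
and the signed joint event itself clears ms.  Negated events use their
complement supports: supp(¬X) = 1 − supp(X), and the signed joint supports
follow by inclusion–exclusion, so the four configurations partition unity.
"""

from __future__ import annotations

from itertools import combinations

from .apriori import SupportTable
from .consolidate import RuleSet
from .data_model import AssociationRule, MiningError, Thresholds

NEGATIVE_FORMS = ("A->notB", "notA->B", "notA->notB")

_EPS = 1e-9


def negative_supports(supp_a: float, supp_b: float, supp_ab: float) -> tuple:
    """Signed joint supports (A∧¬B, ¬A∧B, ¬A∧¬B) by inclusion–exclusion.

    Together with supp(A∧B) these partition the transaction space, so the
    four values sum to one.  Raises on inputs violating the probability
    axioms (guards adjusted supports fed back through the pipeline)."""
    if not (0 <= supp_a <= 1 and 0 <= supp_b <= 1):
        raise MiningError("supports must lie in [0, 1]")
    if supp_ab > min(supp_a, supp_b) + _EPS or supp_ab < supp_a + supp_b - 1 - _EPS:
        raise MiningError(
            f"inconsistent supports: supp(AB)={supp_ab} vs supp(A)={supp_a}, supp(B)={supp_b}"
        )
    a_not_b = max(supp_a - supp_ab, 0.0)
    not_a_b = max(supp_b - supp_ab, 0.0)
    not_a_not_b = max(1.0 - supp_a - supp_b + supp_ab, 0.0)
    return a_not_b, not_a_b, not_a_not_b


def confidence(supp_antecedent: float, supp_joint: float) -> float:
    """Rule accuracy: supp(signed joint) / supp(signed antecedent)."""
    if supp_antecedent <= 0:
        raise MiningError("confidence undefined: antecedent support is zero")
    if supp_joint > supp_antecedent + _EPS:
        raise MiningError("joint support cannot exceed antecedent support")
    return min(supp_joint / supp_antecedent, 1.0)


def interest(supp_joint: float, supp_a: float, supp_b: float) -> float:
    """|supp(joint) − supp(A)·supp(B)| for the signed configuration."""
    return abs(supp_joint - supp_a * supp_b)


def _signed_stats(supp_a, supp_b, supp_ab, form):
    """(joint, antecedent, consequent) supports of one signed configuration."""
    a_nb, na_b, na_nb = negative_supports(supp_a, supp_b, supp_ab)
    if form == "A->B":
        return supp_ab, supp_a, supp_b
    if form == "A->notB":
        return a_nb, supp_a, 1.0 - supp_b
    if form == "notA->B":
        return na_b, 1.0 - supp_a, supp_b
    if form == "notA->notB":
        return na_nb, 1.0 - supp_a, 1.0 - supp_b
    raise MiningError(f"unknown rule form {form!r}")


def _check_disjoint(a, b):
    a, b = frozenset(a), frozenset(b)
    if not a or not b:
        raise MiningError("antecedent and consequent must be nonempty")
    if a & b:
        raise MiningError("antecedent and consequent must be disjoint itemsets")
    return a, b


def is_fipi(a, b, supports: SupportTable, th: Thresholds) -> bool:
    """Is A→B a frequent itemset of potential interest?"""
    a, b = _check_disjoint(a, b)
    ms = th.ms_fraction(supports.n_transactions)
    supp_ab = supports.support(a | b)
    if supp_ab < ms:
        return False
    supp_a, supp_b = supports.support(a), supports.support(b)
    if interest(supp_ab, supp_a, supp_b) < th.mi:
        return False
    if supp_a <= 0:
        return False
    return confidence(supp_a, supp_ab) >= th.mc


def is_iipi(a, b, supports: SupportTable, th: Thresholds, form: str) -> bool:
    """Is the negated configuration ``form`` an infrequent itemset of
    potential interest?  Both plain parts must be individually frequent."""
    a, b = _check_disjoint(a, b)
    if form not in ("A->notB", "notA->B", "notA->notB"):
        raise MiningError(f"not a negative rule form: {form!r}")
    ms = th.ms_fraction(supports.n_transactions)
    supp_a, supp_b = supports.support(a), supports.support(b)
    if supp_a < ms or supp_b < ms:
        return False
    supp_ab = supports.support(a | b)
    joint, s_ant, s_cons = _signed_stats(supp_a, supp_b, supp_ab, form)
    if joint < ms:
        return False
    if interest(joint, s_ant, s_cons) < th.mi:
        return False
    if s_ant <= 0:
        return False
    return confidence(s_ant, joint) >= th.mc


def _make_rule(a, b, supports, form, interval, context_adjusted=False):
    supp_a, supp_b = supports.support(a), supports.support(b)
    supp_ab = supports.support(a | b)
    joint, s_ant, s_cons = _signed_stats(supp_a, supp_b, supp_ab, form)
    return AssociationRule(
        antecedent=a,
        consequent=b,
        antecedent_negated=form.startswith("notA"),
        consequent_negated=form.endswith("notB"),
        support=joint,
        confidence=confidence(s_ant, joint),
        interest=interest(joint, s_ant, s_cons),
        interval=interval,
        supp_antecedent=s_ant,
        supp_consequent=s_cons,
        context_adjusted=context_adjusted,
    )


def mine_rules(
    supports: SupportTable,
    th: Thresholds,
    interval: int,
    max_antecedent: int = 4,
    max_consequent: int = 7,
) -> RuleSet:
    """All positive and negative rules of potential interest at one interval.

    Positive rules come from every bipartition (A, B) of every frequent
    itemset with |A| <= max_antecedent and |B| <= max_consequent passing
    the fipi gate.  Negative rules come from ordered pairs of individually
    frequent itemsets that are disjoint, each of the three negated forms
    tested through the iipi gate; negation applies to a whole itemset side,
    never item-by-item within it.  The result is duplicate-free.
    """
    rules = []
    freq = supports.frequent_itemsets()

    for iset in freq:
        if len(iset) < 2:
            continue
        items = sorted(iset, key=lambda it: (it.indicator_id, it.relation, it.level))
        for r in range(1, len(items)):
            if r > max_antecedent or len(items) - r > max_consequent:
                continue
            for a_items in combinations(items, r):
                a = frozenset(a_items)
                b = frozenset(iset) - a
                if is_fipi(a, b, supports, th):
                    rules.append(_make_rule(a, b, supports, "A->B", interval))

    small = [s for s in freq if len(s) <= max(max_antecedent, max_consequent)]
    for a in small:
        if len(a) > max_antecedent:
            continue
        for b in small:
            if len(b) > max_consequent or a == b or (a & b):
                continue
            for form in NEGATIVE_FORMS:
                if is_iipi(a, b, supports, th, form):
                    rules.append(_make_rule(a, b, supports, form, interval))

    return RuleSet(interval=interval, rules=rules, n_transactions=supports.n_transactions)
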