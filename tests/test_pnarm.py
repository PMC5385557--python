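"""Positive/negative rule generation: the fipi/iipi gates, signed-support
arithmetic, and exact agreement with brute-force enumeration."""

import random

import pytest

from microprospect.apriori import SupportTable, frequent_itemsets
from microprospect.consolidate import rule_key
from microprospect.data_model import MiningError, Thresholds, parse_predicate
from microprospect.pnarm import (
    confidence,
    interest,
    is_fipi,
    is_iipi,
    mine_rules,
    negative_supports,
)

from conftest import brute_rules, item, rule_signature, tx

A = frozenset({item("A")})
B = frozenset({item("B")})


def table_from(supp_a, supp_b, supp_ab, n=100):
    """A SupportTable stub holding exactly the supports under test."""
    return SupportTable(
        n_transactions=n,
        ms=0.0,
        supports={A: supp_a, B: supp_b, A | B: supp_ab},
        singletons={item("A"): supp_a, item("B"): supp_b},
    )


class TestNegativeSupports:
    def test_inclusion_exclusion_arithmetic(self):
        assert negative_supports(0.5, 0.4, 0.2) == pytest.approx((0.3, 0.2, 0.3))

    def test_empirical_containment_gives_zero(self):
        a_nb, _, _ = negative_supports(0.4, 0.7, 0.4)
        assert a_nb == 0.0

    def test_signed_supports_partition_unity(self):
        for sa, sb, sab in [(0.5, 0.4, 0.2), (0.9, 0.1, 0.05), (1.0, 1.0, 1.0)]:
            parts = negative_supports(sa, sb, sab)
            assert sab + sum(parts) == pytest.approx(1.0, abs=1e-12)

    def test_axiom_violations_rejected(self):
        with pytest.raises(MiningError):
            negative_supports(0.5, 0.4, 0.45)  # supp(AB) > supp(B)
        with pytest.raises(MiningError):
            negative_supports(0.5, 0.4, -0.2)


class TestConfidence:
    def test_division(self):
        assert confidence(0.5, 0.4) == pytest.approx(0.8)

    def test_never_cooccur_gives_certain_negative(self):
        # supp(A and not-B) == supp(A) => conf(A -> not B) = 1
        assert confidence(0.5, 0.5) == 1.0

    def test_zero_antecedent_rejected(self):
        with pytest.raises(MiningError):
            confidence(0.0, 0.0)

    def test_matches_conditional_frequency(self):
        transactions = tx("AB", "AB", "AB", "A", "AC", "BC")
        n = len(transactions)
        sa = sum(1 for t in transactions if A <= t) / n
        sab = sum(1 for t in transactions if (A | B) <= t) / n
        count_a = sum(1 for t in transactions if A <= t)
        count_ab = sum(1 for t in transactions if (A | B) <= t)
        assert confidence(sa, sab) == pytest.approx(count_ab / count_a)


class TestGates:
    def test_fipi_worked_arithmetic(self):
        th = Thresholds(ms=0.3, mc=0.7, mi=0.05)
        t = table_from(0.6, 0.6, 0.5)
        # interest = |0.5 - 0.36| = 0.14, conf = 0.5/0.6 = 0.833
        assert is_fipi(A, B, t, th)

    def test_independent_items_fail_interest(self):
        th = Thresholds(ms=0.1, mc=0.1, mi=0.01)
        assert not is_fipi(A, B, table_from(0.5, 0.4, 0.2), th)

    def test_overlap_rejected(self):
        th = Thresholds(ms=0.1, mc=0.1, mi=0.0)
        with pytest.raises(MiningError):
            is_fipi(A, A, table_from(0.5, 0.5, 0.5), th)

    def test_iipi_worked_arithmetic(self):
        th = Thresholds(ms=0.3, mc=0.7, mi=0.05)
        t = table_from(0.6, 0.5, 0.1)
        # supp(A and not-B) = 0.5, interest = |0.5 - 0.6*0.5| = 0.2, conf 0.833
        assert is_iipi(A, B, t, th, "A->notB")

    def test_iipi_gated_on_consequent_frequency(self):
        th = Thresholds(ms=0.3, mc=0.0, mi=0.0)
        assert not is_iipi(A, B, table_from(0.6, 0.2, 0.1), th, "A->notB")

    def test_iipi_independence_fails_interest(self):
        th = Thresholds(ms=0.1, mc=0.0, mi=0.01)
        # supp(notA and notB) = (1-sa)(1-sb) exactly under independence
        assert not is_iipi(A, B, table_from(0.5, 0.4, 0.2), th, "notA->notB")

    def test_interest_symmetric(self):
        for sa, sb, sab in [(0.6, 0.3, 0.25), (0.8, 0.8, 0.7)]:
            assert interest(sab, sa, sb) == interest(sab, sb, sa)


class TestMineRules:
    def test_perfect_cooccurrence_yields_both_directions(self):
        table = frequent_itemsets(tx("AB", "AB", "AB", "C"), ms=0.5)
        rs = mine_rules(table, Thresholds(0.5, 0.5, 0.0), interval=1)
        sigs = {rule_signature(r) for r in rs.positive_rules()}
        assert (A, B, False, False) in sigs
        assert (B, A, False, False) in sigs
        conf = {rule_signature(r): r.confidence for r in rs.positive_rules()}
        assert conf[(A, B, False, False)] == 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_dbs(self, seed):
        rng = random.Random(1000 + seed)
        letters = "ABCDEF"[: rng.randint(3, 6)]
        n_tx = rng.randint(5, 16)
        transactions = tx(
            *("".join(c for c in letters if rng.random() < 0.5) for _ in range(n_tx))
        )
        th = Thresholds(
            ms=rng.uniform(0.15, 0.55),
            mc=rng.uniform(0.3, 0.9),
            mi=rng.uniform(0.0, 0.15),
        )
        table = frequent_itemsets(transactions, th.ms)
        mined = {rule_signature(r) for r in mine_rules(table, th, 1).rules}
        assert mined == brute_rules(transactions, th)

    def test_zero_gates_reduce_to_plain_apriori_positive_rules(self):
        """With mi = mc = 0 the positive side is exactly the support-only
        Apriori rule set (the PNARM-vs-Apriori baseline)."""
        transactions = tx("ABC", "ABC", "AB", "AC", "BC", "A", "B")
        th = Thresholds(ms=2 / 7, mc=0.0, mi=0.0)
        table = frequent_itemsets(transactions, th.ms)
        got = {rule_signature(r) for r in mine_rules(table, th, 1).positive_rules()}
        expected = {
            (a, b, False, False)
            for (a, b, an, cn) in brute_rules(transactions, th)
            if not an and not cn
        }
        assert got == expected

    def test_rule_count_monotone_in_ms(self):
        transactions = tx("ABC", "ABC", "AB", "AC", "BC", "AD", "BD", "CD")
        counts = []
        for ms in [0.2, 0.3, 0.4, 0.5, 0.6]:
            table = frequent_itemsets(transactions, ms)
            counts.append(len(mine_rules(table, Thresholds(ms, 0.3, 0.0), 1).rules))
        assert counts == sorted(counts, reverse=True)

    def test_absolute_count_threshold_admits_worked_rule(self):
        """Ten transactions, eight carrying the four-term antecedent plus the
        prospect item: with ms given as an absolute count of 3 the headline
        worked-example rule is mined."""
        preds = [
            "is_a (Apd, >=X1)",
            "is_a (Pheh, >=X2)",
            "diff_of (Aio.Rps, >X3)",
            "color_of (soil, Y1)",
        ]
        ant = frozenset(parse_predicate(p) for p in preds)
        cons = frozenset({parse_predicate("found (MP, true)")})
        full = ant | cons
        transactions = [full] * 8 + [frozenset(), frozenset()]
        th = Thresholds(ms=3, mc=0.5, mi=0.0)
        table = frequent_itemsets(transactions, th.ms_fraction(len(transactions)))
        sigs = {rule_signature(r) for r in mine_rules(table, th, 1).positive_rules()}
        assert (ant, cons, False, False) in sigs

    def test_rulesets_are_duplicate_free(self):
        table = frequent_itemsets(tx("AB", "AB", "AB", "AB"), ms=0.5)
        rs = mine_rules(table, Thresholds(0.5, 0.0, 0.0), 1)
        keys = [rule_key(r) for r in rs.rules]
        assert len(keys) == len(set(keys))
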