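"""Levelwise Apriori frequent-itemset mining over one interval's transactions.

Exploits support anti-monotonicity (every subset of a frequent itemset is
frequent) with the classical join+prune candidate step.  The resulting
:class:`SupportTable` additionally retains singleton supports *below* the
threshold and can compute arbitrary joint supports on demand — negative
rule generation needs supp(A∪B) for pairs whose union is infrequent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .data_model import MiningError


def canonical(itemset) -> tuple:
    """Canonical tuple order of an itemset: lexicographic on
    (indicator_id, relation, level)."""
    return tuple(sorted(itemset, key=lambda it: (it.indicator_id, it.relation, it.level)))


def support(itemset, transactions) -> tuple:
    """Exact support of an itemset: (fraction, count) of transactions
    containing every item.  The empty itemset has support 1 by convention."""
    if not transactions:
        raise MiningError("support undefined over an empty transaction list")
    iset = frozenset(itemset)
    count = sum(1 for t in transactions if iset <= t)
    return count / len(transactions), count


@dataclass
class SupportTable:
    """Supports of all frequent itemsets at one interval, plus bookkeeping.

    ``supports`` maps frozen itemsets to support fractions and contains
    exactly the itemsets with supp >= ms, plus memoized on-demand entries.
    ``singletons`` records every single item's support regardless of ms
    (flagged storage: they never enter candidate generation).
    """

    n_transactions: int
    ms: float
    supports: dict = field(default_factory=dict)
    singletons: dict = field(default_factory=dict)
    transactions: list = field(default_factory=list)
    tidsets: dict = field(default_factory=dict)
    _frequent: set = field(default_factory=set)

    def support(self, itemset) -> float:
        key = frozenset(itemset)
        if not key:
            return 1.0
        if key in self.supports:
            return self.supports[key]
        if len(key) == 1:
            (it,) = key
            if it in self.singletons:
                return self.singletons[it]
        if self.tidsets:
            # transaction-id intersection: fast exact count
            items = sorted(key, key=lambda it: len(self.tidsets.get(it, ())))
            if items[0] not in self.tidsets:
                frac = 0.0
            else:
                tids = self.tidsets[items[0]]
                for it in items[1:]:
                    tids = tids & self.tidsets.get(it, frozenset())
                    if not tids:
                        break
                frac = len(tids) / self.n_transactions
        else:
            frac, _ = support(key, self.transactions)
        self.supports[key] = frac  # memoize on-demand joints
        return frac

    def frequent_itemsets(self) -> list:
        """The itemsets meeting ms, in canonical order (smallest first)."""
        return sorted(self._frequent, key=lambda s: (len(s), canonical(s)))

    def is_frequent(self, itemset) -> bool:
        return frozenset(itemset) in self._frequent


def generate_candidates(frequent_k: list) -> list:
    """Join size-k frequent itemsets sharing a (k-1)-prefix and prune any
    candidate with an infrequent k-subset."""
    if not frequent_k:
        return []
    sizes = {len(s) for s in frequent_k}
    if len(sizes) != 1:
        raise MiningError(f"mixed itemset sizes in candidate generation: {sorted(sizes)}")
    k = sizes.pop()
    freq = {frozenset(s) for s in frequent_k}
    ordered = sorted((canonical(s) for s in freq))
    candidates = set()
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a[:-1] != b[:-1]:
                break  # sorted order: later tuples share no (k-1)-prefix either
            cand = frozenset(a) | frozenset(b)
            if all(frozenset(sub) in freq for sub in combinations(cand, k)):
                candidates.add(cand)
    return sorted(candidates, key=canonical)


def frequent_itemsets(transactions, ms: float) -> SupportTable:
    """Mine all itemsets with support >= ms (a fraction in (0, 1]).

    Levelwise: frequent singletons seed the lattice; candidate generation
    joins and prunes; termination when a level yields no frequent sets.
    Output is independent of transaction order.
    """
    if not transactions:
        raise MiningError("cannot mine an empty transaction list")
    if not 0 < ms <= 1:
        raise MiningError(f"ms fraction must be in (0, 1], got {ms}")
    transactions = [frozenset(t) for t in transactions]
    n = len(transactions)
    tidsets: dict = {}
    for tid, t in enumerate(transactions):
        for it in t:
            tidsets.setdefault(it, set()).add(tid)
    tidsets = {it: frozenset(s) for it, s in tidsets.items()}
    table = SupportTable(
        n_transactions=n, ms=ms, transactions=transactions, tidsets=tidsets
    )

    level = []
    for it in sorted(tidsets, key=lambda i: (i.indicator_id, i.relation, i.level)):
        frac = len(tidsets[it]) / n
        table.singletons[it] = frac
        if frac >= ms:
            key = frozenset({it})
            table.supports[key] = frac
            table._frequent.add(key)
            level.append(key)

    while level:
        next_level = []
        for cand in generate_candidates(level):
            tids = None
            for it in cand:
                tids = tidsets[it] if tids is None else tids & tidsets[it]
            frac = len(tids) / n
            if frac >= ms:
                table.supports[cand] = frac
                table._frequent.add(cand)
                next_level.append(cand)
        level = next_level
    return table
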