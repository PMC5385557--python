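"""Itemization: map raw indicator measurements to ordinal or presence Items.

Two modes feed the miner.  Ordinal mode bins each raw value into expert
ranges (half-open bins, value at a breakpoint goes to the upper bin).
Binary mode replaces every positive raw value by a presence token — the
simplification used for desk-scale mining runs — with the prospection
outcome itself becoming the item ``(MP, 1, presence)`` when true.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

from .data_model import Item, Record, TransactionDatabase

#: token representing a positive prospection outcome (presence of energy reserve)
PROSPECT_ITEM = Item("MP", "1", "presence")


class OutOfRangeError(ValueError):
    pass


@dataclass
class RangeTable:
    """Per-indicator breakpoints and ordinal labels.

    For breakpoints ``[b0, b1, ..., bn]`` and labels ``[l0, ..., l_{n-1}]``
    a value in ``[b_i, b_{i+1})`` gets label ``l_i``.  ``policy`` controls
    out-of-range values: ``"strict"`` raises, ``"clamp"`` assigns the edge bin.
    """

    breakpoints: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)
    policy: str = "strict"

    def __post_init__(self) -> None:
        if self.policy not in ("strict", "clamp"):
            raise ValueError("policy must be 'strict' or 'clamp'")
        for ind, bps in self.breakpoints.items():
            if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
                raise ValueError(f"breakpoints for {ind} must be strictly increasing")
            labs = self.labels[ind]
            if len(labs) != len(bps) - 1:
                raise ValueError(f"{ind}: need {len(bps) - 1} labels, got {len(labs)}")
            if len(set(labs)) != len(labs):
                raise ValueError(f"{ind}: labels must be unique")

    @classmethod
    def from_config(cls, ranges: dict, policy: str = "strict") -> "RangeTable":
        return cls(
            breakpoints={k: [float(b) for b in v["breakpoints"]] for k, v in ranges.items()},
            labels={k: [str(l) for l in v["labels"]] for k, v in ranges.items()},
            policy=policy,
        )


def ordinalize(value: float, indicator_id: str, ranges: RangeTable) -> Item:
    """Bin one raw value into its ordinal Item.

    The bin predicate is recorded with relation ``>=`` against the bin's
    lower bound label, so equal values always map to the same token.
    """
    if indicator_id not in ranges.breakpoints:
        raise KeyError(f"indicator {indicator_id!r} not in range table")
    bps = ranges.breakpoints[indicator_id]
    labs = ranges.labels[indicator_id]
    idx = bisect.bisect_right(bps, value) - 1
    if idx < 0 or idx >= len(labs):
        if ranges.policy == "strict":
            raise OutOfRangeError(
                f"{indicator_id}={value} outside [{bps[0]}, {bps[-1]})"
            )
        idx = min(max(idx, 0), len(labs) - 1)
    return Item(indicator_id, labs[idx], ">=")


def ordinalize_db(db: TransactionDatabase, ranges: RangeTable) -> TransactionDatabase:
    """Itemize every record's raw values through :func:`ordinalize`."""
    records = []
    for r in db.records:
        items = {ordinalize(v, ind, ranges) for ind, v in r.raw_values.items()}
        if r.prospect:
            items.add(PROSPECT_ITEM)
        records.append(replace_record(r, items=frozenset(items)))
    return TransactionDatabase(records, db.context_specs, db.indicator_columns)


def binarize_presence(db: TransactionDatabase) -> TransactionDatabase:
    """Replace every positive raw indicator value by a presence Item.

    Zero, negative or missing values yield no Item, so absence never counts
    as positive evidence (it is what negated rule sides quantify instead).
    A true prospection outcome contributes the MP presence item.  Record
    count is conserved: all-zero records stay, with empty itemsets.
    Idempotent — re-binarizing an already binarized database is a no-op.
    """
    records = []
    for r in db.records:
        items = {
            Item(ind, "1", "presence") for ind, v in r.raw_values.items() if v > 0
        }
        if not r.raw_values and r.items:
            items = set(r.items)  # already itemized, nothing raw to redo
        if r.prospect:
            items.add(PROSPECT_ITEM)
        records.append(replace_record(r, items=frozenset(items)))
    return TransactionDatabase(records, db.context_specs, db.indicator_columns)


def replace_record(r: Record, **kw) -> Record:
    return replace(r, **kw)


def build_transactions(db: TransactionDatabase, interval: int) -> list:
    """Per-interval transaction list: one itemset per record, in record order."""
    return [r.items for r in db.records_for_interval(interval)]


def equal_width_ranges(db: TransactionDatabase, n_bins: int = 3) -> RangeTable:
    """Convenience equal-width binning over observed raw values.

    Not part of the prospection method itself (ranges are expert input);
    provided only to bootstrap ordinal-mode experiments.
    """
    breakpoints, labels = {}, {}
    for ind in db.indicator_columns:
        vals = [r.raw_values[ind] for r in db.records if ind in r.raw_values]
        if not vals:
            continue
        lo, hi = min(vals), max(vals)
        if hi <= lo:
            hi = lo + 1.0
        step = (hi - lo) / n_bins
        breakpoints[ind] = [lo + i * step for i in range(n_bins)] + [hi + 1e-9]
        labels[ind] = [f"b{i + 1}" for i in range(n_bins)]
    return RangeTable(breakpoints, labels, policy="clamp")
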