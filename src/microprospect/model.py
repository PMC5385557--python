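"""Context-based rule-mining model and its fitted results.

:class:`ContextRuleMiner` is the front door of the package: construct it
from a :class:`~.data_model.TransactionDatabase` with mining thresholds,
call :meth:`~ContextRuleMiner.fit`, and read the fitted
:class:`MiningResults` — per-interval rule sets, the temporally
consolidated final rules, stage counts and a ``summary()`` table.

The fit pipeline mirrors the mining process end to end: itemize
(binary presence or expert ordinal ranges) → Apriori frequent itemsets
per interval → positive/negative rule generation through the
support–confidence–interestingness gates → context-variable support
adjustment at intervals whose context is out of range → intersection of
the per-interval rule sets across time (keep keys recurring at >= k
intervals).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import apriori, consolidate, context_adjust, pnarm
from .data_model import (
    Thresholds,
    TransactionDatabase,
    write_rules,
)
from .discretize import RangeTable, binarize_presence, build_transactions, ordinalize_db

logger = logging.getLogger(__name__)


class ContextRuleMiner:
    """Model: context-based positive & negative association rule mining.

    Parameters
    ----------
    db : TransactionDatabase
        Prospection records with raw indicator values and context values.
    thresholds : Thresholds
        ms / mc / mi mining gates and the temporal intersection count k.
    mode : {'binary', 'ordinal'}
        Itemization: presence/absence of each indicator, or expert ordinal
        ranges (requires ``range_table``).
    context_enabled : bool
        Whether out-of-range context variables adjust rule supports.
    max_antecedent, max_consequent : int
        Size caps of the rule search (consequents cap at 7 as serialized).
    """

    def __init__(
        self,
        db: TransactionDatabase,
        thresholds: Thresholds,
        mode: str = "binary",
        range_table: RangeTable | None = None,
        context_enabled: bool = True,
        context_subset: list | None = None,
        max_antecedent: int = 4,
        max_consequent: int = 7,
    ) -> None:
        if mode not in ("binary", "ordinal"):
            raise ValueError("mode must be 'binary' or 'ordinal'")
        if mode == "ordinal" and range_table is None:
            raise ValueError("ordinal mode requires a range table")
        self.db = db
        self.thresholds = thresholds
        self.mode = mode
        self.range_table = range_table
        self.context_enabled = context_enabled
        self.max_antecedent = max_antecedent
        self.max_consequent = max_consequent
        if context_subset is None:
            self.context_specs = list(db.context_specs)
        else:
            self.context_specs = [s for s in db.context_specs if s.name in set(context_subset)]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        indicator_columns,
        context_specs,
        thresholds: Thresholds,
        **kwargs,
    ) -> "ContextRuleMiner":
        """Build the model straight from a records DataFrame (same columns
        as the CSV dialect of :func:`~.data_model.load_database`)."""
        import io

        from .data_model import load_database

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        db = load_database(buf, indicator_columns, context_specs)
        return cls(db, thresholds, **kwargs)

    def _itemized(self) -> TransactionDatabase:
        if self.mode == "ordinal":
            return binarize_presence(ordinalize_db(self.db, self.range_table))
        return binarize_presence(self.db)

    def fit(self) -> "MiningResults":
        """Run the full pipeline and return the fitted results."""
        th = self.thresholds
        itemized = self._itemized()
        rulesets, adjusted_counts, frequent_count = [], {}, 0
        for interval in itemized.intervals:
            transactions = build_transactions(itemized, interval)
            ms = th.ms_fraction(len(transactions))

            ctx = {
                s.name: context_adjust.interval_context(
                    itemized.records_for_interval(interval), s.name
                )
                for s in self.context_specs
            }
            ms_candidates = ms
            if self.context_enabled:
                ms_candidates = ms * context_adjust.candidate_ms_relaxation(
                    ctx, self.context_specs
                )
            supports = apriori.frequent_itemsets(transactions, max(ms_candidates, 1e-9))
            frequent_count += sum(1 for _ in supports.frequent_itemsets())
            mined = pnarm.mine_rules(
                supports,
                Thresholds(max(ms_candidates, 1e-9), th.mc, th.mi, th.k),
                interval,
                self.max_antecedent,
                self.max_consequent,
            )
            if self.context_enabled:
                adjusted = context_adjust.apply_context(mined, ctx, self.context_specs, th)
            else:
                kept = [r for r in mined.rules if r.support >= ms]
                adjusted = consolidate.RuleSet(interval, kept, mined.n_transactions)
            adjusted_counts[interval] = sum(1 for r in adjusted.rules if r.context_adjusted)
            rulesets.append(adjusted)

        final = consolidate.intersect_rulesets(rulesets, th.k)
        return MiningResults(
            model=self,
            rulesets=rulesets,
            final=final,
            n_frequent_itemsets=frequent_count,
            adjusted_counts=adjusted_counts,
        )


@dataclass
class MiningResults:
    """Fitted results of :class:`ContextRuleMiner`."""

    model: ContextRuleMiner
    rulesets: list
    final: consolidate.FinalRuleSet
    n_frequent_itemsets: int
    adjusted_counts: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict:
        """Stage counts of the run: the quantities a mining report tracks."""
        pos = sum(len(rs.positive_rules()) for rs in self.rulesets)
        neg = sum(len(rs.negative_rules()) for rs in self.rulesets)
        return {
            "records": len(self.model.db.records),
            "intervals": len(self.rulesets),
            "frequent_itemsets": self.n_frequent_itemsets,
            "positive_rules": pos,
            "negative_rules": neg,
            "adjusted_rules": sum(self.adjusted_counts.values()),
            "distinct_rule_keys": len({k for rs in self.rulesets for k in rs.keys()}),
            "final_rules": len(self.final.rules),
        }

    def mean_confidence(self, positive_only: bool = False) -> float:
        vals = [
            r.confidence
            for rs in self.rulesets
            for r in (rs.positive_rules() if positive_only else rs.rules)
        ]
        return sum(vals) / len(vals) if vals else float("nan")

    def summary(self) -> str:
        th = self.model.thresholds
        c = self.counts
        lines = [
            "Context-Based Positive & Negative Association Rule Mining",
            "=" * 57,
            f"records: {c['records']}    intervals: {c['intervals']}    "
            f"mode: {self.model.mode}    context: {'on' if self.model.context_enabled else 'off'}",
            f"thresholds: ms={th.ms}  mc={th.mc}  mi={th.mi}  k={th.k}",
            "-" * 57,
            f"frequent itemsets (all intervals): {c['frequent_itemsets']}",
            f"positive rules: {c['positive_rules']}    negative rules: {c['negative_rules']}",
            f"context-adjusted rules: {c['adjusted_rules']}",
            f"distinct rule keys: {c['distinct_rule_keys']}    "
            f"final rules (>= {th.k} intervals): {c['final_rules']}",
            "-" * 57,
        ]
        for cr in self.final.rules[:20]:
            lines.append(
                f"[{cr.interval_count}x @ {','.join(f'T{i}' for i in cr.intervals)}] "
                f"supp={cr.mean_support:.3f} conf={cr.mean_confidence:.3f}  {cr.key}"
            )
        if len(self.final.rules) > 20:
            lines.append(f"... and {len(self.final.rules) - 20} more final rules")
        return "\n".join(lines)

    def final_keys(self) -> set:
        return self.final.keys()

    def save(self, out_dir) -> dict:
        """Write run artifacts: final rules, per-interval rules, run report.

        Returns a manifest of paths and the sha256 of the final rules file
        (runs are deterministic: identical config + data → identical hash).
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        final_path = out / "final_rules.csv"
        finals = []
        for cr in self.final.rules:
            from dataclasses import replace

            finals.append(
                replace(cr.rule, support=cr.mean_support, confidence=cr.mean_confidence)
            )
        write_rules(finals, final_path)
        interval_paths = []
        for rs in self.rulesets:
            p = out / f"rules_T{rs.interval}.csv"
            write_rules(rs.rules, p)
            interval_paths.append(str(p))
        report = {
            "counts": self.counts,
            "thresholds": {
                "ms": self.model.thresholds.ms,
                "mc": self.model.thresholds.mc,
                "mi": self.model.thresholds.mi,
                "k": self.model.thresholds.k,
            },
            "context_enabled": self.model.context_enabled,
            "mode": self.model.mode,
            "final_rules": [
                {
                    "key": cr.key,
                    "interval_count": cr.interval_count,
                    "intervals": cr.intervals,
                    "mean_support": cr.mean_support,
                    "mean_confidence": cr.mean_confidence,
                }
                for cr in self.final.rules
            ],
        }
        report_path = out / "run_report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        digest = hashlib.sha256(final_path.read_bytes()).hexdigest()
        return {
            "final_rules": str(final_path),
            "per_interval": interval_paths,
            "report": str(report_path),
            "final_rules_sha256": digest,
        }


def compare_modes(
    db: TransactionDatabase,
    thresholds: Thresholds,
    ms_grid,
    context_subset: list | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Mine under three context regimes across a grid of ms values.

    Regimes: context off, context on with every variable, and context on
    with a subset (default: the first half of the spec list).  Reports
    positive/negative rule counts and mean confidence per (regime, ms).
    """
    if context_subset is None:
        names = [s.name for s in db.context_specs]
        context_subset = names[: max(1, len(names) // 2)]
    rows = []
    regimes = [
        ("context-off", dict(context_enabled=False)),
        ("context-on-all", dict(context_enabled=True)),
        ("context-on-subset", dict(context_enabled=True, context_subset=context_subset)),
    ]
    for ms in ms_grid:
        th = Thresholds(ms, thresholds.mc, thresholds.mi, thresholds.k)
        for name, opts in regimes:
            res = ContextRuleMiner(db, th, **opts, **kwargs).fit()
            c = res.counts
            rows.append(
                {
                    "regime": name,
                    "ms": ms,
                    "positive_rules": c["positive_rules"],
                    "negative_rules": c["negative_rules"],
                    "final_rules": c["final_rules"],
                    "mean_confidence": res.mean_confidence(),
                }
            )
    return pd.DataFrame(rows)
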