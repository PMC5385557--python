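"""Domain types and flat-file IO for microbial prospection databases.

A prospection database holds one record per (site, time interval): raw
measurements for the 29 soil/microbial indicators (methane-oxidizing
bacteria counts, paraffin dirt, pH/Eh ratio, iron-mineral precipitation,
...), the measured values of the five context variables (temperature,
salinity of water, humidity, rainfall, fossil pollution) and a Boolean
prospection outcome.  Records are itemized (see :mod:`.discretize`) into
transactions of canonical ``Item`` tokens before mining.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

CONTEXT_VARIABLES = ("temperature", "salinity", "humidity", "rainfall", "fossil")

#: relations an Item may record about how a raw value maps to its token
RELATIONS = (">=", "<=", ">", "<", "==", "presence")

_RESERVED = ("^", ",", "|")


class SchemaError(ValueError):
    """A required column is missing or a column mapping is inconsistent."""


class IntegrityError(ValueError):
    """Database-level invariant violated (e.g. duplicate (site, interval))."""


class MiningError(ValueError):
    """Contract violation inside the mining stages."""


@dataclass(frozen=True, order=True)
class Item:
    """One canonical indicator token, e.g. ``is_a(Apd, >=X1)``.

    Two Items are equal iff indicator_id, level and relation all agree;
    the triple is the unit of identity throughout mining.
    """

    indicator_id: str
    level: str
    relation: str = "presence"

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        for f_ in (self.indicator_id, self.level):
            if any(ch in str(f_) for ch in _RESERVED):
                raise ValueError(f"reserved character in item field {f_!r}")

    def token(self) -> str:
        return f"{self.indicator_id},{self.relation},{self.level}"

    @classmethod
    def from_token(cls, token: str) -> "Item":
        parts = token.split(",")
        if len(parts) != 3:
            raise ValueError(f"malformed item token {token!r}")
        return cls(parts[0], parts[2], parts[1])


_PREDICATE_RE = re.compile(r"\s*(\w+)\s*\(\s*([^,()]+?)\s*,\s*(>=|<=|==|>|<)?\s*([^,()]+?)\s*\)\s*$")


def parse_predicate(text: str) -> Item:
    """Parse a rule predicate string such as ``is_a (Apd, >=X1)`` into an Item.

    ``is_a`` and ``found`` functors map the first argument straight to
    the indicator id; any other functor (``diff_of``, ``color_of``,
    ``close_to`` ...) is folded into the indicator id as ``functor(arg)``
    so that structurally different predicates never collide.
    """
    m = _PREDICATE_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse predicate {text!r}")
    functor, arg, rel, level = m.groups()
    rel = rel or "=="
    if functor in ("is_a", "found"):
        indicator = arg
    else:
        indicator = f"{functor}({arg})"
    return Item(indicator, level, rel)


@dataclass(frozen=True)
class ContextSpec:
    """Normal range [civ, cfv] of one context variable.

    civ/cfv (context initial/final value) bound the range considered
    normal; values outside it trigger support adjustment.  The bounds are
    expert-supplied, in the variable's own units.
    """

    name: str
    civ: float
    cfv: float

    def __post_init__(self) -> None:
        if not self.civ < self.cfv:
            raise ValueError(f"context {self.name}: civ ({self.civ}) must be < cfv ({self.cfv})")

    @property
    def width(self) -> float:
        return self.cfv - self.civ


@dataclass(frozen=True)
class Thresholds:
    """User-specified mining thresholds.

    ms — minimum support: a fraction in (0, 1] or an absolute transaction
    count (> 1; converted per interval by dividing by the interval's record
    count).  mc — minimum confidence, mi — minimum interest, both in [0, 1].
    k — minimum number of distinct time intervals a rule must be extracted
    at to enter the final consolidated set.
    """

    ms: float
    mc: float
    mi: float
    k: int = 3

    def __post_init__(self) -> None:
        if self.ms <= 0:
            raise ValueError("ms must be > 0")
        if not 0 <= self.mc <= 1:
            raise ValueError("mc must be in [0, 1]")
        if not 0 <= self.mi <= 1:
            raise ValueError("mi must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def ms_fraction(self, n_transactions: int) -> float:
        """Resolve ms to a support fraction for an interval of n transactions."""
        if self.ms > 1:
            if n_transactions <= 0:
                raise ValueError("cannot convert count-style ms without transactions")
            return self.ms / n_transactions
        return self.ms


@dataclass(frozen=True)
class AssociationRule:
    """A (possibly negated) association rule with its mining statistics.

    ``support`` is the fraction of transactions satisfying the signed
    joint event (e.g. A present and B absent for A→¬B);
    ``supp_antecedent`` / ``supp_consequent`` are the supports of the
    signed antecedent / consequent events, so that
    confidence = support / supp_antecedent and
    interest = \\|support − supp_antecedent·supp_consequent\\|.
    """

    antecedent: frozenset
    consequent: frozenset
    antecedent_negated: bool
    consequent_negated: bool
    support: float
    confidence: float
    interest: float
    interval: int
    supp_antecedent: float = 0.0
    supp_consequent: float = 0.0
    context_adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be nonempty")
        if self.antecedent & self.consequent:
            raise MiningError("antecedent and consequent must be disjoint itemsets")

    @property
    def is_negative(self) -> bool:
        return self.antecedent_negated or self.consequent_negated


def itemset_tokens(itemset: Iterable[Item]) -> str:
    """Canonical serialized form of an itemset: sorted tokens joined by ' ^ '."""
    return " ^ ".join(sorted(it.token() for it in itemset))


def parse_itemset(text: str) -> frozenset:
    return frozenset(Item.from_token(t.strip()) for t in text.split("^") if t.strip())


@dataclass
class Record:
    """One (site, time-interval) observation."""

    prospect_id: str
    site: str
    interval: int
    date_of_evaluation: _dt.date
    items: frozenset = frozenset()
    raw_values: dict = field(default_factory=dict)
    context_values: dict = field(default_factory=dict)
    prospect: bool = False
    coordinates: str = ""

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("interval indices start at 1")


@dataclass
class TransactionDatabase:
    """Ordered collection of records plus the context-variable specs."""

    records: list
    context_specs: list = field(default_factory=list)
    indicator_columns: list = field(default_factory=list)

    @property
    def sites(self) -> set:
        return {r.site for r in self.records}

    @property
    def intervals(self) -> list:
        return sorted({r.interval for r in self.records})

    @property
    def item_universe(self) -> frozenset:
        out = set()
        for r in self.records:
            out |= r.items
        return frozenset(out)

    def records_for_interval(self, interval: int) -> list:
        recs = [r for r in self.records if r.interval == interval]
        if not recs:
            raise KeyError(f"interval {interval} not present in database")
        return recs

    def context_spec(self, name: str) -> ContextSpec:
        for spec in self.context_specs:
            if spec.name == name:
                return spec
        raise KeyError(f"no context spec named {name!r}")


DEFAULT_SCHEMA = {
    "prospect_id": "prospect_id",
    "site": "site",
    "date": "date_of_evaluation",
    "prospect": "prospect",
    "coordinates": "prospect_coordinates",
}


def load_database(
    path,
    indicator_columns: Sequence[str],
    context_specs: Sequence[ContextSpec],
    schema: Mapping[str, str] | None = None,
) -> TransactionDatabase:
    """Read a prospection CSV into a validated :class:`TransactionDatabase`.

    Interval indices are assigned per site by sorting that site's distinct
    evaluation dates; within a (site, date) group rows are ordered by
    prospect_id, so the result is independent of file row order.  Raw
    indicator values are retained for :mod:`.discretize`.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    df = pd.read_csv(path, dtype={schema["prospect_id"]: str, schema["site"]: str})

    required = [schema["prospect_id"], schema["site"], schema["date"], schema["prospect"]]
    required += list(indicator_columns) + [s.name for s in context_specs]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")

    for spec in context_specs:
        bad = pd.to_numeric(df[spec.name], errors="coerce").isna() & df[spec.name].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"non-numeric context value in column {spec.name!r} at row {row}")
        df[spec.name] = pd.to_numeric(df[spec.name])

    df["_date"] = pd.to_datetime(df[schema["date"]]).dt.date
    records = []
    for site, grp in df.groupby(schema["site"], sort=True):
        dates = sorted(grp["_date"].unique())
        date_to_interval = {d: i + 1 for i, d in enumerate(dates)}
        grp = grp.sort_values(["_date", schema["prospect_id"]])
        for _, row in grp.iterrows():
            records.append(
                Record(
                    prospect_id=str(row[schema["prospect_id"]]),
                    site=str(site),
                    interval=date_to_interval[row["_date"]],
                    date_of_evaluation=row["_date"],
                    raw_values={c: float(row[c]) for c in indicator_columns if pd.notna(row[c])},
                    context_values={s.name: float(row[s.name]) for s in context_specs},
                    prospect=bool(row[schema["prospect"]]),
                    coordinates=str(row[schema["coordinates"]]) if schema["coordinates"] in df.columns else "",
                )
            )
    records.sort(key=lambda r: (r.site, r.interval, r.prospect_id))
    seen = set()
    for r in records:
        if (r.site, r.interval) in seen:
            raise IntegrityError(f"duplicate (site, interval) pair ({r.site}, {r.interval})")
        seen.add((r.site, r.interval))
    return TransactionDatabase(
        records=records,
        context_specs=list(context_specs),
        indicator_columns=list(indicator_columns),
    )


def write_database(db: TransactionDatabase, path) -> None:
    """Write a database back to the CSV dialect :func:`load_database` reads."""
    rows = []
    for r in db.records:
        row = {
            "prospect_id": r.prospect_id,
            "site": r.site,
            "date_of_evaluation": r.date_of_evaluation.isoformat(),
            "prospect_coordinates": r.coordinates,
        }
        for c in db.indicator_columns:
            row[c] = r.raw_values.get(c, "")
        for s in db.context_specs:
            row[s.name] = r.context_values.get(s.name, "")
        row["prospect"] = int(r.prospect)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_database(db: TransactionDatabase) -> list:
    """Return a list of invariant violations; empty iff the database is mineable."""
    findings = []
    if not db.records:
        findings.append("database has no records")
    seen = set()
    known_contexts = {s.name for s in db.context_specs}
    for r in db.records:
        key = (r.site, r.interval)
        if key in seen:
            findings.append(f"duplicate (site, interval) pair {key}")
        seen.add(key)
        for name in r.context_values:
            if name not in known_contexts:
                findings.append(
                    f"record {r.prospect_id}: context value for unknown variable {name!r}"
                )
        if len(r.items) != len(set(r.items)):  # frozenset makes this vacuous; guard lists
            findings.append(f"record {r.prospect_id}: duplicate items")
    return findings


RULE_COLUMNS = [
    "antecedent",
    "consequent",
    "antecedent_negated",
    "consequent_negated",
    "support",
    "confidence",
    "interest",
    "interval",
    "supp_antecedent",
    "supp_consequent",
    "context_adjusted",
]


def write_rules(rules: Iterable[AssociationRule], path) -> None:
    """Serialize rules, one row each, grouped so an antecedent lists all its
    consequents on adjacent rows (up to the 7-consequent cap).

    Antecedent groups are ordered by descending best support, then
    lexicographic antecedent; within a group rows are ordered by descending
    support, then descending confidence, then consequent.  Support values
    are written with shortest-roundtrip float repr so a read-back is exact.
    """
    rules = list(rules)
    for r in rules:
        if len(r.consequent) > 7:
            raise ValueError(
                f"rule consequent has {len(r.consequent)} items; serialized rules cap at 7"
            )
    groups: dict = {}
    for r in rules:
        key = (itemset_tokens(r.antecedent), r.antecedent_negated)
        groups.setdefault(key, []).append(r)
    ordered_groups = sorted(
        groups.items(),
        key=lambda kv: (-max(r.support for r in kv[1]), kv[0][0], kv[0][1]),
    )
    rows = []
    for (ant_s, _), grp in ordered_groups:
        grp.sort(key=lambda r: (-r.support, -r.confidence, itemset_tokens(r.consequent)))
        for r in grp:
            rows.append(
                {
                    "antecedent": ant_s,
                    "consequent": itemset_tokens(r.consequent),
                    "antecedent_negated": int(r.antecedent_negated),
                    "consequent_negated": int(r.consequent_negated),
                    "support": repr(r.support),
                    "confidence": repr(r.confidence),
                    "interest": repr(r.interest),
                    "interval": r.interval,
                    "supp_antecedent": repr(r.supp_antecedent),
                    "supp_consequent": repr(r.supp_consequent),
                    "context_adjusted": int(r.context_adjusted),
                }
            )
    pd.DataFrame(rows, columns=RULE_COLUMNS).to_csv(path, index=False)


def read_rules(path) -> list:
    """Parse a rules CSV written by :func:`write_rules` back into rule objects."""
    df = pd.read_csv(path, dtype=str)
    rules = []
    for _, row in df.iterrows():
        rules.append(
            AssociationRule(
                antecedent=parse_itemset(row["antecedent"]),
                consequent=parse_itemset(row["consequent"]),
                antecedent_negated=bool(int(row["antecedent_negated"])),
                consequent_negated=bool(int(row["consequent_negated"])),
                support=float(row["support"]),
                confidence=float(row["confidence"]),
                interest=float(row["interest"]),
                interval=int(row["interval"]),
                supp_antecedent=float(row["supp_antecedent"]),
                supp_consequent=float(row["supp_consequent"]),
                context_adjusted=bool(int(row["context_adjusted"])),
            )
        )
    return rules


def load_config(path):
    """Load a YAML config holding context specs, thresholds and range tables.

    Expected top-level keys: ``context_specs`` (list of {name, civ, cfv}),
    ``thresholds`` ({ms, mc, mi, k}), optional ``ranges`` (per-indicator
    {breakpoints, labels}) and optional ``columns`` mapping overrides.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    specs = [ContextSpec(d["name"], float(d["civ"]), float(d["cfv"])) for d in raw.get("context_specs", [])]
    th = None
    if "thresholds" in raw:
        t = raw["thresholds"]
        th = Thresholds(float(t["ms"]), float(t["mc"]), float(t["mi"]), int(t.get("k", 3)))
    return {
        "context_specs": specs,
        "thresholds": th,
        "ranges": raw.get("ranges", {}),
        "columns": raw.get("columns", {}),
    }
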