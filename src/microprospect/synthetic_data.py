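"""Synthetic microbial prospection databases with planted associations.

The generator emulates the statistical shape of a desk-scale prospection
campaign: a grid of sites sampled over repeated time intervals, 29
soil/microbial indicators recorded per visit, a site-level Boolean
prospection outcome, and five context variables with a handful of
injected out-of-range instances.  Defaults match the benchmark shape —
28 sites x 178 intervals (4984 records), 20 prospect sites and seven
abnormal-context records per variable.

The co-occurrence model is a signal-plus-background mixture: a planted
rule A→MP contributes a joint "signal block" (all antecedent indicators
positive at once) drawn more often at prospect sites, calibrated so the
rule's empirical support and confidence hit the configured targets;
every indicator additionally fires independently at a background
marginal.  Context values are uniform inside their normal range;
anomalies sit a configurable multiple of the range width outside it.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .consolidate import rule_key
from .data_model import (
    AssociationRule,
    ContextSpec,
    Item,
    Record,
    TransactionDatabase,
)
from .discretize import PROSPECT_ITEM

logger = logging.getLogger(__name__)

#: the 29 indicator abbreviations (bacterial counts, hydrocarbon traces,
#: redox/pH chemistry, mineral precipitation, magnetic particles)
INDICATORS = (
    "Nmob", "Neob", "Npob", "Nbob", "Nsrb", "Ndb", "Ni", "Nhdf", "Noh", "Nah",
    "Rcdp", "Nimb", "Ahs", "An", "Ano", "Apd", "Orp", "Phs", "Pheh", "Rps",
    "Aio", "Ap", "Ac", "Qc", "Ppr", "Pg", "Ppy", "Pmg", "Qmp",
)

DEFAULT_CONTEXT_SPECS = (
    ContextSpec("temperature", 10.0, 40.0),   # deg C soil temperature
    ContextSpec("salinity", 0.5, 5.0),        # g/L water salinity
    ContextSpec("humidity", 30.0, 80.0),      # % relative humidity
    ContextSpec("rainfall", 100.0, 300.0),    # mm precipitation
    ContextSpec("fossil", 1.0, 50.0),         # fossil-pollution index
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRule:
    """One planted association A→MP with its target statistics.

    ``support`` is the target fraction of records containing the antecedent
    block together with a positive prospection outcome; ``confidence`` the
    target P(prospect | antecedent block).  ``interval_supports`` optionally
    overrides the support target per interval (0 plants no signal there) —
    used to stage temporally heterogeneous scenarios.
    """

    antecedent: tuple
    support: float = 0.3
    confidence: float = 0.9
    interval_supports: dict | None = None

    def key(self) -> str:
        rule = AssociationRule(
            antecedent=frozenset(Item(a, "1", "presence") for a in self.antecedent),
            consequent=frozenset({PROSPECT_ITEM}),
            antecedent_negated=False,
            consequent_negated=False,
            support=self.support,
            confidence=self.confidence,
            interest=0.0,
            interval=1,
        )
        return rule_key(rule)


@dataclass(frozen=True)
class ContextModel:
    """Sampling model of one context variable: normal range plus anomalies."""

    spec: ContextSpec
    n_abnormal: int = 7
    abnormal_side: str = "above"
    abnormal_magnitude: float = 0.75  # multiples of the range width


@dataclass
class GeneratorConfig:
    n_sites: int = 28
    n_intervals: int = 178
    seed: int = 0
    indicators: tuple = INDICATORS
    planted_rules: tuple = (PlantedRule(("Apd", "Pheh", "Aio")),)
    context_models: tuple = tuple(ContextModel(s) for s in DEFAULT_CONTEXT_SPECS)
    prospect_fraction: float = 20.0 / 28.0
    background_marginal: float = 0.15

    def __post_init__(self) -> None:
        if not 0 < self.prospect_fraction < 1:
            raise ConfigError("prospect_fraction must be in (0, 1)")
        for rule in self.planted_rules:
            for s in self._rule_supports(rule):
                self._check_feasible(rule, s)

    def _rule_supports(self, rule):
        if rule.interval_supports:
            return [s for s in rule.interval_supports.values() if s > 0]
        return [rule.support]

    def _check_feasible(self, rule, s):
        c, f = rule.confidence, self.prospect_fraction
        if not 0 < s <= c <= 1:
            raise ConfigError(f"planted rule {rule.antecedent}: need 0 < support <= confidence")
        p1 = s / f
        p0 = s * (1 - c) / (c * (1 - f))
        if p1 > 1 or p0 > 1:
            raise ConfigError(
                f"planted rule {rule.antecedent}: targets (s={s}, c={c}) infeasible "
                f"with prospect_fraction {f:.3f}"
            )

    @property
    def context_specs(self) -> list:
        return [cm.spec for cm in self.context_models]


def _signal_probabilities(rule: PlantedRule, s: float, f: float) -> tuple:
    """P(signal block | prospect site), P(signal block | barren site) hitting
    the targets: supp(A∧MP) = f·p1 = s and conf = s / (f·p1 + (1−f)·p0) = c."""
    c = rule.confidence
    p1 = s / f
    p0 = s * (1 - c) / (c * (1 - f))
    return p1, p0


def generate(config: GeneratorConfig) -> TransactionDatabase:
    """Draw a full prospection database; byte-deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n_sites, n_int = config.n_sites, config.n_intervals
    n = n_sites * n_int
    indicators = list(config.indicators)
    idx = {ind: j for j, ind in enumerate(indicators)}

    n_prospect = int(round(config.prospect_fraction * n_sites))
    prospect_sites = set(rng.choice(n_sites, size=n_prospect, replace=False).tolist())

    # background presence, then planted signal blocks overlaid
    present = rng.random((n, len(indicators))) < config.background_marginal
    site_of = np.repeat(np.arange(n_sites), n_int)
    interval_of = np.tile(np.arange(1, n_int + 1), n_sites)
    is_prospect = np.isin(site_of, list(prospect_sites))

    for rule in config.planted_rules:
        cols = [idx[a] for a in rule.antecedent]
        for t in range(1, n_int + 1):
            s_t = rule.support
            if rule.interval_supports is not None:
                s_t = rule.interval_supports.get(t, 0.0)
            if s_t <= 0:
                continue
            p1, p0 = _signal_probabilities(rule, s_t, config.prospect_fraction)
            mask_t = interval_of == t
            p = np.where(is_prospect, p1, p0)
            signal = (rng.random(n) < p) & mask_t
            present[np.ix_(signal.nonzero()[0], cols)] = True

    raw = np.where(present, np.round(rng.uniform(50.0, 500.0, present.shape), 2), 0.0)

    context = {}
    for cm in config.context_models:
        spec = cm.spec
        vals = np.round(rng.uniform(spec.civ, spec.cfv, n), 3)
        if cm.n_abnormal > 0:
            chosen = rng.choice(n, size=min(cm.n_abnormal, n), replace=False)
            width = spec.width
            if cm.abnormal_side == "above":
                vals[chosen] = round(spec.cfv + cm.abnormal_magnitude * width, 3)
            else:
                vals[chosen] = round(max(spec.civ - cm.abnormal_magnitude * width, 1e-6), 3)
        context[spec.name] = vals

    base_date = _dt.date(2015, 1, 1)
    records = []
    for i in range(n):
        site, t = int(site_of[i]), int(interval_of[i])
        records.append(
            Record(
                prospect_id=f"P{i + 1:05d}",
                site=f"site{site + 1:02d}",
                interval=t,
                date_of_evaluation=base_date + _dt.timedelta(days=7 * (t - 1)),
                raw_values={ind: float(raw[i, j]) for ind, j in idx.items() if raw[i, j] > 0},
                context_values={name: float(vals[i]) for name, vals in context.items()},
                prospect=bool(is_prospect[i]),
                coordinates=f"33-{site:02d}-00N 72-{t % 60:02d}-00E",
            )
        )
    return TransactionDatabase(
        records=records,
        context_specs=config.context_specs,
        indicator_columns=indicators,
    )


def inject_context_anomaly(
    db: TransactionDatabase,
    variable: str,
    record_selector,
    magnitude: float,
    side: str = "above",
) -> TransactionDatabase:
    """Push selected records' context value out of range by ``magnitude``
    range-widths (above CFV or below CIV); all other fields untouched.

    magnitude 0 lands exactly on the boundary, which still classifies as
    within range — a warning is issued since no adjustment will trigger.
    """
    spec = db.context_spec(variable)
    if magnitude == 0:
        warnings.warn("magnitude 0 places the value on the range boundary (still within)")
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    value = spec.cfv + magnitude * spec.width if side == "above" else spec.civ - magnitude * spec.width
    n = len(db.records)
    for i in record_selector:
        if not 0 <= i < n:
            raise IndexError(f"record index {i} out of bounds (database has {n} records)")
    records = list(db.records)
    for i in record_selector:
        r = records[i]
        ctx = dict(r.context_values)
        ctx[variable] = value
        records[i] = Record(
            prospect_id=r.prospect_id,
            site=r.site,
            interval=r.interval,
            date_of_evaluation=r.date_of_evaluation,
            items=r.items,
            raw_values=dict(r.raw_values),
            context_values=ctx,
            prospect=r.prospect,
            coordinates=r.coordinates,
        )
    return TransactionDatabase(records, db.context_specs, db.indicator_columns)


def suppression_rescue_scenario(seed: int, n_sites: int = 1000):
    """Stage the false-suppression scenario end to end.

    A genuine rule {Nmob, Neob} → MP is planted over five sampling
    intervals: at full strength (support 0.30) at intervals 1–2, damped
    into the adjustment band (support 0.18) at intervals 3–4, and absent
    at interval 5.  Rainfall is then forced below its normal range (50 mm
    against [100, 300]) for every record of intervals 3–4 — the abnormal
    context that damped the microbial signal.  The relative excursion is
    (100−50)·100/50 = 100%, so context adjustment doubles the damped
    support (0.18 → 0.36), carrying it back over a minimum support of
    0.24.  Mining context-off therefore sees the rule at two intervals
    only (dropped at k=3); context-on sees it at four.

    Returns (database, planted rule, recommended thresholds).
    """
    from .data_model import Thresholds

    rule = PlantedRule(
        ("Nmob", "Neob"),
        support=0.3,
        confidence=0.9,
        interval_supports={1: 0.3, 2: 0.3, 3: 0.18, 4: 0.18, 5: 0.0},
    )
    config = GeneratorConfig(
        n_sites=n_sites,
        n_intervals=5,
        seed=seed,
        planted_rules=(rule,),
        context_models=tuple(ContextModel(s, n_abnormal=0) for s in DEFAULT_CONTEXT_SPECS),
        background_marginal=0.1,
    )
    db = generate(config)
    selector = [i for i, r in enumerate(db.records) if r.interval in (3, 4)]
    db = inject_context_anomaly(db, "rainfall", selector, magnitude=0.25, side="below")
    return db, rule, Thresholds(ms=0.24, mc=0.72, mi=0.01, k=3)


def truth_table(config: GeneratorConfig) -> list:
    """Machine-readable manifest of the planted rules for recovery scoring."""
    return [
        {
            "key": rule.key(),
            "antecedent": list(rule.antecedent),
            "consequent": "MP",
            "support": rule.support,
            "confidence": rule.confidence,
            "interval_supports": dict(rule.interval_supports) if rule.interval_supports else None,
        }
        for rule in config.planted_rules
    ]
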