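"""Context-variable support adjustment — the step that makes mining
context-aware.

A context variable (rainfall, temperature, salinity, humidity, fossil
pollution) has an expert-defined normal range [CIV, CFV].  When the value
recorded at an interval falls outside that range, the supports of the
rules extracted there are corrected by the relative excursion

    difference = (CIV − value) * 100 / value      (below the range)
    difference = (value − CFV) * 100 / value      (above the range)

applied with opposite sign for positive and negative rules (four cases):
a positive rule's support is boosted when the context is below range and
shrunk when above; a negative rule's support moves the other way.  The
corrected support is then re-tested against ms, so rules falsely created
or falsely suppressed by an abnormal context are pruned or rescued.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, replace

from .consolidate import RuleSet
from .data_model import ContextSpec, Thresholds
from .pnarm import interest

logger = logging.getLogger(__name__)


def classify_context(value: float, spec: ContextSpec) -> str:
    """'below' | 'within' | 'above'; the bounds themselves count as within."""
    if value < spec.civ:
        return "below"
    if value > spec.cfv:
        return "above"
    return "within"


@dataclass(frozen=True)
class SupportAdjustment:
    """Outcome of one context correction on one rule's support."""

    context_name: str
    context_value: float
    civ: float
    cfv: float
    actual_support: float
    difference: float  # percentage surplus/deficiency, >= 0
    new_support: float
    polarity: str  # 'positive' | 'negative'
    case_id: str  # 'positive-below' | 'positive-above' | ... | 'within-range'


def adjustment_difference(value: float, spec: ContextSpec) -> float:
    """Percentage excursion of an out-of-range context value; 0 within range."""
    side = classify_context(value, spec)
    if side == "below":
        return (spec.civ - value) * 100.0 / value
    if side == "above":
        return (value - spec.cfv) * 100.0 / value
    return 0.0


def adjusted_support(
    actual: float,
    value: float,
    spec: ContextSpec,
    polarity: str,
    is_fraction: bool | None = None,
) -> SupportAdjustment:
    """Apply the four-case support correction for one context variable.

    Within-range values leave the support untouched (difference 0).  The
    corrected support is clamped at 0, and at 1 when the support is a
    fraction (inferred from ``actual`` <= 1 unless stated).
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    if actual < 0:
        raise ValueError("support must be >= 0")
    if value <= 0:
        raise ValueError(
            f"context value must be > 0 for relative adjustment, got {value}"
        )
    if is_fraction is None:
        is_fraction = actual <= 1.0

    side = classify_context(value, spec)
    if side == "within":
        return SupportAdjustment(
            spec.name, value, spec.civ, spec.cfv, actual, 0.0, actual, polarity, "within-range"
        )
    diff = adjustment_difference(value, spec)
    delta = actual * diff / 100.0
    # below range boosts positive rules / shrinks negative rules; above range
    # does the opposite — an abnormally high context can fake a positive rule.
    if (polarity == "positive") == (side == "below"):
        new = actual + delta
    else:
        new = actual - delta
    new = max(new, 0.0)
    if is_fraction:
        new = min(new, 1.0)
    return SupportAdjustment(
        spec.name, value, spec.civ, spec.cfv, actual, diff, new, polarity, f"{polarity}-{side}"
    )


_warned_variables: set = set()


def interval_context(records, name: str) -> float | None:
    """The interval's context value: the median of its records' values.

    Records within an interval routinely disagree (per-record measurement
    jitter); a warning is logged once per variable, further disagreements
    at debug level.
    """
    values = [r.context_values[name] for r in records if name in r.context_values]
    if not values:
        return None
    if len(set(values)) > 1:
        log = logger.debug if name in _warned_variables else logger.warning
        _warned_variables.add(name)
        log(
            "context %r varies within interval (%d distinct values); using median",
            name,
            len(set(values)),
        )
    return float(statistics.median(values))


def apply_context(
    ruleset: RuleSet,
    record_context: dict,
    specs,
    th: Thresholds,
) -> RuleSet:
    """Adjust every rule of an interval's ruleset for its out-of-range
    context variables and re-test against ms.

    Each abnormal variable is applied sequentially in spec order, every
    correction acting on the running support.  Confidence and interest are
    recomputed from the adjusted joint support (antecedent/consequent
    marginals are left as measured).  Rules whose adjusted support falls
    below ms are pruned; candidates mined below ms whose boost carries them
    over are kept.  When every variable is within range the ruleset is
    returned unchanged, no flags set.
    """
    ms = th.ms_fraction(ruleset.n_transactions) if ruleset.n_transactions else th.ms
    abnormal = [
        s for s in specs
        if s.name in record_context
        and record_context[s.name] is not None
        and classify_context(record_context[s.name], s) != "within"
    ]
    if not abnormal:
        kept = [r for r in ruleset.rules if r.support >= ms]
        return RuleSet(ruleset.interval, kept, ruleset.n_transactions)

    out = []
    for rule in ruleset.rules:
        polarity = "negative" if rule.is_negative else "positive"
        new_supp = rule.support
        for spec in abnormal:
            adj = adjusted_support(
                new_supp, record_context[spec.name], spec, polarity, is_fraction=True
            )
            new_supp = adj.new_support
        if new_supp < ms:
            logger.debug("pruned %s: adjusted support %.4f < ms %.4f",
                         rule.antecedent, new_supp, ms)
            continue
        changed = new_supp != rule.support
        conf = min(new_supp / rule.supp_antecedent, 1.0) if rule.supp_antecedent > 0 else 0.0
        out.append(
            replace(
                rule,
                support=new_supp,
                confidence=conf,
                interest=interest(new_supp, rule.supp_antecedent, rule.supp_consequent),
                context_adjusted=changed,
            )
        )
    return RuleSet(ruleset.interval, out, ruleset.n_transactions)


def candidate_ms_relaxation(record_context: dict, specs) -> float:
    """Factor f <= 1 such that mining candidates at ms*f cannot miss any rule
    whose boosted support could reach ms.

    Only boost-capable excursions matter: below-CIV for positive rules and
    above-CFV for negative rules both multiply a support by (1 + diff/100);
    the compounded product over abnormal variables bounds the reachable
    boost, so candidates at ms / product suffice.
    """
    factor = 1.0
    for spec in specs:
        value = record_context.get(spec.name)
        if value is None or value <= 0:
            continue
        if classify_context(value, spec) != "within":
            factor *= 1.0 + adjustment_difference(value, spec) / 100.0
    return 1.0 / factor
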