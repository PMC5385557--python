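# Methods

## Model

The package mines association rules over a *transaction database* of
microbial prospection records. Each record is one visit to one site during
one sampling interval; it carries raw measurements for 29 soil/microbial
indicators, the values of five context variables (temperature, salinity of
water, humidity, rainfall, fossil pollution), and a Boolean prospection
outcome. Records are itemized before mining:

- **binary mode** (default): every indicator with a positive raw value
  becomes a presence token `(indicator, 1, presence)`; zero, negative or
  missing values contribute nothing, so *absence is never positive
  evidence* — what absence means is exactly what the negated rule forms
  quantify. A true outcome contributes the prospect token `(MP, 1,
  presence)`.
- **ordinal mode**: raw values are binned into expert-supplied ranges
  (half-open bins `[b_i, b_{i+1})`; a value on a breakpoint joins the upper
  bin; out-of-range values either raise or clamp to the edge bin,
  policy-controlled). The package ships no default breakpoints: indicator
  ranges are domain input, and the equal-width helper provided for
  bootstrapping is explicitly a convenience, not part of the method.

Support is stored internally as a fraction of the interval's transactions.
The minimum-support threshold `ms` accepts either a fraction (≤ 1) or an
absolute transaction count (> 1, divided by the interval's record count).
This keeps count-style worked examples and fraction-style inequalities in
one consistent frame.

### Rule admission (fipi / iipi)

For disjoint nonempty itemsets A, B with supports measured at one interval:

- interest(A, B) = |supp(A∪B) − supp(A)·supp(B)|, the departure from
  statistical independence; it is symmetric in A and B and bounded by 0.25
  for a single binary configuration.
- A positive rule A→B is admitted ("frequent itemset of potential
  interest") iff supp(A∪B) ≥ ms, interest ≥ mi and conf(A→B) =
  supp(A∪B)/supp(A) ≥ mc.
- A negated configuration (A→¬B, ¬A→B, ¬A→¬B) is admitted ("infrequent
  itemset of potential interest") iff additionally supp(A) ≥ ms and
  supp(B) ≥ ms, and the *signed* joint event itself clears ms, mi and mc.
  Signed quantities use complement supports supp(¬X) = 1 − supp(X) and
  inclusion–exclusion: supp(A∧¬B) = supp(A) − supp(A∧B), supp(¬A∧B) =
  supp(B) − supp(A∧B), supp(¬A∧¬B) = 1 − supp(A) − supp(B) + supp(A∧B).
  The four signed joints therefore partition unity, which the test suite
  asserts to 1e-12 for every mined pair. Confidence of a ¬A antecedent is
  taken over supp(¬A) = 1 − supp(A).

Negation applies to a whole itemset side, never item-by-item within a
side, and negative candidates are drawn only from pairs whose plain parts
are individually frequent — this is what bounds the search. Positive rules
are enumerated as bipartitions of each frequent itemset with antecedent
size ≤ 4 (matching the four-term antecedents of the canonical worked
example) and consequent size ≤ 7 (the serialization cap: each antecedent
is written with all its consequents up to seven items).

Frequent itemsets come from a classical levelwise Apriori (join on shared
(k−1)-prefix, prune candidates with an infrequent k-subset). Support
counting uses per-item transaction-id sets with set intersection; the same
mechanism serves on-demand joint supports supp(A∪B) for negative-rule
pairs whose union is infrequent. Singleton supports are retained even
below ms — the iipi gate needs them — but flagged so they never seed
candidate generation.

### Context adjustment

Each context variable has an expert normal range [CIV, CFV]; bounds
inclusive (a value equal to CIV or CFV is within range, matching the
reading of "between 100 and 300" in the canonical example). The interval's
context value is the median of its records' values; per-record jitter is
expected, so disagreement is logged once per variable rather than per
interval. For an out-of-range value v the relative excursion is

    difference = (CIV − v) · 100 / v     (v < CIV)
    difference = (v − CFV) · 100 / v     (v > CFV)

and the four cases move a rule's support by `support · difference / 100`:
below-range adds for positive rules and subtracts for negative rules;
above-range does the reverse. Results are clamped to [0, 1] for fractional
supports (at 0 for counts). The excursion is relative to the measured
value itself, so the effect grows monotonically with distance from the
violated bound. Values ≤ 0 cannot be adjusted (division by the value);
such rules are left unadjusted and flagged.

Design choices where the procedure was genuinely open:

- **Composition.** With several simultaneously abnormal variables the
  corrections compose sequentially in spec order, each acting on the
  running support. Sequential multiplicative composition is commutative,
  and order-independent up to the clamps.
- **Level of adjustment.** The correction acts on rule-level support;
  confidence and interest are then recomputed from the adjusted joint
  support with the measured antecedent/consequent marginals. Raw
  transaction counts are never rewritten.
- **Crossing ms upward.** Adjustment can also *rescue* a rule whose
  measured support sits below ms when a boost-capable excursion exists
  (below-CIV for positive rules, above-CFV for negative ones). Since only
  existing candidates are re-tested, the fit pipeline mines such intervals
  with a relaxed candidate threshold ms/(1 + difference/100) — the exact
  bound on what a boost can reach — then filters at the true ms after
  adjustment. The full lattice is not re-mined under adjusted counts.

### Temporal consolidation

Rules are mined independently per interval; the final set keeps exactly
the rule *keys* (canonical sorted antecedent tokens + polarity + canonical
consequent tokens; statistics excluded) extracted at ≥ k distinct
intervals, default k = 3. A rule recurring twice within one interval
counts once. A final rule reports its contributing intervals, per-interval
support/confidence, and their means as the aggregate (the source procedure
prescribes no aggregate, so the per-interval values are retained
alongside). A *near-miss* diagnostic lists keys differing from a given
rule in exactly one predicate term — the situation where an abnormal
context flips a predicate direction — but near-misses are only reported,
never merged, since no predicate-level reconciliation rule is defined.

## Synthetic data generator

The generator emulates the statistical shape of a desk-scale prospection
campaign, not soil geochemistry. Defaults: 28 sites × 178 intervals (4984
records), 29 indicators, 20 of 28 sites bearing energy, and 7 out-of-range
records per context variable at 0.75 range-widths beyond the bound.
Normal-range context values are uniform on [CIV, CFV] (ranges: temperature
10–40 °C, salinity 0.5–5 g/L, humidity 30–80 %, rainfall 100–300 mm,
fossil-pollution index 1–50).

Indicator co-occurrence is a signal-plus-background mixture. Each planted
rule A→MP with targets (support s, confidence c) draws its antecedent
block jointly: P(block | prospect site) = s/f and P(block | barren site) =
s(1−c)/(c(1−f)), where f is the prospect fraction — these solve
supp(A∧MP) = s and conf = c exactly in expectation. Every indicator
additionally fires independently at a background marginal (default 0.15).
Infeasible targets (probabilities above 1) are rejected at configuration
time. A planted rule may carry per-interval support overrides, which is
how temporally heterogeneous scenarios (signal damped at specific
intervals) are staged. The generator is fully deterministic given its
seed, to the byte in CSV form.

What the generator does *not* model — and hence what passing tests do not
establish about field data: realistic count distributions or detection
limits for the indicators, spatial correlation between neighbouring sites,
temporal autocorrelation of context series, any mechanistic link between a
context value and indicator levels beyond the staged scenarios, and
missingness patterns. Tests on this generator validate the *mining
machinery* under the statistical structure the miner assumes, nothing
more.

The shipped suppression/rescue scenario stages the method's motivating
situation quantitatively: a genuine rule at support 0.30 at two intervals,
damped to 0.18 (inside the adjustment band) at two intervals where
rainfall is forced to 50 mm (100% excursion below a 100–300 range, so
adjustment doubles the damped support to 0.36), absent at a fifth.
Against ms = 0.24 and k = 3, context-off mining finds the rule at two
intervals and drops it; context-on finds it at four and keeps it.

## Numerical and procedural choices

- Canonical item order is lexicographic on (indicator_id, relation,
  level); itemset serialization and rule keys inherit it, so identity is
  stable under term reordering and across runs.
- Supports are exact ratios count/n; oracle tests demand bit-exact
  equality between the levelwise miner and powerset enumeration, which
  holds because both compute the same rational values.
- Rule CSV serialization writes floats with shortest-roundtrip repr;
  read-back reproduces every field exactly.
- negative_supports validates the Fréchet bounds
  (max(0, supp(A)+supp(B)−1) ≤ supp(A∧B) ≤ min(supp(A), supp(B)), ±1e-9)
  and raises rather than emit a negative probability — this guards the
  pipeline when adjusted supports are fed back through derived quantities.
- Degenerate inputs: empty transaction lists and zero antecedent supports
  raise typed errors; all-zero records are kept (they count in n); an
  empty planted-rule list yields an empty manifest; k larger than the
  number of intervals yields an empty final set.
- Mining output is independent of transaction order and interval order
  (asserted by tests); end-to-end runs on identical config and data
  produce identical artifacts (checked by file hash).

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
statistics decisive while staying desk-scale: oracle equivalence uses 200
random databases of ≤ 8 items and ≤ 20 transactions (rule enumeration at
≤ 6 items, where exhaustive signed-pair enumeration is exact and cheap);
planted-rule recovery uses 10 seeds × 5000 records (1000 sites × 5
intervals), where a planted support of 0.30 against ms = 0.24 sits ≈ 4
standard errors above the threshold per interval; the regime comparison
uses 240 records over 4 intervals with a 5-point ms grid. The worked-example
reconstruction and adjustment arithmetic are exact and size-independent.

## Known limitations

- The support adjustment is the prescribed relative-excursion heuristic;
  it is not derived from a probabilistic model of context influence, and
  `difference` > 100% can clamp supports to 0 or 1.
- Candidate rescue re-tests mined candidates only; a rule whose *subsets*
  were pruned at the relaxed threshold cannot be recovered.
- Negative-rule enumeration over all disjoint pairs of frequent itemsets
  is quadratic in the number of frequent itemsets; the implementation
  targets desk-scale databases (thousands of records), not market-basket
  scale.
- CIV/CFV are expert inputs; the package deliberately does not learn them
  from data.
- Cross-site consolidation simply treats per-interval rule sets uniformly;
  no site-stratified semantics are implemented.
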