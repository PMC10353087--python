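# Methods

## Scope and data model

The package structures 15 concepts from Chinese reproductive outpatient
notes: menstrual history (menarche age, cycle length, menstruation amount),
hormone tests (date, FSH, LH, E2, P, PRL, T, AMH) and ultrasound measures
(endometrial thickness, uterine position, left/right antral follicle
counts). Documents carry a structured age field; gold labels are stand-off
annotations — `(concept, half-open character span, normalised value,
optional date, optional unit)` with spans counted in Unicode code points,
which is the only unambiguous convention for CJK text.

Six hormones plus AMH, endometrial thickness and the two follicle counts
are *timed* concepts kept as date-ordered `(date, value)` series; the
remaining concepts keep the first occurring value only.

## Rule-based extraction

**Sections.** The extractor locates 现病史 and 月经史 by their headers; the
section runs to the next recognised header or end of text. Sections are
offset windows — the raw text is never rewritten, so spans stay valid.
When neither header exists the whole document becomes one pseudo-section
with a warning: for a screening tool, recall is preferred over failing.

**Patterns.** One compiled pattern per concept, from three families:
quantity (keyword, separator or a bounded non-numeric filler, signed
decimal, optional unit), categorical (keyword then one of the concept's
qualitative tokens, longest first), and date (年月日 plus optional `-` and
`.` dialects). Keywords match longest-first. Latin aliases are guarded
against in-word hits (not adjacent to Latin letters), and single-letter
aliases (E, P, T) must additionally head a value (optional separator then a
digit) — this keeps E out of `TEST`/`En` and P out of `PRL`. The numeric
token is deliberately loose (`\d+(?:\.\d*)*`) so that clinician typos like
`5..32` are *captured* and then rejected by postprocessing rather than
silently half-matched.

**Date–value pairing.** Sentence items are bounded by full stops,
semicolons and newlines; a half-width period splits only when it is not
acting as a decimal point (not followed by a digit or another dot). Inside
an item every value is paired with the nearest preceding date; values
before any date get a null date, and dates never leak across a full stop.
Comma-joined measurements therefore inherit the date that opens their
sentence, which reflects the `2018年10月3日查FSH…，LH…` reporting style.

**Postprocessing.** Four ordered checks, each drop logged with a reason
code: malformed numerics (multiple decimal points, unparseable tokens);
date-like values (integers 1900–2100) for non-date concepts; plausibility
windows (FSH/LH 0–200 IU/L, E2 0–10 000 pg/mL, P 0–300, PRL 0–10 000,
T 0–100, AMH 0–30 ng/mL, endometrium 1–30 mm, per-ovary AFC 0–60, menarche
8–20 y, cycle 10–365 d — editable in the packaged concept table; values in
an alternate unit are converted for the check only, e.g. AMH pmol/L ÷
7.14); and exact `(concept, date, value)` duplicates collapsed to the first
occurrence. The operation is idempotent.

The menstrual-cycle concept accepts the `X/Y天` shorthand (menses days /
cycle days) with ranges (`5-7/28-30天`) and the explicit `月经周期Y天`
form; ranges are kept as `(lo, hi)` pairs.

## GP regex synthesis

An individual is a regex encoded as an ordered syntax tree over character
classes (`\d`, `\w`, `[a-z]`, `[A-Z]`, `[0-9]`), literal characters
observed in the snippets, mined building blocks, possessive quantifiers
(`++`, `*+`, `?+`), concatenation and disjunction. Possessive quantifiers
are preferred in random generation to preclude catastrophic backtracking;
uncompilable or over-length (> 300 chars) expressions score 0.

**Building blocks** are maximal substrings occurring in more than 90% (the
threshold is configurable) of the desired extractions, mined by exhaustive
substring counting and sorted longest first.

**Seeding.** For every example four trees are built that extract exactly
its desired portions: the literal; a character-class generalisation; a
quantifier-compressed generalisation; and a building-block substitution.
When a generalisation would over-match on its own snippet it is anchored
with the shortest fixed-width lookbehind context that restores exactness
(the full-prefix literal anchor is the guaranteed fallback). This
exactness-by-construction is asserted as a test invariant.

**Evolution** is elitist and generational: each step creates as many new
individuals as the population holds — 10% random (ramped half-and-half,
depth ≤ 4), 10% by subtree mutation, 80% by subtree crossover, with size-7
tournament selection — then keeps the best distinct expressions of the
merged pool (duplicate serialisations are removed during truncation, which
preserves diversity at no cost to elitism). Fitness is compared
lexicographically: higher character-level F first, then shorter regex, then
serialisation order, giving deterministic total order. Termination is at
`n_gen` generations or when the best fitness is unchanged for `n_stop`
generations.

**Separate-and-conquer.** Branches joined by `|` are accepted only at
perfect precision on the residual example set; accepted branches remove the
examples they fully solve and evolution recurs on the remainder, up to a
branch cap. The branch taken from one evolution run is the most-recalling
perfectly-precise individual among the final population *plus the
residual's seed individuals* — seeds belong to that run's initial
population, but aggregate-F ranking can displace precise specialists, and
re-admitting them guarantees progress toward full training recall. When no
precise candidate exists the loop stops and the plain best-by-F regex is
returned.

Default evolution settings (population 100, 60 generations, stall 10) suit
interactive use; the study-condition experiments in the test suite run a
scaled profile (population 60, 15 generations, stall 5, ≤ 25 training
examples, branch cap 5), which the learning tasks below converge under.

**Experiments.** `run_experiment` splits a corpus deterministically,
trains on a fraction, and reports span-level precision/recall/F on held-out
snippets under the same annotation convention used for training (keyword +
value + unit, or value + unit only). Two packaged tasks reproduce the
qualitative findings: a high-variability menstrual-shorthand task (four
cycle dialects with distractor numbers) where held-out F grows with the
training share because small samples miss rare dialects, and a
multi-hormone panel task (identical numeric formats, keyword as the only
reliable cue) where keyword-annotated training is at least as good as
value-only training.

## Diagnostic scoring and stratification

Thresholds live in one configuration block: FSH 10 / 25 / 40 IU/L, AMH
1 ng/mL, AFC 5 follicles, cycle window 24–35 days, four weeks = 28 days,
age gate 40 years. Numerical conventions:

- "> 4 weeks apart" means strictly more than 28 days between two qualifying
  *dated* occasions; an occasion is a distinct calendar date; undated
  measurements count toward the occasion number but cannot certify the
  separation (a conservative 2, never 3).
- mIU/mL is numerically equal to IU/L for FSH/LH; AMH in pmol/L is divided
  by 7.14; the minimum documented AMH is used.
- Per-occasion AFC totals are formed only where left and right counts share
  a date; a missing side nulls the occasion. A single undated exam with
  exactly one count per side is also paired.
- Cycle ranges are abnormal iff the minimum is below 24 or the maximum
  above 35 days.
- A block total is the sum of its non-null subscores and null only when
  every subscore is null — EMR data are incomplete, and a partially
  documented patient should still be scorable.

Stratification is deliberately looser than the strict criteria (one
abnormal pivotal result reveals risk): all applicable subscores null →
Insufficient; FSH>40 subscore ≥ 1 under 40 → POF; else FSH>25 subscore ≥ 1
under 40 → POI; else DOR total ≥ 1 → DOR; else Healthy. POF/POI/DOR are
high risk, Healthy low, Insufficient indeterminate. Menstrual irregularity
alone maps to Healthy by default — the least certain design point, isolated
behind `require_irregular_menses`, which restores the textbook conjunction
of irregular menses and elevated FSH. By construction a Healthy label
forces a DOR total of 0 (or null), so the Healthy group's mean DOR score is
exactly 0 — the model-construction quantity the acceptance script reports.

## Evaluation

Timed concepts are compared as multisets of `(date, value)` pairs (the
stricter reading for series that trace dynamic change): matched pairs are
TPs, unmatched predictions FPs, unmatched gold FNs; a concept absent on
both sides is one TN. Non-timed concepts compare single values; a
mismatched value counts as a false positive. Values are compared exactly
after normalisation (extraction is string-derived; no epsilon).
Zero-denominator convention: nothing to find and nothing found → all
metrics 1.0; nothing found with gold present → precision undefined
(excluded from averages), recall 0. Cross-validation uses a deterministic
shuffled k-fold partition and Student-t 95% intervals over fold means.
Paired t and Friedman tests compare extraction methods per concept. Risk
screening is a 2×2 accuracy/sensitivity with high risk as the positive
class; label agreement uses Cohen's kappa, reported null with a warning for
a degenerate reference.

## Synthetic corpus generator

The generator defines the study conditions. Latent profiles are drawn from
a state mixture (healthy 0.55, DOR 0.20, POI 0.15, POF 0.10) with FSH bands
straddling the diagnostic thresholds (healthy 4–9, DOR 10.5–24, POI
25.5–39, POF 41–120 IU/L), AMH and AFC bands consistent with each state,
1–3 dated hormone panels 10–60 days apart, and menstrual values such that a
healthy profile violates *every* criterion and a POF profile exceeds
40 IU/L on at least one dated occasion under age 40. Rendering mimics
outpatient style: 主诉 / 现病史 / 月经史 / 既往史 sections, keyworded
panels with dates, per-ovary follicle counts, cycle shorthand, qualitative
amount tokens. Dialect rates cover unit variants (IU/L vs mIU/ml, AMH
pmol/L), keyword synonyms (抗苗勒管激素, En, E), full/half-width
punctuation and ranged cycles; the extra date dialects (ISO and dotted) are
off by default, matching the single 年月日 form of the source material.

Per-concept missingness defaults (2–25%) reflect that AMH and qualitative
menstrual details are the most often undocumented. Noise corruptions are
injected at low per-document rates (3–4%) and logged out-of-band: a typo
doubles a decimal point (and removes that value's gold annotation, since
the intended value is no longer extractable), a duplicate restates a
measurement verbatim, an out-of-range corruption injects `FSH 5000`, and a
date-in-value corruption injects `内膜 2018`. Gold always describes the
intended correct values, so on this generator a perfect extractor plus
postprocessor reproduces gold exactly — which the tests assert.

**What passing tests do and do not show.** The generator's surface
variety is a modelling choice reconstructed from a single worked example
and the concept table; real notes from other hospitals will have styles,
negations and therapy context the generator does not emulate. Perfect
extraction here demonstrates the machinery is correct under the stated
conditions, not that real-world F-scores would be perfect; conversely the
scoring and stratification layers are exact implementations of the stated
criteria and transfer as-is.

## Problem sizes

The shipped test-and-acceptance runs use 400-document corpora for the
extraction quality bar, 500 documents × 3 seeds for the oracle-equivalence
check, 1 000 documents × 3 seeds for gold-span fidelity, 200-patient
cohorts for parameter recovery and the Healthy-group score, and 40-example
GP tasks over 5 seeds for the learning trends — sizes chosen to make every
stochastic check decisive while keeping a full run inside a few minutes on
one CPU.

## Known limitations

- No negation or pre-/post-therapy temporality handling; all documented
  values are taken at face value.
- Menstrual narratives richer than the supported shorthands (free-text
  fluctuation descriptions) are out of scope.
- The machine-regex path extracts whole matches and recovers the value as
  the first numeric token inside the match; machine regexes trained on
  value-only annotations therefore pair dates correctly but may not carry
  units.
- Same-day repeated panels count as one occasion; this is a stated
  convention, not clinical ground truth.
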