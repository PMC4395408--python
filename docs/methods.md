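# Methods

## Problem and model

The package estimates early disease risk from longitudinal outpatient
claims. Each patient is reduced to a *transaction*: the set of distinct
ICD-9-CM diagnosis codes in their retained history, labelled RA or non-RA.
For RA patients the retained history is everything strictly before the
*index date* — the first qualifying RA diagnosis (ICD-9-CM 714.0x, or
legacy A-code 430 on pre-2000 records) accompanied by a
catastrophic-illness confirmation — so every mined pattern predates the
definite diagnosis and can in principle serve as an early-warning signal.

A class association rule `P => c` (P an itemset, c a class) is scored by

* **group support** `sup(P|c)` — fraction of class-c transactions
  containing P. The minimum-support threshold is applied per class, which
  is the scale on which group support percentages are conventionally
  reported, and which keeps rules for the small RA class minable at all
  under heavy class imbalance.
* **confidence** `conf = |P ∧ c| / |P|` over the whole database, the
  empirical P(c | P).
* **lift** `conf / P(c)` — 1 under independence.
* **relative risk** `RR = sup(P|RA) / sup(P|nonRA)` with a 95% CI by the
  Katz log method, `exp(ln RR ± 1.96·√(1/a − 1/n₁ + 1/b − 1/n₂))`. The CI
  method is a package choice; it is the standard closed form for a ratio
  of two binomial proportions and its empirical coverage is checked by
  simulation in the test suite (≈95% at nominal 95%).
* **χ²** of the 2×2 table (P present/absent × class c/not-c), defined as 0
  whenever a margin is empty.

### Mining

The rule search is exhaustive: depth-first enumeration over per-item
transaction bitsets, pruning a prefix as soon as it is infrequent in every
class (class-relative support is anti-monotone per class). This produces
exactly the same rule set as FP-growth would; on a few thousand patients
and a few hundred distinct codes the bitset scan is simpler and fast
enough (about one second for 800 transactions, 80 codes, antecedents up to
length 3). All counts are exact integers; a brute-force powerset
enumerator in the test suite checks equality of the complete rule set on
dozens of random databases.

Pruning follows the CMAR scheme:

1. *general-rule* pruning — a rule is dropped when a proper subset of its
   antecedent implies the same class with at least its confidence (ties
   favour the more general rule);
2. *correlation* pruning — rules with χ² below a threshold (default 3.84,
   p≈0.05 at 1 d.f.) are dropped;
3. *database coverage* — scanning rules by precedence (confidence desc,
   support desc, shorter antecedent, lexicographic), a rule is kept iff it
   matches at least one transaction not yet covered δ times (default δ=4);
   a transaction retires once covered δ times. Coverage counts any matched
   transaction regardless of its class label.

Rule precedence is a total, deterministic order, so identical inputs give
byte-identical rule sets.

### Classification

A new patient's code set collects all matching rules, grouped by
consequent. Each group's score is `Σ χ²·χ²/maxχ²`, where `maxχ²` is the
largest χ² attainable at the rule's margins (antecedent support, class
support, database size — all frozen from the training set, so prediction
never touches test labels). The larger score wins. Two decisions the
method itself does not fix:

* a patient matching **no rule** receives the training majority class
  (non-RA under realistic imbalance) — configurable;
* an exact score **tie** goes to RA — the tool is a screening aid, so the
  default favours sensitivity; also configurable.

`CMARClassifier` packages mine → prune → vote as a scikit-learn estimator
(`fit`/`predict`/`get_params`, `classes_`, `rules_`), so it composes with
sklearn model selection; the module-level functions (`mine_cars`, `prune`,
`classify`, `evaluate`, `metrics`) expose the same steps functionally.

### Validation

Ten-fold cross-validation over patient transactions, stratified by class:
with cohorts as imbalanced as real registries (≈0.1% RA) an unstratified
split can lose the RA class from folds entirely, and stratification is
required already at the synthetic scales used here. Sensitivity
`TP/(TP+FN)` and specificity `TN/(TN+FP)` treat RA as positive; an empty
denominator yields an absent value, never 0, and fold averages are taken
over defined values only. Two sweeps rerun the CV per grid value: minimum
support over 0.1%–1.1% in 0.2% steps (production choice 0.7%), and the
record-count filter over {4, 9, 15} (production choice 15, roughly five
visits at ≤3 codes per visit). The "best" grid value maximises the mean of
average sensitivity and average specificity.

### Chapter table and viewer report

Rules aggregate into the 17 numeric ICD-9-CM chapters (001–139 … 800–999).
A rule counts toward a chapter when *any* antecedent code falls in its
range — a rule can hit several chapters; V- and E-codes go to an explicit
"unmapped" bucket. Per chapter the table reports the fraction of each
class's rules touching it, their ratio (RR over rules, not patients — the
per-patient alternative is a documented variant), and a Katz CI over rule
counts; chapters empty in both classes report RR 0 with a null CI. The
viewer report is a two-part JSON: per-chapter summary (pattern share,
class breakdown, distinct-disease count) and a per-pattern listing (group,
confidence, group support %, lift, codes, descriptions), sortable by any
numeric attribute.

### Literature novelty

For a pattern's diseases the query
`d1[TIAB] AND ... AND dn[TIAB] AND target[TIAB]` counts PubMed records
naming every disease together with the target in title/abstract. A
pattern is Type II (novel) iff the joint count is ≤ a threshold, default
0 — "never reported" is the only sharply testable reading; "rarely
reported" is the user's threshold to set. Counts flow through a
single-method client protocol: a CSV/dict fixture offline, or NCBI
E-utilities (rate-limited, via biopython) live. Tests use only the
fixture client.

## Synthetic cohort generator

The generator emulates the *structure* of a nationwide claims registry,
not its content:

* two classes with configurable sizes (defaults 200 RA / 800 non-RA — a
  deliberately scaled-down case-control design; the real registry ratio of
  ≈1:730 would make desk-scale statistics vacuous);
* calendar window 1997-01-01..2008-12-31; per-patient visit counts
  Poisson(mean 10, min 2); 1–3 codes per visit, sampled without
  replacement within a visit from a weighted pool of ~75 common outpatient
  codes spanning all 17 ICD-9-CM chapters;
* demographics per class: RA age ≈ N(58.7, 15.4²), 77% female; non-RA age
  ≈ N(42.5, 20.6²), 49% female;
* every RA patient gets an index visit strictly inside the window with at
  least one earlier visit: code 714.0 (or A-code 430 when the index falls
  before 2000) with the catastrophic flag set; all other RA rows are
  dated strictly before the index (post-index rows only on request, to
  exercise truncation);
* planted patterns: each patient is an independent Bernoulli carrier at
  the configured class-conditional fraction; carriers get every pattern
  item by overwriting randomly chosen background slots (pre-index slots
  for RA), so carrier status is guaranteed regardless of visit count.
  Planted codes should be chosen outside the background pool when exact
  closed-form statistics are wanted (the shipped defaults are);
* optional row corruption at a configured rate, cycling through four
  modes — blank ID, invalid sex, birth date after visit, empty code — one
  per cleaning rule; rows establishing the RA index are never corrupted,
  so the sidecar labels remain the ground truth of the emitted file;
* a ground-truth sidecar records labels, index dates, per-pattern carrier
  assignments and the corruption tally.

`expected_pattern_stats` returns the closed-form confidence, per-group
support, lift and RR implied by the carrier fractions and class sizes;
realized cohorts fluctuate binomially around these, which is the tolerance
the end-to-end tests use (99% binomial bands on carrier counts, propagated
to confidence and RR).

What the generator does **not** model: disease co-occurrence structure
beyond the planted patterns, code frequencies drifting over calendar time,
visit-frequency/age/sex dependence, drug or inpatient records. Passing
tests therefore demonstrate that the pipeline recovers known signal from
realistic-shaped noise — not that any particular clinical association
holds.

## Numerical and design notes

* RA case matching uses the prefix 714.0 (covers 4- and 5-digit dialects);
  codes are compared as trimmed exact strings otherwise — no ICD hierarchy
  rollup, since raw codes are what claims carry.
* The record-count filter counts diagnosis rows (not visits), is inclusive
  at the boundary (exactly 15 rows survives), and is monotone in the
  threshold.
* Minimum-support thresholds convert to integer count thresholds with
  `ceil(frac·class_size − 1e−9)`; confidences are compared exactly.
* χ² of a degenerate table (any empty margin) is 0, and a rule whose
  maxχ² margins are degenerate contributes 0 to the vote.
* Undefined quantities (RR with a zero denominator, confidence of an
  absent pattern, sensitivity with no positives) are reported as absent
  values with explanatory flags, never coerced to 0.
* Determinism: one pseudo-random stream ordered by (patient, visit, slot)
  in the generator; seeded `StratifiedKFold` for folds; total rule
  precedence order. Identical config + seed reproduces cohorts, folds,
  rule sets and reports exactly.
* The separable sanity check (carriers 1.0/0.0) runs at minimum support
  0.3 / minimum confidence 0.9: at looser thresholds, chance associations
  in finite background noise legitimately become rules and perfect
  specificity is not a property the data has.
* Problem sizes in the tests and the acceptance script (1,000-patient
  cohorts, ≤60-transaction oracle databases, 1,000-draw coverage
  simulations) are chosen so the whole analysis reruns in well under a
  minute per component on one CPU while keeping sampling error far below
  the asserted tolerances.

## Known limitations

* Confidence is a case-control quantity: it depends on the cohort's class
  ratio and is not a population P(RA | pattern) unless the sampling ratio
  matches the population.
* The weighted-χ² vote is a heuristic score, not a calibrated
  probability; no probability outputs are offered.
* Chapter-table RRs are computed over rules, which overweights chapters
  that appear in many overlapping rules; a per-patient variant would need
  the underlying transactions.
* The A-code crosswalk covers only the RA definition pair (430 ↔ 714.0).
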