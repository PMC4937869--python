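# Methods

This note records the scientific and numerical conventions of the package:
what each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Problem setting

Many independently developed models predict, for each chemical in a large
screening library, whether it binds the estrogen receptor and whether it
acts as an agonist or antagonist; a few models additionally predict a
potency (AC50, µM). Individual models err in different ways, so their
calls are combined into an accuracy-weighted consensus, evaluated against
two imperfect gold standards: high-throughput-screening (HTS) activity
scores and a multi-source literature compilation.

## Structure curation

The curation cascade runs parse → carbon filter → desalting → molecular
weight filter → standardization → InChI deduplication → metal filter.
Conventions:

* **Parsing.** Records that fail valence or integrity checks are dropped
  and logged under `invalid_structure`. A `resolver` hook can supply a
  replacement structure for an invalid record (the original procedure
  queried online registries); the default resolver is "drop".
* **Desalting.** The kept fragment is the carbon-containing fragment with
  the most heavy atoms; ties break by molecular weight, then by the
  lexicographically smallest canonical SMILES. If no fragment contains
  carbon the record counts as inorganic.
* **Weight filter.** Strictly greater than 1000 g/mol is removed; exactly
  1000 is kept ("exceeding" is strict).
* **Standardization** uses the RDKit `rdMolStandardize` machinery: the
  functional-group normalizer (which unifies nitro/azide mesomer
  drawings), the uncharger (protonation/deprotonation only where the
  charge can be balanced by hydrogen bookkeeping — quaternary ammonium and
  similar permanent ions stay charged and are kept), full stereo stripping
  (tetrahedral and double-bond), and the canonical-tautomer enumerator,
  whose fixed published rule set covers keto-enol, enamine-imine and
  ynol-ketene interconversions. The enumerator is broader than those three
  named families, which we accept in exchange for a deterministic,
  idempotent canonical form maintained upstream; standardization is a
  fixed point (tested).
* **Deduplication** keys on the standard InChI and nothing else. Whether
  aromatization runs before or after InChI generation is immaterial for
  dedup because InChI normalizes aromaticity internally; canonical SMILES
  output reflects RDKit's aromaticity perception.
* **Metal filter.** The allowed-element set is
  {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; everything else counts as a
  metal. Si/Se/B retention is a deliberate default (organosilicons,
  selenoamino acids and boronic acids are standard QSAR substrate) and the
  set is a function argument.
* **Bookkeeping.** Each removed record is counted once, under the first
  filter that rejected it; `n_input = n_output + Σ removals + Σ merges`
  is asserted.

Explicit hydrogens are not materialized in the stored canonical SMILES;
InChI handles hydrogen counts internally, so this does not affect
deduplication.

## Literature harmonization and reference sets

* Units are converted to µM by exact powers of ten (M, mM, µM, nM, pM).
  Mass-per-volume units would need a molweight join and are dropped as
  ambiguous, as are in-vivo and cytotoxicity records and records with
  neither an endpoint value nor an activity flag. A record with a
  quantitative endpoint but no flag is treated as active at that AC50 (a
  reported AC50 implies measured activity).
* Cell-proliferation records are active iff the response exceeds 125% of
  control; their AC50 is the concentration reported in the assay field.
* Inactive records carry the sentinel AC50 of 1 M (1e6 µM).
* **Categorical reference.** Within each (chemical, activity class) group
  the minority-call fraction is the disagreement; groups with
  disagreement strictly above 20% are removed (exactly 20% keeps the
  majority call — the removal rule says "exceeds"). Then an active
  agonist or antagonist fills a missing binding call as active, and a
  chemical inactive as both agonist and antagonist fills it as inactive.
  Propagation also fills binding slots whose observed group was removed
  for disagreement (removed = no usable information), but never
  overwrites a surviving observed binding call.
* **Potency reference.** Each entry's AC50 maps to one of five classes:
  strong < 0.09 µM, moderate [0.09, 0.18), weak [0.18, 20),
  very weak [20, 800], inactive > 800. Boundaries are half-open with the
  lower bound belonging to the weaker class, except 800 µM itself, which
  is still very weak ("higher than 800" is inactive). Classes score
  {0, 0.25, 0.5, 0.75, 1}; the arithmetic mean of per-entry scores drives
  the merged class (strong > 0.75 ≥ moderate > 0.5 ≥ weak > 0.25 ≥
  very weak > 0 = inactive, with a 1e-9 tolerance on the comparisons).
  The log10-median AC50 is computed and stored as a descriptive field but
  does not drive the class; the two summaries are deliberately both
  emitted so either convention can be compared downstream.

## Model evaluation

Six evaluation subsets per model: (1) HTS chemicals whose
activity-relevant AUC score lies outside the ambiguous [0.01, 0.1) band
(active iff AUC > 0.01); (2) all literature-reference chemicals; (3) at
least two sources; (4) excluding very-weak actives; (5) inside the
model's applicability domain, defaulting to subset 2 when no AD was
supplied; (6) the intersection of 3–5. The ambiguity band applies to the
AUC of the model's own activity class (a config switch widens it to any
of the three AUCs). HTS chemicals are *not* excluded from literature
subsets.

Balanced accuracy is the mean of sensitivity and specificity; a zero
margin leaves the metric undefined (`None`), never coerced to 0 or 0.5.
Score₁ weights each literature-subset BA by the model's coverage of that
subset and by its global coverage, normalized by the five literature
filters; an undefined subset BA contributes zero and is logged. Score₂
is the unweighted mean of the HTS BA and the all-filters BA; a model with
undefined Score₂ is excluded from the consensus with a warning.

Continuous models are binned through the potency classes and scored per
literature subset as the unweighted mean of the five one-vs-rest BAs
(classes absent from a subset are skipped, not imputed). On the HTS
subset, where only a binary label exists, a continuous model is scored as
binary with active = any non-inactive class. The multiclass aggregation
and the HTS convention are package choices; the source procedure does not
specify them.

## Consensus and corrections

For each chemical, the Score₂ values of active-calling and
inactive-calling models are summed and divided by the number of
predicting models; the larger average wins and ties go to active (the
screening context prefers false positives to false negatives). With equal
scores this reduces to simple majority voting, and each side's average
tracks its concordance (fraction of predicting models on that side).
Models that did not predict the chemical are excluded; chemicals predicted
by no model are emitted as `not_predicted` rather than dropped.

The quantitative consensus weights each continuous model's predicted
class score by wⱼ = scoreⱼ/Σscore and rounds C = Σ wⱼ s(Pⱼ) to the
nearest class score, ties toward the more potent class (conservative for
screening).

Corrections run in one pass, agonist and antagonist first, binding last:

1. a categorically active chemical becomes quantitatively active, its
   potency read from the active concordance (≥ 0.9 strong, ≥ 0.75
   moderate, ≥ 0.6 weak, else very weak);
2. a quantitatively active chemical with ≥ 3 active categorical calls
   becomes categorically active;
3. a chemical with < 3 active categorical calls (raw call counts, not
   score-weighted) is forced quantitatively inactive;
4. an active agonist or antagonist becomes an active binder and binding
   inherits its potency class (the more potent if both endpoints are
   active).

The pass is implemented as the fixed point of these rules: rule 1 skips
chemicals that rule 3 would immediately demote, and the binding rules 1/3
skip chemicals that rule 4 overrides. The final state is identical to the
literal 1→2→3→4 sequence; only log churn (promote-then-demote pairs in a
single pass) is avoided, which makes the correction idempotent — a second
application produces an empty log (tested). An optional fixed-point
iteration mode exists but is off by default since one pass already
reaches the fixed point. When model concordance is near 0.5 only one or
two models drive the classification; no special handling is applied.

The threshold sweep counts a chemical as a potential active at threshold
t when at least one model called it active and its active concordance is
≥ t; counts are non-increasing in t by construction, and metrics are
reported per literature-source-count stratum.

## Synthetic worlds

The generator reproduces the statistical structure the pipeline assumes,
with defaults chosen as the study conditions:

* 10% binding prevalence; given binding, 60% agonist and 25% antagonist
  activity (antagonists deliberately rare, as in real ensembles), and any
  active agonist/antagonist is a true binder. Active log10-AC50 is
  uniform over [−2, log10 800] µM so that every active occupies an active
  potency class; inactives carry the 1 M sentinel.
* Model ensembles draw sensitivity and specificity from [0.7, 0.9] and
  coverage from [0.8, 1]; AD flags mark 80% of covered chemicals. A
  chemical's detection probability is shifted on the logit scale by
  1.0 × (class score − 0.53): strong actives are easier to call than very
  weak ones, which is what produces the concordance-vs-potency trend in
  the consensus. The shift is centered on the mean active class score
  under the default potency distribution, so the marginal sensitivity
  matches the nominal parameter. Continuous models add N(0, 0.5) log10
  noise around the true AC50 of their active calls.
* Literature source counts are geometric with mean 3, truncated at 20;
  each source flips the true call with 10% false-positive and 10%
  false-negative rates and reports concentrations with N(0, 0.3) log10
  error in a random molar unit. 10% of records arrive as proliferation
  assays (% response with the concentration in the assay field) and 5%
  extra in-vivo decoy records are interleaved for the cleaning rules to
  drop.
* Training AUC scores map potency classes to base values
  (0, 0.15, 0.35, 0.6, 0.9) with small Gaussian noise clipped to [0, 1];
  5% of scores are relocated into the ambiguous [0.01, 0.1) band.
* All draws are bit-reproducible under (config, seed); each generator
  operation uses its own child stream of the master seed, so adding a
  generator never perturbs existing draws. Chemical identifiers are
  syntactically valid standard InChIs of an enumerable family of small
  substituted amino-chloro alkanes, so curation can be smoke-tested on
  them; curation chemistry proper is exercised on a separate hand-picked
  real-molecule fixture.

What the generator does **not** emulate: real descriptor-space structure
(model errors are independent given the truth, whereas real QSAR models
share training data and fail on correlated chemical classes), assay-
specific artifacts such as cytotoxicity burst, inter-species or
receptor-subtype differences, and citation duplication between literature
sources. Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline and the qualitative behavior of the consensus
(majority-vote gains, concordance-potency trend, evidence-count trend) —
not the quantitative accuracy that would be observed on real ensembles,
where inter-model correlation typically reduces the consensus advantage.

## Numerical conventions

* Reported tables round to 2 decimals, round-half-even.
* Class-score boundary comparisons use a 1e-9 tolerance so that exact
  fractions (e.g. a mean of 0.75) land on the intended side.
* Undefined metrics propagate as `None`/blank; empty report slices are
  marked undefined, not zero.
* All policy thresholds (weight cutoff, disagreement fraction, potency
  boundaries, AUC band, the three-model support rule, sweep grid) live in
  `RunConfig`; nothing numeric is hard-coded in the stages.

## Problem sizes used in tests and the acceptance script

Stochastic checks run at sizes where the tested signal is well resolved:
ensemble-vs-median comparisons use 100 replicates of 2,000 chemicals and
15 models (tests) and 25 such replicates (acceptance script); the
evidence-stratification trend uses 50 replicates of 800 chemicals;
parameter recovery uses 500–2,000 chemicals with 3-standard-error bands.
The full-pipeline demonstration runs 1,000 chemicals and 15 models per
endpoint.

## Known limitations

* Curation relies on RDKit sanitization; exotic valence states that RDKit
  rejects are dropped rather than repaired.
* The one-vs-rest multiclass BA treats the five potency classes as
  unordered; an ordinal metric would credit near-miss classes.
* Score₂-weighted voting assumes model errors are independent; correlated
  ensembles (models trained on the same data) will overstate concordance.
* The corrected consensus is intentionally liberal: under noisy synthetic
  ensembles the correction rules can substantially lower binding
  specificity in exchange for sensitivity, mirroring its prioritization
  purpose.
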