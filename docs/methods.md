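# Methods

## The comparison model

The unit of all comparisons is the **canonical pair**: an unordered pair
of normalised ingredient identifiers, ordered internally by
case-insensitive lexicographic collation with a byte-wise tie-break so
the representation is total, deterministic and locale-independent.
Pairs whose two raw names resolve to the same ingredient (salt variants
of one drug listed against each other) are dropped as self-pairs and
counted; the sources are silent on this case and silently keeping either
interpretation would corrupt the conservation accounting (every input
row must end up either in a surviving record's provenance or in exactly
one exclusion counter).

### Severity and evidence schemes

Each resource publishes its severity levels in descending order of
severity; rank 1 is therefore the most severe level, and "keep the
highest rating" on a merged duplicate means keeping the **minimum**
rank. The BNF's *Unknown* level is ranked 4 (least severe) because the
resource displays it last, even though semantically it flags an
unpredicted outcome. Critical subsets follow the resources' own
definitions: BNF {Severe}; Thesaurus {Contraindicated, Not recommended};
Micromedex {Contraindicated, Major}. They ship as defaults and are
overridable configuration, not code.

Evidence vocabularies are ordered strongest-first (BNF: Study >
Anecdotal > Theoretical; Micromedex: Established > Theoretical >
Probable) and duplicate rows merge by keeping the strongest level — the
sources do not state a rule, and keeping the strongest parallels the
severity rule. BNF-style records without an evidence rating form an
explicit `none` bucket in the evidence cross-tab rather than being
dropped, so the no-rating mass is visible in the comparison.

Unknown severity or evidence labels are hard errors: the schemes are
closed vocabularies and a typo silently dropped would bias every
downstream count. Rows lacking a severity value merge normally; when a
rated duplicate exists the rated value wins and the unrated row's
provenance is retained.

### Set statistics

`venn_partition` computes exact exclusive 7-region counts by set
algebra. Pairwise intersections are reported both inclusive of the
triple region (as the published counts are) and exclusive, clearly
labelled. Coverage rate is 100·|A∩B|/|A| and errors on empty A; the
Jaccard index errors only when both sets are empty. All internal
computation is full precision; percentages are rounded half-up to two
decimals only at presentation (`round2`), because banker's rounding
would disagree with several printed values.

### Critical overlap

A jointly-critical pair must be present in both resources *and* rated
critical by both. Coverages are taken against each resource's full
critical set size. Two published directional coverages of the
Thesaurus–Micromedex joint-critical set and one of the BNF–Micromedex
set are not reproducible from the severity-table critical sizes under
any denominator we could construct; the verify harness reports these
rows as flagged, with the full-critical-set candidate value alongside
the printed one, rather than adjusting either number. The same harness
flags two BNF severity shares whose printed counts sum to more than the
BNF pair total, and one Micromedex share that was evidently truncated
rather than rounded.

## Advice annotation

Pre-processing lowercases the text, replaces every drug-lexicon name by
the common token `DRUG` (longest match first, word-boundary anchored, so
multi-word names are blinded as a unit), splits sentences on
`.` `!` `?` boundaries, tokenises on non-alphanumeric boundaries with no
stop-word list, and stems with a self-contained Porter stemmer. The
tokeniser choice is recorded here because the upstream description
leaves punctuation handling open; hyphens and slashes become token
boundaries.

The tf-idf weight of word *w* in sentence *s* is
`tf(w,s) · ln(N/(df(w)+1))` with *tf* the relative within-sentence
frequency. The logarithm base is not stated upstream; we use the
natural log (any base rescales all weights by a constant and leaves a
linear-kernel SVM's decisions unchanged, so the choice is cosmetic).
Note `df+1` in the denominator makes ubiquitous words carry small
*negative* weights; the formula is implemented literally rather than
"fixed" to a conventional smoothed idf.

Per category, a linear-kernel soft-margin SVM (C = 1) with
inverse-class-frequency ("balanced") class weights is trained on the
labelled sentences. Decision scores — not calibrated probabilities —
feed the ROC analysis: scores are produced by leave-one-out
cross-validation (fold *i*'s score comes from a model trained without
sentence *i*; folds with a single-class remainder are skipped and
logged, and a category whose surviving scores contain no positive is
REJECTED outright). Candidate thresholds are the midpoints between
consecutive sorted unique scores plus ±∞ sentinels; among operating
points with PPV ≥ the configured floor (default 0.80) the
maximum-sensitivity point is selected, ties broken by higher PPV then
higher threshold. Categories with no qualifying point are REJECTED —
rejection is an expected outcome for rare categories, not a failure.
Hold-out validation reports PPV, sensitivity and F1 per category, with
undefined metrics reported as not-applicable rather than zero.

## The synthetic generator

The generator emulates the *structure* of compendia extracts, not their
pharmacology: ingredient names are synthetic tokens (`drug0001`…), and
no real drug nomenclature beyond salt suffixes is imitated. Defaults
are the study conditions:

| parameter | default | rationale |
|---|---|---|
| `venn_region_sizes` | (29, 19, 46, 8, 7, 5, 7) | the analysed compendia's exclusive regions ÷ 1000 |
| `n_ingredients` | 120 | smallest round pool comfortably holding the 121 default pairs |
| severity distributions | per-resource empirical level frequencies | matches the published severity tables |
| evidence distributions | per-resource empirical frequencies, incl. a 69 % no-rating bucket for the BNF-style resource | matches the published evidence shares |
| `salt_variant_rate` | 0.10 | a ~10 % duplicate/variant burden is typical of name-normalisation workloads |
| `class_row_rate` | 0.10 | the class-indexed resource lists a minority of rows at class level |
| `advice_noise_rate` | 0.10 | a minority of management texts carry no actionable advice |
| `multi_label_rate` | 0.20 | advice sentences frequently combine two recommendations |

One pseudo-random stream per artifact (pair universe, names, severity,
evidence, classes, advice) is derived by seeding a PCG64 generator with
(master seed, CRC32 of the stream label), so adding a stream never
perturbs the others and identical seeds give byte-identical outputs.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: real name-mapping ambiguity (the emitted
mapping table is complete and correct by construction), correlated
severity assignments between resources (severities are drawn
independently per resource, so cross-tab agreement on synthetic data is
at chance), non-template sentence variation, and French-language advice
text (small corpora are manually labelled upstream, so the automated
path never sees French).

Class-level rows share a single drawn rating across their member pairs,
which slightly flattens the per-resource severity distribution; the
distribution-recovery check therefore runs with class rows and salt
variants disabled.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to run
on one CPU in a few minutes: set statistics on the full published scale
(121 351 realised pairs over 600 ingredients — exact, sub-second), the
severity-distribution χ² check at ≥ 5 000 pairs per resource
(α = 0.01), LOO-equivalence at n ≤ 30, and classifier recovery at
n = 400 training / 200 hold-out sentences. The SVM's quadratic-program
solver converges to its default tolerance, so tests comparing decision
scores across equivalent-but-reordered training sets use a 1e-2
absolute band, while LOO-against-naive-retrain comparisons (identical
data, identical order) use 1e-9.

## Known limitations

* The published dataset-level counts cannot be recomputed from raw
  sources here (the sources are licensed/scraped); they enter as printed
  inputs, and only the *derived* statistics are recomputed.
* Severity cross-tabs require fully rated tables; a resource with
  unrated records is skipped as a cross-tab row resource with a logged
  warning rather than given an imputed rating.
* No agreement significance testing or kappa statistics: the analysis
  is deliberately descriptive.
* The advice classifiers are bag-of-roots linear models; they cannot
  capture negation ("do not discontinue") or scope, and on real text
  the hold-out metrics would sit well below the near-perfect synthetic
  values.
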