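# Methods

This note documents the models, procedures and design choices behind
`druglabel`: what each stage assumes, which knobs matter, what the
synthetic corpus does and does not emulate, and where the design was
genuinely open.

## Section vocabulary and identifiers

The pipeline targets twelve labeling sections: boxed warning, indication,
dosage and administration, pregnancy, lactation, mechanism of action,
pharmacodynamics, and the five pharmacokinetics subsections — absorption,
distribution, metabolism, excretion, food effect (ADMEF). The
pharmacokinetics parent is a thirteenth, internal kind: it is extracted
only so it can be split, because ADMEF subsections have no LOINC codes of
their own.

All cross-source joining happens on the six-digit FDA application number.
Sources write it inconsistently (`NDA021436`, `N021436`, bare `21436`), so
`normalize_app_number` strips an optional `NDA`/`ANDA`/`N`/`A` prefix,
left-pads to six digits and records the inferred application type. The rule
is deliberately isolated in one function: none of the sources documents its
own textual convention, and the canonical form is a reconstruction that can
be swapped without touching the parsers.

Whitespace normalization is uniform everywhere: CRLF→LF, horizontal runs
collapsed, lines trimmed, blank-line runs collapsed to a single blank line.
The blank line is the paragraph boundary — the paragraph is the minimum
unit of annotation and classification throughout, a deliberate limitation:
food-effect statements spanning paragraph boundaries, or buried as single
sentences inside otherwise unrelated paragraphs, are out of scope.

## Parsing the four sources

**SPL (DailyMed).** Sections are located by LOINC code (eight coded
sections, `34066-1` … `43682-4`); element matching uses local names only
because real SPL files vary in namespace declarations. Section text is
assembled from `<paragraph>` markup joined by blank lines. Application
numbers are read from `approval` elements' `id/@extension` anywhere in the
document — the exact carrier location is not standardized, so the parser is
deliberately permissive, and the synthetic generator and parser agree on
this convention. Documents without a Set ID are kept and flagged unmapped
rather than dropped.

**Pharmacokinetics splitting.** Subtitles among {absorption, distribution,
metabolism, excretion, food effect(s), effect(s) of food} are recognized in
two forms: a standalone title line, or a paragraph-leading prefix
terminated by `:` or `-`. Content runs until the next subtitle; content
before any subtitle stays under the pharmacokinetics key; subtitle text is
removed from content. Two small generalizations are applied uniformly: an
optional outline-number prefix (`12.3 Absorption`) is tolerated, and the
caller may supply extra synonyms (the free-text heading lexicon adds
`elimination` for excretion). When a pharmacokinetics container is present
the `pharmacokinetics` key is always emitted, with empty content if
everything sat under subtitles — so downstream code can distinguish "had a
PK section" from "had none".

**Free text (Drugs@FDA).** PDF conversion is out of scope; the input is
text. A heading is a *whole line*: optional outline number, a lexicon
phrase, optional trailing punctuation, nothing else — this blocks false
positives from sentences that merely mention a section name. ADMEF
headings are only honored inside an open pharmacokinetics or
clinical-pharmacology region, because words like "distribution" occur as
ordinary prose elsewhere. The heading lexicon ships as a JSON data file
(`data/heading_lexicon.json`) and is overridable at every call site; the
shipped phrases are reconstructions of standard FDA labeling headings.
Application number and date come from a sidecar manifest when given, else
from the `NDAnnnnnn_YYYYMMDD.txt` filename convention; manifest wins.

**DrugBank.** One XML datafile, streamed drug-by-drug (`iterparse`, memory
proportional to one `<drug>` element). Seven content tags map to section
kinds — including DrugBank's native spellings `volume-of-distribution` and
`route-of-elimination` — and `products/…/fda-application-number` is the
eighth extracted element. DrugBank has no boxed warning, dosage and
administration, pregnancy, lactation or food-effect fields; those kinds are
never emitted by this parser, which is why the coverage report shows 0 for
them.

**Orange Book.** The products file (tilde-delimited, `Appl_Type`/`Appl_No`
by default; both configurable) yields the set of distinct NDA application
numbers. ANDA rows are excluded, duplicates collapse, malformed rows are
skipped with a warning — the pipeline is best-effort integration, not
validation.

## Integration, coverage, overlap

Unification preserves one-to-many mappings: a document listing several
application numbers appears under each. Per (application number, source)
the latest version wins: maximum effective date, ties broken by version
number then native ID, so the choice is deterministic and order-invariant;
undated documents lose to any dated one. Restricting to the Orange Book
errors on an empty reference rather than silently emptying the table.

Coverage of source S for section k is `100 · |{items where S provides
k}| / |{items where any source provides k}|`; the "drug" row uses the
reference-set size as denominator. Overlap is formalized as
`100 · mean_{i covered by S} (n_i − 1)/(M_k − 1)`, with `n_i` the number of
sources providing k for item i and `M_k` the number of sources providing k
anywhere. This is the unique linear form matching both calibration
endpoints — a sole provider scores 0%, and a source whose items are always
also covered by every other provider scores 100%. The verbal definition of
overlap admits other readings (e.g. a fixed denominator of all sources
rather than providers of that section); the formula is isolated in one
function so an alternative can be swapped in. When `M_k = 1` no sharing is
possible and overlap is reported absent (NaN), as is coverage when nobody
provides a section.

## Food-effect dataset and classifiers

**Regex annotation.** Inside absorption-area content, a paragraph
immediately following a standalone food-effect title, or opening with a
food-effect prefix, is labeled Food Effect (method `regex_title` /
`regex_prefix`, marker removed from the stored text); everything already
extracted into a food-effect subsection counts as title-detected; remaining
absorption paragraphs default to Non-Food Effect. A manual-review hook
merges corrections (paragraph text → label, method `manual`) before
training; it is empty by default.

**Rules.** Rule 1: the phrase alternation matched anywhere. Rule 2: the
bare keyword `food`. Every rule-1 phrase contains "food", so rule-1
positives are a subset of rule-2 positives — asserted exhaustively in the
tests.

**TF-IDF.** `TF(t,d) = ln(1 + freq(t,d))`, `IDF(t,D) = ln(N/df(t))`,
natural log, no smoothing: a term in every training document weighs zero
(a smoothed sklearn-style variant exists behind a flag, off by default).
The formulas are implemented directly rather than via a library vectorizer
so that tests can check them against brute-force evaluation to 1e-12.
Tokenization is lowercase splitting on non-alphanumeric runs — unigrams, no
stop-word removal; this choice is for determinism and auditability, not
tuned performance. The TF formula's per-document frequency is the one
implemented; log base only rescales features and cannot change rankings
under the monotone-invariant classifiers used.

**Classifiers.** Logistic regression (max_iter 2000), LinearSVC, and a
200-tree random forest, all seeded, all from scikit-learn. Training errors
on single-class inputs and unknown algorithm names. Evaluation counts
TP/FP/FN with Food Effect as the positive class — the only convention under
which rule-based precision/recall are meaningful; degenerate denominators
yield 0 with an explicit flag so reports stay total.

**Protocol.** Datasets are source-balanced (equal records per source,
sampled without replacement), class proportions following the pools —
sources, not classes, are balanced. Splits are 80/20, stratified by source,
seeded. The cross-source grid trains and tests on
{drugs_at_fda, dailymed, combined}², where combined is the union of the
per-source partitions, so no test paragraph can appear in any training set;
a leakage guard errors otherwise. Learning curves subsample the training
set without replacement per (algorithm, size, repetition) with derived
seeds, evaluating on the fixed test set; repetitions both re-seed and
re-draw the subsample.

**Transformer hook.** `finetune_transformer` carries the fine-tuning
defaults (learning rate 4e-5, batch 32, gradient clipping at norm 1.0,
Adam) and requires the optional `bert` extra plus locally available
pretrained weights; the core pipeline neither imports nor needs it, and
fine-tuning reproducibility across runs is documented as not guaranteed.

## Synthetic corpus

The generator is template-based, not statistical: ground truth must be
exact. One seeded drug universe (names, application numbers, Set IDs,
DrugBank-IDs, source membership, version counts, reference membership) is
shared by all four format emitters, so cross-source joins are consistent.
Defaults: 20 drugs; each section present with probability 0.8 per document;
source membership 0.9/0.85/0.8 for DailyMed/Drugs@FDA/DrugBank; 15%
two-application drugs; 8% unmapped documents; 20% multi-version documents
(3 versions, 90-day spacing); 10% of drugs outside the reference set.
These rates are chosen so a default corpus exercises every parser branch
(one-to-many IDs, unmapped buckets, version filtering, reference
restriction) — a checklist test enforces this — while staying drug-like in
content. The first four drugs force the rare branches deterministically.

Food-effect paragraphs come from four template families: positives with
food vocabulary, positives phrased via "high-fat meal"/"breakfast" with no
occurrence of "food" (the false-negative archetype), plain absorption
negatives with no food vocabulary, and negatives that mention "effect of
food … has not been evaluated/studied" (the false-positive archetype). By
construction the adversarial flag equals "keyword rules err here", for both
rules — tests assert the equivalence exhaustively. Document-level fixtures
embed non-adversarial positives under explicit title/prefix markers and
adversarial positives unmarked, so structural annotation misses exactly the
unmarked ones.

What the synthetic corpus does **not** emulate: real clinical prose and
vocabulary breadth, OCR/layout noise beyond stray line breaks and repeated
page headers, tables and figures inside sections, inconsistent section
ordering, or the class imbalance and ambiguity of real annotation. Passing
tests therefore demonstrate that the machinery is correct and calibrated on
auditable inputs — parser round-trips, oracle agreement, rule failure
modes, classifier-vs-rule ordering — not that real-corpus scores would
match. Classifier F1 near 1.0 on synthetic data reflects the limited
template vocabulary; on real labels the same models are expected to be
substantially weaker, with the rule/classifier *ordering*, not the levels,
being the transferable observation.

## Numerical and degenerate-input conventions

- Undefined percentages (empty denominators, `M_k ≤ 1`) are NaN in
  reports, never silently 0; degenerate precision/recall/F1 are 0 with a
  flag.
- All randomness flows through explicit integer seeds; derived seeds are
  string-keyed (`"seed:algo:size:rep"`) so they are stable across
  processes. Two runs with identical configuration are byte-identical, and
  a test runs the full pipeline twice to assert it.
- Problem sizes in the shipped tests and acceptance script (60-drug
  corpora, 800-paragraph datasets, learning curves to 400) keep the whole
  suite in the tens of seconds while leaving every measured rate stable
  across seeds; they are the package's default study conditions, not
  tuned values.

## Known limitations

- Only absorption-section text is annotated and classified; food-effect
  content elsewhere (dosage instructions, clinical pharmacology prose) is
  out of scope.
- Live retrieval from the four services is not implemented; the file
  readers define the interfaces and everything is offline.
- The heading lexicon and the application-number carrier conventions are
  reconstructions; both are configuration, not code, precisely because
  real-corpus variation would demand tuning them.
- Layout-aware PDF parsing and OCR are out of scope; the free-text reader
  assumes the conventional blank-line paragraph structure of PDF-to-text
  output.
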