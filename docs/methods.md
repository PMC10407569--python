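# Methods

## Corpus model and input formats

A corpus is an ordered, pmid-unique list of documents; each document
carries title, abstract, publication date, a set of publication-type
strings, and optional pre-computed entity annotations. MEDLINE flat files
are parsed with Biopython's Medline reader (continuation lines joined with
single spaces); a matching writer exists so generated corpora round-trip
through the same reader as real exports. PubTator files contribute entity
annotations whose character spans index the concatenation
`title + " " + abstract` — the separator is a single space, and any
annotation whose surface string does not equal the text slice at its span
is dropped with a warning rather than silently shifted.

Publication-type filtering retains a document iff it has at least one type
on the inclusion list and none on the exclusion list, matched
case-insensitively as exact strings (PubMed publication types are a
controlled vocabulary, so substring matching would over-reach). The default
inclusion list deliberately contains both "Clinical Trial" and the
historical misspelling "Clinical Trail", because corpora assembled under
the misspelled filter circulate; accepting both is robust in either case.
Dates are reduced to the first four-digit year for all counting;
unparseable dates are counted under an explicit "unknown" bucket so totals
are conserved.

## miRNA recognition and normalization

Recognition uses a single nomenclature-aware regular expression with two
alternatives — the miR/miRNA/microRNA family (optional letters allow
"mi(c)r(o)(r)(n)(a)" prefix degenerations) and the historical let-N family
— each followed by the identifying number and optional letter,
genomic-copy (-1..-5) and arm (-3p/-5p) suffixes, in either case. The
pattern is intentionally permissive (it admits forms such as "mir1"); a
`strict=True` mode requiring a full "miR"/"miRNA"/"microRNA"/"micro-RNA"/
"let" prefix is available but off by default, because recall on informal
usage matters more than rejecting rare degenerate tokens. "lin-4", the
other historical exception, is outside the pattern and only matched under
an explicit `include_lin4` opt-in.

Matching is applied per token after hyphen-preserving tokenization (tokens
are maximal runs of alphanumerics and internal hyphens), with spans mapped
back to the source text. Tokenwise application means a species prefix
("hsa-") does not block recognition inside the same token, and greedy
matching within the token prevents partial matches inside "miR-146a-5p".

Normalization reduces any recognized surface to `prefix-number`: the
prefix collapses to "miR" or "let", the number is the first digit run, and
species prefixes, letter suffixes, genomic-copy suffixes and arm suffixes
are discarded. Letter variants (miR-146a vs miR-146b) therefore merge into
one core, matching how the downstream analyses aggregate families. Within
a document each core counts once, so mention repetition cannot inflate
frequency or feature values.

## Topic modeling

LDA is fitted by batch variational Bayes (scikit-learn) with a fixed
random seed, making theta and phi bitwise reproducible for a given corpus
and configuration. The vocabulary is built from lowercased,
hyphen-preserving tokens minus a standard English stopword list and
single-character tokens, with minimum document frequency 2. Default priors
are the fitter's 1/K defaults; K defaults to 13 — the number of themes
resolved at full corpus scale in the motivating analysis — but is a plain
parameter, and the fitted perplexity is reported for anyone sweeping K.
A document's *dominant topic* is the argmax of its topic mixture, ties
breaking to the lowest index; topic indices are reported 1-based. The
topic-by-year matrix counts documents by dominant topic and year; the
miRNA-by-topic matrix counts, for each core, the documents mentioning it
whose dominant topic is t. Topic modeling is intended to run on a single
thematically coherent corpus (e.g. the disease corpus alone): on a mixed
case/control corpus the class axis (case-enriched vocabulary such as the
disease name) competes with genuine themes for topics.

## Classification

Features are binary presence of each normalized core over a vocabulary
defaulting to the union of observed cores; labels are 1 for the case
corpus, 0 for control. Class imbalance is handled by down-sampling the
larger corpus uniformly without replacement to the size of the smaller.
Validation is a single stratified holdout split with test fraction 0.3 (a
common convention; the fraction is configurable). Four families are
supported: Bernoulli naive Bayes (the natural likelihood for binary
features), decision tree, random forest, and SVC with C=10,
gamma="scale", kernel="sigmoid" as defaults. All seeds are explicit.
Metrics computed from the confusion matrix report NaN, never 0, when a
denominator vanishes. Scores for ROC/AUC are decision-function values for
the SVM and positive-class probabilities otherwise.

Because a sigmoid-kernel SVM exposes no native coefficients, feature
relevance is measured by permutation importance: the mean drop in held-out
accuracy over n_repeats=20 independent shuffles of one column, seeded and
reported sorted descending. This is model-agnostic and directly
interpretable as "accuracy the model loses without this feature".

### A note on the sigmoid kernel on small binary matrices

On the synthetic benchmark below, the Bayes-optimal rule reaches ~0.92
held-out accuracy and Bernoulli naive Bayes attains it, while the
sigmoid-kernel SVM at its default calibration plateaus near 0.88: with few
dense binary features gamma="scale" is large and tanh saturates, and with
many sparse features C=10 leaves enough capacity to memorize
noise-feature patterns (stronger regularization, e.g. C=0.1, closes the
gap). The defaults are nevertheless kept, because they are the method's
stated calibration; users benchmarking on small binary matrices should be
aware of this behaviour.

## Gene co-mention and enrichment

For a chosen core, documents mentioning it contribute their gene-type
annotation surfaces (uppercased; surfaces that are themselves miRNA names
are excluded) to a binary gene-by-study matrix, with rows kept for genes
in at least `min_docs=2` studies. Intersection with a TargetScan-style
target list flags co-mentioned genes that are predicted targets; matching
is case-insensitive and tolerant of arm/species decorations in the family
column. Over-representation uses the exact upper-tail hypergeometric
probability with Benjamini–Hochberg adjustment across the collection; the
universe defaults to the union of the GMT collection's genes, and the
query is intersected with the universe before testing. Enrichment here is
a desk-scale, fully local computation: no identifier mapping service or
web API is involved, so results depend on the supplied GMT and target
files.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:
two document classes; abstracts drawn as bags of words, each word coming
from the document's planted topic pool with probability 0.7 and otherwise
from shared filler vocabulary; the disease term planted in case abstracts
(rate 0.3 of filler draws) so case/control vocabularies differ the way
they do in real corpora; and per-document Bernoulli miRNA mentions. The
default study conditions are 1,000 documents per class, three disjoint
topic pools, five signal miRNAs at 0.6 (case) vs 0.1 (control), and a
literature-scale background vocabulary of 94 class-neutral miRNAs with
long-tailed rates (0.15/√rank, roughly 2–3 incidental mentions per
abstract) — real corpora mention many distinct miRNAs, most rarely, and
the breadth matters: it makes "the five signal miRNAs rank in the top ten
importances" a meaningful check rather than a near-tautology. Synthetic
core numbers are drawn from 900–999 so they cannot collide with real
names in mixed tests.

Every planted mention is rendered through a weighted choice of surface
families (plain, miRNA-/microRNA- prefixes, hyphen dropped, species
prefix, letter suffix, arm suffix, case variants), all recoverable by the
recognition pattern; an adversarial mode adds "lin-4" for negative
testing. Ground truth records each document's label, planted topic, and
every mention with its span, so tagger recall and precision are computed
exactly, not estimated. What the generator does **not** emulate:
linguistic structure (word order, syntax), correlated miRNA co-mention
patterns, citation metadata, and annotation noise — passing tests
demonstrate correct recovery of planted statistical structure, not
robustness to the full messiness of real abstracts.

## Numerical and design choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` and estimator `random_state`); regenerated
  corpora are byte-identical, splits, metric tables and importance
  rankings identical.
- Ranking ties break lexicographically (top terms, top miRNAs) or to the
  lowest index (dominant topics) so outputs are deterministic.
- Probability rows of theta/phi are renormalized after fitting and
  asserted to sum to 1 within 1e-8.
- Problem sizes in the test suite and acceptance script — 500 documents
  for topic recovery, 1,000 per class for classification, 100,000 draws
  for the resampling oracle — were chosen as the smallest sizes at which
  the planted effects concentrate well away from their thresholds.
- Metrics are reported to 4 decimals in formatted output; raw values are
  kept at full precision.

## Known limitations

- The permissive default regex can fire on degenerate tokens ("mir1");
  use strict mode when precision outweighs recall.
- Letter variants merge (miR-146a = miR-146b = miR-146); analyses needing
  arm- or variant-level resolution require a different normalization.
- Publication-type matching trusts the input's controlled vocabulary;
  free-text type fields will not match the default lists.
- LDA topic indices are arbitrary across configurations; only
  permutation-invariant summaries are comparable between fits.
- The sigmoid-kernel SVM calibration issue described above.
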