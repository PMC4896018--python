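# Methods

## Problem and model

Each radiology report receives four independent binary labels (inner,
middle, outer ear, mastoid; abnormal = positive). We treat the multi-label
problem as binary relevance: four separate classifiers over a shared
preprocessing and featurization stack, no joint modeling of label
correlations. The features are raw n-gram presence/counts; no TF-IDF,
frequency floors, hashing or embeddings. This is deliberate: the decisive
signal in this genre is the co-occurrence of an anatomy term with either a
pathology term or a nearby negation token, which low-order n-grams capture
once the negation words are retained through stopword removal.

## Preprocessing

* **Section extraction.** A section header is a line beginning with an
  all-caps token (possibly several all-caps words) followed by a colon;
  bare all-caps `FINDINGS`/`IMPRESSION` lines also count, and a combined
  "FINDINGS AND IMPRESSION" header is treated as FINDINGS. A section is all
  lines from its header to the next header. If a report has neither
  section, the whole text is normalized instead — reports should degrade to
  whole-text classification, not silently become empty documents (ablation
  evidence from comparable corpora shows whole-report input changes
  accuracy only marginally).
* **Normalization order**: lowercase → tokenize (decimals like `3.14` kept
  whole) → number masking → unit masking → stopword removal → Porter
  stemming. Lowercasing first keeps n-gram matching stable; masking both
  decimals and integers (configurable) makes features robust to measurement
  values. The stopword list is a standard ~140-word English list shipped as
  `data/stopwords.txt`; "no", "not" and "under" are always retained. The
  unit list (`data/units.txt`) covers length, volume, frequency, loudness
  and time units and is user-extensible.
* **Stemming.** The Porter stemmer is implemented in-package as a faithful
  port of the reference implementation (canonical end-to-end vectors are
  frozen in the tests). Note that Porter stems are not all fixed points
  ("erosion" → "eros" → "ero" on a second pass), so normalization is
  idempotent in its masking/stopword layers but not literally on stems; the
  pipeline always normalizes raw text exactly once.

## Features

The vocabulary is fitted on training documents only and ordered
lexicographically for reproducibility. Character n-grams are taken over the
space-joined token string and may span the joining spaces, preserving
cross-word character context (the usual vectorizer semantics). Binary and
count modes share the same vocabulary; a binary vector is exactly the
indicator of the count vector.

## Model search

Six families, all via scikit-learn: logistic regression (liblinear),
LinearSVC, SVC with RBF kernel, decision tree, random forest, Bernoulli
naive Bayes (binary features only — an assumption of the event model).
The cost parameters C (SVM) and l (logistic regression) are both inverse
regularization strengths: larger = weaker penalty. This convention is
configurable in the sense that any grid of values may be supplied.

Two grid presets ship with the package:

* `paper_grid`: C, l ∈ {0.01, 0.0333, 0.1, 0.333, 1, 3.33, 10}; tree depth
  1–10; forest sizes {10, 50, 100}; RBF width = scikit-learn's "scale"
  heuristic × {0.1, 1, 10}; each crossed with the full feature lattice
  (word/character × n ∈ {1–1, 1–2, 1–3} × binary/count). ≈ 366 candidates
  per region — intended for offline runs.
* `compact_grid` (default for the CLI, the test suite and the acceptance
  script): the same families with 1–2 hyperparameter values each over three
  representative feature shapes (word 1–1, word 1–2, character 1–3),
  27 candidates per region. It retains the hyperparameter values that win
  per region in the full grid. The routine problem size — 726 reports,
  5-fold CV, four regions — completes in about half a minute on one CPU
  with this preset.

Cross-validation is stratified, shuffled once with a recorded seed. The
feature space is refitted inside each fold on the fitting portion only;
grid search shares the per-fold fitted spaces between candidates with the
same n-gram shape (a pure optimization — results are identical to running
each candidate independently, which a test asserts). Ties in mean CV
accuracy keep the earlier candidate in the fixed enumeration order. Across
families the per-region winner is chosen by held-out test accuracy with F1
as tie-break, then fixed algorithm order.

Continuous scores for ROC: class-1 probability where available (logistic
regression, trees, forests, naive Bayes) and the signed margin for SVMs.

## Evaluation conventions

* Reported rounding: accuracy as an integer percent, other metrics to two
  decimals.
* 0/0 ratios (e.g. PPV with no positive calls) are NaN with an explicit
  `undefined` flag; F1 is defined as 0 when tp = 0 so degenerate folds
  remain comparable.
* Majority-class margin is computed from the *rounded* integer accuracy
  percent, matching how such margins are conventionally reported alongside
  rounded accuracies.
* McNemar's test doubles the smaller exact binomial(b+c, ½) tail and clips
  at 1 (p = 1 when b = c, including b = c = 0, which is flagged).
* Learning-curve subsampling is stratified and nested (the size-s subsample
  is a prefix of the size-s′ one for s < s′), giving smooth curves.

## Synthetic corpus

The generator emulates the structural features of pediatric temporal-bone
CT reports that the pipeline exploits; it does not attempt clinically
realistic prose. Each report has EXAM/HISTORY/FINDINGS/IMPRESSION sections.
Region labels are sampled independently with default prevalences 26.72 %
(inner), 37.59 % (middle), 13.79 % (outer), 30.86 % (mastoid) — the rates
of the 580-report training corpus the tool family was developed on.
Abnormal regions emit 1–2 abnormality sentences from ~10 templates per
region over the standard anatomy vocabulary (enlarged vestibular aqueduct,
ossicular erosion, canal atresia, mastoid opacification, …); normal regions
emit a negated mention with probability `negation_rate` (default 0.5), else
a benign mention half the remaining time, else nothing. Measurement phrases
("measuring 4.2 mm") are inserted at `measurement_rate` (default 0.3);
single-character typos at `vocabulary_noise` (default 0.02) mimic OCR/typing
errors; labels are flipped at `label_noise` after the text is written,
mimicking annotation error. ICD9 codes are attached per abnormal region
with probability 0.7 (plus low-rate spurious codes), so the ICD9 baseline
is informative but imperfect, as in real registries. The paper-scale preset
is 726 reports with the prevalences above, negation 0.5 and 2 % label
noise.

What passing tests on this corpus do and do not show: they demonstrate that
the pipeline recovers planted, learnable structure (region-specific
vocabulary behind heavy negation) at realistic prevalence and scale, that
negation defeats keyword search but not the learned models, and that every
stage is deterministic under seeding. They do not certify performance on
real clinical text, whose section dialects, vocabulary breadth and label
correlations are richer than the template grammar; real deployments need a
labeled local corpus.

## Numerical and design choices

* Train fraction uses ⌊f·N⌋ (726 × 0.8 → 580/146); stratification is on
  the any-abnormal flag only, with per-stratum train shares within one
  report of exact proportionality. Per-region proportions are then only
  approximately preserved, which is the accepted behavior for this design.
* Cohen's kappa is computed from the two marginal rates; kappa := 1 when
  both raters are constant and identical (p_o = p_e = 1).
* ICD9 codes are canonicalized to a trailing-zero-free dotted form
  ("389.10" → "389.1") before exact matching.
* Keyword matching runs on raw, un-normalized text with word-boundary
  semantics — the baseline is meant to be what a researcher would actually
  try, and normalizing for it would blur the comparison.
* The shipped keyword and ICD9 lists are representative, built from the
  region labeling criteria and the standard 380–389 ear-disease code range;
  both are user-replaceable CSV files.
* Bundles persist the feature space as versioned JSON and the fitted
  estimator via joblib; a loaded bundle reproduces predictions exactly.

## Known limitations

Four independent binary classifiers ignore inter-region label correlation;
no negation-scope detection, concept normalization or sequence models (the
n-gram + retained-negation-words approach is the point, and suffices here);
no probability calibration; the HTTP service is a plain stateless endpoint
without authentication or batching infrastructure; English-only
preprocessing.
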