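# Methods

This note records the models, rules and numerical choices behind
`screenlite`, and what the synthetic-corpus experiments do and do not show.

## Screening model

Each citation's title and abstract are lowercased, split on
non-alphanumerics, stripped of pure numbers, single characters and English
stopwords (scikit-learn's built-in list), and Porter-stemmed (the classic
1980 algorithm, implemented in `_porter.py` and frozen against the
published reference behavior). Features are:

* unigram counts of the surviving stems;
* bigram counts of *adjacent* surviving stems, with title and abstract
  tokenized separately so no bigram spans the boundary (pairing happens
  after stopword removal; pairing before removal is the other defensible
  reading, but post-filter pairing keeps the bigram vocabulary denser);
* binary indicators for MeSH terms, matched by case-insensitive
  whole-phrase dictionary lookup against a user-supplied vocabulary file
  (no ontology expansion).

A corpus `FeatureSpace` keeps keys with document frequency ≥ `min_df`
(default 2, to bound vocabulary growth) in lexicographic order. The default
weighting is TF-IDF with smoothed idf, `ln((1+N)/(1+df)) + 1`, and L2 row
normalization; `tf` and `binary` weightings are available and are left
unnormalized so that counts remain interpretable.

The classifier is a linear SVM (scikit-learn `LinearSVC`, C = 1, balanced
class weights, fixed `random_state`). Balanced weighting matters because
screening corpora are heavily skewed (an included fraction of a few percent
is typical). Scores are signed distances to the decision boundary; no
probability calibration is applied before the star mapping, since only the
ranking and its quintiles are consumed.

### Star ratings

Stars discretize the score distribution of the *currently unlabeled*
citations by quintile: midrank-based quantile `(rank − ½)/n` mapped through
`1 + floor(5q)`. Ties share their midrank's star, so an all-tied score set
lands at three stars. The mapping is monotone in the raw score by
construction.

### Retraining and stopping

Suggestions are withheld until at least five included *and* five excluded
citations are labeled; below that the labeled set carries too little signal
to be worth surfacing. A retrain additionally requires
`max(10, 5% of labeled)` citations labeled since the last training set was
taken, and stops permanently once the internal quality estimate — a
two-fold stratified cross-validated AUC on the labeled set — has improved
by less than 0.005 for three consecutive retrains. The 0.005/3 plateau rule
is this package's operationalization of "retrain while the model can still
improve"; the thresholds are module constants.

`active_loop` simulates prospective screening: an initial random batch,
then repeatedly (retrain if the policy fires, re-score, read the top-ranked
batch, ties broken stably by citation id). It runs to corpus exhaustion so
recall trajectories are complete; all randomness flows from one seed.

## Evaluation

* **AUC** is computed via `sklearn.metrics.roc_auc_score` and equals the
  Mann–Whitney pair statistic with ties counted ½; the test suite checks it
  against an independent brute-force O(P·Q) pairwise oracle to 1e-12.
* **WSS@95**: citations are ranked by descending score; the smallest prefix
  whose recall reaches the target (0.95) is "read"; everything beyond it is
  predicted excluded; then `WSS = (TN+FN)/N − (1−Recall)` is applied with
  the *achieved* recall of that prefix. On discrete data the achieved
  recall generally overshoots the nominal target, and using it keeps the
  perfect-ranking closed form `(N−prefix)/N − (1−achieved)` exact. A
  consequence worth knowing: a fully reversed ranking scores exactly 0
  (the whole list is read, recall 1), not −0.05.
* **Protocol**: stratified twofold cross-validation (50/50 split), repeated
  ten times with fresh splits, both fold directions evaluated — 20 runs,
  summarized as mean ± sd. A `directions=1` switch gives the 10-run
  accounting for anyone who reads "repeated ten times" as ten evaluations.
  Stratification requires ≥ 2 members per class per fold.

## Similarity graph

Text similarity is `1 − Levenshtein/max(len)` on lowercased,
whitespace-collapsed strings (edit distance via `edlib`, with a pure-Python
DP fallback and oracle). Normalizing by length makes thresholds scale-free.
Abstracts are compared on their first 1500 characters to bound the
quadratic cost; the limit is a parameter. Author similarity is the Jaccard
index over surname + first-initial keys, which survives the `Smith, J` /
`J Smith` format split between databases. The overall similarity is the
weighted combination 0.4·title + 0.4·abstract + 0.2·authors (configurable,
must sum to 1); thresholds are conjunctive by default (every per-field
threshold *and* the overall threshold must pass), with a disjunctive flag.
Edge sets are antitone in every threshold, so threshold sweeps only ever
remove edges. Clusters are connected components, singletons included.

## Decisions and PRISMA counts

One current decision per (citation, reviewer); re-tagging replaces it and
clears its reasons. Timestamps are logical counters for reproducibility.
"Undecided" never conflicts; a conflict is an included-vs-excluded split.
Review-level PRISMA counts use a consensus rule — a citation counts as
included/excluded only when all deciding reviewers agree, otherwise
undecided — chosen over a union rule because it is conservative: it never
reports a contested citation as resolved. Per-reviewer counts treat
untouched citations as that reviewer's undecided pile. Conservation
(`included + excluded + undecided = total`) holds by construction and is
property-tested on random decision logs.

## Synthetic corpora

The generator emulates the statistical shape of screening corpora: a small
included fraction (exact count `round(n·prevalence)`, so tests are
deterministic), background tokens drawn i.i.d. from a Zipf(1.1)-weighted
pseudo-word vocabulary (heavy-tailed document frequencies, which is what
TF-IDF and `min_df` react to), and included citations drawing each token
from a disjoint trial-design signal vocabulary with probability
`signal_strength`. Defaults: 1000 citations, prevalence 0.1 (inside the
0.5–21.7% band spanned by published screening collections), signal 0.8,
2000 background / 30 signal types, Poisson title/abstract lengths with
means 10 and 120 tokens.

What this does *not* emulate: real abstracts' syntax and topical drift,
vocabulary overlap between included and excluded studies (signal words
never appear in excluded citations unless overlap is configured), MeSH
hierarchies, multilingual records, or annotator noise. Consequently,
near-perfect AUC on strong-signal synthetic corpora demonstrates that the
pipeline is wired correctly — featurization preserves the class signal and
the ranking front-loads it — not that comparable performance transfers to
real reviews, where published screening benchmarks sit well below 1.0.
`signal_strength = 0` yields a true null corpus (identical class
distributions) used to verify the evaluation stack is unbiased: CV AUC
centers at 0.5 and random-score WSS@95 at ≈ 0.

`inject_near_duplicates` appends copies with a fraction `edit_rate` of
characters substituted — ground truth for the similarity graph
(`edit_rate = 0` gives similarity exactly 1).

## Problem sizes in tests and the acceptance script

The bundled experiments use corpora of 100–600 citations, 5 seeds for the
cross-validation summary, 200 seeds for the WSS null, and 1000 threshold
pairs on a 50-citation corpus for graph monotonicity. These sizes put every
quantity's Monte-Carlo error well inside the asserted bands while keeping
the whole suite fast on one CPU. The WSS null experiment uses 100 positives
of 500: the discrete-prefix overshoot of the achieved recall biases the
null mean by roughly `0.95/P`, so with P = 100 the bias (≈ 0.01) is
comfortably inside the ±0.02 band — at P = 20 it would not be.

## Known limitations

* RIS/EndNote parsing covers the common tag set (TI/T1, AB/N2, AU/A1,
  PY/Y1, JO/JF/JA/T2, KW; %T/%A/%D/%X/%J/%K); exotic dialect tags are
  ignored rather than mapped.
* Language detection is a stopword-profile heuristic over en/es/fr/de and
  returns `unknown` below 20 tokens; it is a metadata convenience, not a
  classifier feature.
* Exact-duplicate detection keys on normalized title + year + first-author
  surname; fuzzy merging is the similarity graph's job, and interactive
  merge resolution is out of scope.
* The SVM is retrained from scratch each cycle (no incremental updates);
  at screening-corpus scale a full `LinearSVC` fit is sub-second.
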