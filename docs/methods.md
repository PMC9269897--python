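# Methods

## The pipeline

The package analyzes mini-snowball word-association data: each participant
produces `n_level1 = 5` associates to a focal cue and `n_level2 = 5`
associates to each of those, 30 records in total. The analysis proceeds in
stages, each exposed as a library function:

1. **Normalization and filtering.** Responses are trimmed, case-folded, and
   whitespace-collapsed. Nonwords and refusals are removed via a
   user-supplied exclusion list (manual curation is out of scope; a
   restricted Damerau-Levenshtein utility quantifies the string distance of
   supplied correction pairs). The eligible level-1 vocabulary is the set of
   level-1 responses with **token count ≥ 3 at level 1** (level-1 counts
   only, not pooled with level-2; token counting, not distinct
   participants). Level-2 records are kept regardless of their own
   frequency — they form the profile dimensions.
2. **Similarity network.** Word profiles are rows of the level-1 × level-2
   count matrix; relatedness is weighted Jaccard `Σ min / Σ max` (defined as
   0 for two all-zero profiles, which cannot occur after filtering). Every
   strictly positive similarity becomes an edge (`min_weight = 0`): the
   analysis is about community structure in a dense weighted graph, not
   about sparsification.
3. **Community detection.** Two-phase Louvain maximizing Newman-Girvan
   weighted modularity at resolution 1, best of 10 seeded restarts by Q.
   Ties in modularity gain break toward the lowest community index, making
   runs reproducible given the seed. Two robustness measures beyond the
   textbook algorithm: odd-numbered restarts start local moving from a
   random partition rather than singletons, and after aggregation a final
   single-node refinement pass runs on the original graph. Both address a
   known failure mode of greedy local moving on small dense weighted
   graphs, where every singleton start converges to the same local optimum.
4. **Centrality.** Weighted PageRank at damping 0.85 (the conventional
   value), L1 convergence tolerance 1e-10.

## Cluster stability

Bootstrap replicates resample level-2 response tokens within each cue row
(row-wise multinomial with the original row total), rebuild the similarity
network and re-run Louvain with a replicate-specific seed. The resampling
unit is the response token, preserving each word's level-2 sample size. For
word `w` and original component `k`, the raw co-membership score is the
mean over replicates of `|k-members (excluding w) in w's cluster| / |k \ {w}|`
— the division by component size prevents large components from dominating
modal assignments mechanically. Per-word scores are renormalized to sum to
one; the modal component is the argmax, with ties resolved toward the
word's original component and then the lowest index. A component's
stability is the fraction of its members whose modal component is the
original one. Default `B = 1000`; replicate-level Louvain uses 2 restarts
(replicates only feed co-membership counts, not a reported partition).

## Sentiment and similarity to the focal concept

A sentiment lexicon maps words to scores in [−1, 1]. A network word's
inferred score is the average of its own score and the count-weighted mean
score of its level-2 associates covered by the lexicon; if only one of the
two is available, that one is used; weights are association frequencies
because associates are observed as tokens. Component sentiment is the mean
over member words with a percentile bootstrap CI (default B = 1000,
95% level) over words.

The focal concept enters the similarity space through its level-1 response
frequency vector projected onto the level-2 column vocabulary;
out-of-vocabulary responses are dropped from the projection. A word's risk
similarity is the weighted Jaccard between its profile row and this vector.

Cross-language comparison takes a second similarity matrix (e.g. built from
association norms in another language via a translation table), restricts
both to shared terms, and reports the Pearson correlation over shared
upper-triangle pairs plus within/between-component block means under the
reference partition.

## Group differences

- **Age:** per-word Poisson log-linear model of level-1 counts per age bin
  (index 1..6) with offset `log(total level-1 tokens in bin)`; the slope is
  the change in log relative retrieval frequency per bin, tested by Wald.
  An OLS-on-log-relative-frequency variant is available behind
  `model="ols"` since the exact form of a "log linear model" is
  underdetermined. Words must be retrieved at least once in every bin.
- **Gender:** difference of log relative retrieval frequencies
  (female − male) with +0.5 smoothing on the word counts for display; the
  test is the 2×2 chi-square of word vs all-other tokens by gender on raw
  counts, without continuity correction.
- No multiple-testing correction is applied to the per-word flags at
  α = 0.05; Benjamini-Hochberg adjusted columns are emitted alongside,
  clearly labeled, for transparency.

Both tests treat level-1 tokens as independent. The task forbids repeating
a response within a cue page, so one participant contributes at most one
token of a given word, and the five tokens a participant contributes are
mildly negatively dependent; in calibration runs both tests are therefore
slightly conservative (type-I error ≈ 0.035–0.045 at α = 0.05).

## Prediction of self-reported risk taking

Each participant's feature for component `k` is the mean over their
in-network level-1 responses `r` of the mean similarity `J(r, w)` over
member words `w` of `k` (a retrieval-proportion variant is available behind
`variant="proportion"`). Out-of-network responses are dropped, not
zero-imputed; exclusion counts are logged. Standardized OLS (z-scored
predictors and outcome; age-bin index, female indicator, K features)
quantifies per-item effects. Predictive value is assessed by repeated
k-fold cross-validation (default 10×10) of elastic nets with mixing 0.5 and
penalty strength chosen by inner 5-fold CV on each training fold; R² is
computed on held-out folds. Model variants (components only, demographics
only, combined) share fold assignments, and per-fold differences feed the
corrected resampled t-test
`t = mean(d) / sqrt(var(d)·(1/J + n_test/n_train))` with J−1 degrees of
freedom, which inflates the variance for the overlap of training sets
across folds.

Word-level analysis correlates the binary retrieved-at-level-1 indicator
with each item for words retrieved by at least 10 participants, ordering
rows by mean correlation and flagging |r| > 0.05.

## The synthetic generator

`snowsem.simulate` emulates the study design: 1205 participants
quota-balanced over six age bins × two genders (cells differ by at most
one), 5 + 5×5 responses each. Words live in K = 5 planted components of 40
word types; within-component retrieval follows a Zipf rank distribution
(exponent 1.0) so that the frequency heterogeneity driving the ≥3 filter is
realistic. A participant's propensity over components is
`softmax(base + age_effect·age_bin + gender_effect·1[female] + ε)` with
`ε ~ N(0, propensity_sd²)` per component. The individual heterogeneity term
(default `propensity_sd = 1.0`) is essential: without it propensities are a
deterministic function of demographics and component features could never
predict outcomes over and above age and gender. Level-2 responses come
from the eliciting word's home component with probability `1 − leakage`
(default 0.1), else a uniformly random other component; repeats within a
cue page are rejection-resampled. Word sentiment is Gaussian around the
component mean (sd 0.15, clipped to [−1, 1]). Survey ratings are
`round(clip(intercept_item + Σ_k loading_k·propensity_k + N(0, 1.5), 0, 10))`,
seven items with item-specific intercepts and shared loadings (default
(+4, −4, +2, −2, 0)). Loadings and heterogeneity were fixed by a
design-stage power analysis so that all nonzero loadings are reliably
detectable in sign at the design sample size of 1200.

What the generator does **not** emulate: natural-language token statistics,
spelling errors, polysemy (every word has exactly one home component),
response-position effects, and item-specific loading profiles. Tests
passing on synthetic data therefore establish the correctness and
calibration of the machinery, not substantive claims about real
association data.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng`; generator stages
  draw from independent named substreams of the config seed, so outputs are
  byte-identical across runs with the same config.
- Louvain restarts keep the earliest best-Q partition on exact ties;
  community labels are canonicalized by first appearance over alphabetically
  sorted nodes.
- The validation harness that checks Louvain against exhaustive
  maximum-modularity search on 4–8-node graphs uses 50 restarts: the check
  targets global optimality, so it gets a larger search budget than the
  production default.
- Degenerate inputs: empty graphs, edgeless thresholds, empty eligible
  vocabularies, all-zero profile pairs, components without scored words, CV
  folds with zero outcome variance, and zero-variance t-test differences
  are all either defined explicitly (see docstrings) or rejected with a
  specific error.
- Validation problem sizes (e.g. 20 seeds × 1000 participants for
  partition recovery, 30 null datasets for calibration, B = 50 for the
  zero-leakage stability check) were chosen to keep Monte-Carlo error small
  relative to the property margins while remaining desk-scale; the
  zero-leakage stability result is independent of B because disjoint
  supports cannot mix under resampling.

## Known limitations

- The ≥3 frequency threshold is token-based; if a protocol allows the same
  participant to repeat a word across cue pages, token and participant
  counting can differ.
- The chi-square calibration statement applies to words with ≥ 20 tokens;
  rarer words inherit the usual small-sample caveats of 2×2 chi-square.
- Cross-language comparison requires a user-supplied translation table and
  inherits its coverage; untranslatable or duplicated terms are dropped.
- Modularity-based clustering has no single "correct" resolution; the
  package fixes resolution 1 and reports Q rather than searching over
  resolutions.
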