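# Methods

This note records the modelling choices behind `spherodict`: what each
component assumes, which parameters matter and why their defaults are what
they are, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Tokenization and vocabulary

Notes are lowercased and split on any non-letter character; Unicode letters
(German umlauts, ß) are preserved, so `Übelkeit` survives intact while
punctuation and standalone digits vanish. There is no stemming,
lemmatization or compound splitting: the goal is an auditable, reproducible
mapping from note to token set, and any normalisation beyond case folding
would make dictionary matches harder to trace. The cost is recall on
compounding languages — `thoraxschmerz` does not match the keyword
`thorax`. A prefix-match mode was considered and rejected for the default
because it silently widens every dictionary; users working with German
compounds should add the compounds themselves as keywords (the suggestion
step surfaces them naturally, since compounds embed near their heads).

The vocabulary applies a frequency floor of 10 by default: rarer words make
unstable embedding neighbours and unreliable keywords. The floor applies
both when suggesting candidates and when enhancing dictionaries.

## CBOW embedding

The embedding trainer implements the continuous bag-of-words objective with
negative sampling (5 noise words per positive, unigram^0.75 noise
distribution), in plain numpy, single-threaded and fully seeded: a fixed
corpus and seed reproduce vectors byte for byte. Defaults are dimension
300 and 100 epochs — short notes give each token little context, so many
passes are needed for stable geometry — with a symmetric context window of
5 (the corpus' sentences rarely exceed 10 tokens, so the window usually
spans the whole note), initial learning rate 0.05 decayed linearly.

Frequent-word subsampling (threshold 1e-3, the standard word2vec setting)
is on by default, and matters more here than in large corpora: without it,
two words that *always* co-occur can end up anti-aligned in input space,
because a word never co-occurs with itself and the training objective
treats that as strong negative evidence at high frequency. With
subsampling, words sharing sentences and contexts embed close together,
which is the property dictionary suggestion relies on.

Similarity is always cosine; **distance is defined as 1 − cosine
similarity** (range [0, 2]) and used consistently by the enhancement
geometry. Neighbour queries rank against the centroid of the query words
(a seed list acts as one query), exclude the query words, and break ties
deterministically by (similarity desc, corpus frequency desc, word asc).

## Spherical dictionary enhancement

Given a topic's embedded single-word keywords K, the radius is the largest
pairwise cosine distance d_max; the candidate pool is the union of each
keyword's 50 nearest neighbours (subject to the frequency floor), minus
words already in the topic; a candidate joins iff its distance to *every*
keyword is at most d_max — the intersection of the closed balls.

Choices worth recording:

* **Closed boundary (≤ d_max).** A word exactly as far as the widest
  keyword pair is retained; an open boundary would let floating-point noise
  exclude seed-equivalent words.
* **Geometry uses all current single-word keywords** (seed + manual), since
  enhancement runs after manual curation; a `seeds_only` switch restricts
  it to seeds.
* **Combination rules are excluded from the geometry.** Their semantics are
  conjunctive ("pain AND chest"), not lexical proximity; letting their
  constituent words widen d_max would conflate the two.
* **Topics with fewer than two embedded keywords are skipped** with an
  explicit report — one point defines no radius, and guessing one would be
  arbitrary. (Single-seed topics are legitimate; they simply cannot be
  enhanced.)
* **Per-topic candidate exclusion only**: a word may be added to several
  topics, consistent with multi-label tagging downstream.
* **n_closest defaults to 50**, matching the suggestion step's breadth.
  Enhancement is monotone in n_closest, and with n_closest = |vocabulary|
  it equals an exhaustive scan — the equivalence the validation study
  checks.

Enhancement can overreach: a topic whose keywords are already spread out
(large d_max) admits many candidates, including background words. The
share-table report (initial vs enhanced counts, percent increase) is the
intended audit surface for this; the worked example in the README shows a
topic where a wide radius triples the tagged count.

## Tagging and clusters

Rule matching is exact at the token level and case-insensitive (case is
folded at tokenize time). Multi-label by design: the free text can mention
several problems, unlike the single-choice chief complaint, whose cluster
matrix is one-hot at most. Severity-style *modulating* topics (acute,
chronic, severe, nonsevere) are tagged like any other topic but kept
outside the symptom clusters, carried as separate columns so models can
control for severity; a visit tagged only with a severity word still counts
as "no tag" at the symptom level. Cluster membership is configuration, not
code: a `ClusterMap` JSON maps topic names and chief-complaint codes into a
common cluster set and lists excluded codes (not-otherwise-specified
buckets), whose visits get all-zero rows flagged `unspecified`.

Keyword systems have no negation handling: "kein Fieber" tags fever. This
is a documented property of the method, acceptable for cohort-level
analysis, not for individual-level decisions.

## Outcome models

The three nested specifications share the covariate block X (age, gender,
admission mode indicators, ED census, shift with the early shift as
reference, treating team as indicator columns against the alphabetically
first level) and differ in the cluster blocks: NLP clusters Z (model 1),
chief-complaint clusters W (model 2), both (model 3).

The coefficient tables use a linear probability model (OLS), whose
coefficients read directly as probability differences; prediction uses
logistic regression. Both estimators sit behind the same design-matrix
builder. Classical standard errors are the default with an HC1 robust
option — LPM errors are heteroskedastic by construction, so robust errors
are recommended for inference on real data; the default keeps the simpler
estimator the coefficient tables are usually read with. Rank deficiency is
detected before fitting and reported with the offending columns (via
pivoted QR). A constant outcome yields the degenerate fit (intercept equal
to the constant, zero slopes) with R² reported as 0.

For OLS, model 3's R² dominates models 1 and 2 algebraically whenever all
three are fitted on the same sample; `nesting_check` asserts exactly that
and treats a violation as a sample-mismatch signal, not a statistical
finding.

Prediction uses a random, unstratified, seeded 2:1 train-test split;
F1 is computed on the positive class at a 0.5 probability threshold. Both
conventions are stated rather than tuned; stratification would only matter
for much rarer outcomes than the ones modelled here.

## Synthetic generator

The generator emulates the structure of an ED triage table, not its
language. Per visit: one latent topic, or — with probability 0.33 — two or
three (weighted 3:1), drawn by prevalence weights under which trauma
dominates (weight 0.32) and seven further topics share the rest; a note of
8–24 tokens that names every true topic at least once and otherwise mixes
topic words (share 0.5) with background words; a chief-complaint code that
names a true topic with fidelity 0.8, another topic otherwise, and an
uninformative "diverse" code with probability 0.115; covariates from
simple documented distributions (age uniform 18–90, EMS arrival 17%,
three-level shift, four-level team). Outcomes follow the linear probability
model on the *true* topic indicators and true chief-complaint cluster, with
coefficients in the ±0.02–0.15 range typical of triage outcomes, clipped to
[0, 1] (clipping beyond 1% of visits raises a warning).

Vocabularies are abstract letter-only stems (`traumaa`, `bgf`), pairwise
disjoint between topics and background, so tests carry no language
dependency; a small German-flavoured demo (chest-pain combination rule
`(schmerz|druck) AND (brust|thorax)`) ships in the fixture suite. What the
generator deliberately does **not** emulate: realistic clinical phrasing,
negation, spelling variation, compound words, overlapping topic
vocabularies, temporal or seasonal structure. Tests passing on this
generator therefore validate the *mechanics* — tagging, enhancement
geometry, estimator behaviour — not recall on real clinical German.

A `planted_embedding` companion places each topic's words around a common
unit direction (noise 0.25) and background words at independent random
directions — the geometry CBOW converges to on such a corpus — so
enhancement studies can run at scales where actual training would dominate
the runtime.

## Validation studies and problem sizes

The standing studies in `spherodict.experiments` use these sizes, chosen to
give stable rates while keeping a full run in the order of a minute:

* spherical oracle study: 50 random embeddings of 50–200 words,
  dimension 4–15, 2–5 seed keywords; checks exhaustive-scan equality and
  the per-word sphere certificate (tolerance 1e-12);
* no-tag monotonicity: 20 corpora of 1,000 visits; initial dictionaries
  hold 4 of 10 topic words, enhanced against a planted embedding;
* parameter recovery: 20 replicates at n = 50,000; each model is fitted on
  data generated under that model (fitting model 1 to data where the
  chief-complaint cluster also moves the outcome would measure
  omitted-variable bias, not recovery), on the true indicator matrices,
  with recovery-sized coefficients chosen so no generating probability
  needs clipping; a coefficient counts as recovered within 3 standard
  errors, and the R² nesting check runs on every replicate;
* prediction sanity: a separable outcome (AUC must be exactly 1), labels
  independent of features at n = 10,000 (AUC 0.5 ± 0.02), and the
  closed-form F1 of an all-positive predictor at 30% prevalence
  (2·0.3/1.3 = 0.4615).

With imperfect dictionaries the estimated cluster effects attenuate toward
zero relative to the generating coefficients (classical measurement-error
direction); the recovery study therefore uses oracle indicators, and
attenuation is observable but not asserted, since its size depends on
dictionary completeness.

## Known limitations

* Token-exact matching under-tags compounding languages (see above).
* No negation or uncertainty detection.
* The CBOW trainer is a reference implementation: correct, deterministic,
  and adequate for corpora up to a few hundred thousand short notes, but
  not performance-competitive with optimised implementations on large
  corpora.
* The enhancement radius is determined entirely by the initial keywords; a
  single outlier keyword widens d_max for the whole topic. Curating seeds
  before enhancing is part of the method, not optional polish.
* LPM probabilities are unbounded; coefficients near the [0, 1] boundary
  should be read with the logistic estimator as a cross-check.
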