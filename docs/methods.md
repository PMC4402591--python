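# Methods

## The knowledge-driven gate

The extraction model treats a set of known drug–side-effect pairs
K ⊂ D × S as an implicit sentence classifier.  A text unit (sentence, or
whole abstract) is *SE-related* iff it contains at least one known pair;
all drug × SE co-occurrences inside SE-related units become candidate
pairs, and candidates outside K are reported as novel, each with the set of
supporting units.  A unit contributes at most one count to a pair's support
regardless of repeated mentions, mirroring retrieval-set semantics.

Assumptions the gate relies on:

- side effects are reported in bursts — a unit that reports one SE of a
  drug usually reports several — so gating on one known pair exposes the
  others;
- the knowledge base is broadly correct: an erroneous pair (the packaged
  fixtures include a treatment relation mislabeled as a side effect)
  gates treatment sentences and propagates false extractions;
- co-occurrence within a gated unit implies relatedness.  This fails for
  n-drugs × m-SEs enumerations, where only a diagonal of the cross product
  is real; resolving those is explicitly out of scope.

Two granularities are supported.  Sentence-level extraction requires both
terms in one sentence and is the precise channel; abstract-level
containment lets the drug and SE sit in different sentences of one
abstract, a superset-style, noisier channel (`abstract` level in
`query_pair`, `classify_units`, `extract`).  The abstract title, when
present, is sentence 0.

## Matching and the noun-phrase restriction

Dictionary matching is case-insensitive whole-term matching at word
boundaries (boundary = text edge or non-alphanumeric character), with `/`
and `-` internal when part of a lexicon term, so composite terms like
`thrombosis/embolism` match as one unit.  Overlaps resolve
longest-match-leftmost, implemented by a single alternation ordered by
descending term length: multi-word terms ("decreases in hemoglobin") beat
their embedded unigrams.  Term normalization lowercases, strips and
collapses whitespace, and preserves punctuation; it is idempotent.

Matched drug and SE strings must additionally be noun phrases.  NP spans
are data: the corpus JSONL carries optional 0-based half-open character
intervals per sentence (in practice derived from a constituency parse; the
synthetic generator emits gold spans for every planted term).  A match is
kept iff its span is contained in some NP span (`np_strict=True` demands
exact span equality — the looser containment is the default because base-NP
annotations often include modifiers).  For unannotated sentences the
behavior is configurable: `require` drops all matches, `off` waives the
restriction, and the default `fallback` chunks the sentence with a
deterministic rule-based base-NP chunker (maximal token runs not containing
closed-class words — prepositions, conjunctions, determiners, auxiliaries
and a small list of reporting verbs — split at commas and parentheses).
The chunker is a surrogate, not a parser; its closed-class list is
versioned in the package so results are reproducible.  By default the NP
restriction also applies when classifying units (`NPConfig.gate`), since
gating and enumeration should see the same matches.

## SVM baseline

The comparison system is a two-class sentence classifier over bag-of-words
features: tokenize on non-alphanumerics, drop stopwords (an in-repo list of
function words), apply the standard Porter suffix-stripping stemmer, weight
with TF-IDF (idf = ln((1+N)/(1+df)) + 1, L2-normalized rows; the TF-IDF
and SVM fits are delegated to scikit-learn behind the module interface),
and fit a polynomial-kernel SVM.  Training data is distantly labeled:
positives are sentences containing at least one knowledge-base pair (with
the evaluation drugs' held-out pairs excluded from labeling), negatives an
equal-size uniform sample of the remaining sentences.  Class counts are
equal by construction and training aborts if the corpus cannot supply
enough negatives.

Kernel degree and cost are configuration, defaulting to degree 1 and C = 1
(the toolkit defaults; the original description names a polynomial kernel
without fixing either), with coef0 = gamma = 1 held fixed for
reproducibility.  Accuracy is estimated by stratified 10-fold
cross-validation (folds shrink only if a class has fewer than 10 members)
and stored in the model metadata.  Featurization determinism — a training
sentence re-featurizes to its training-time vector bit-for-bit — is
asserted on every training run; prediction uses an explicit kernel decision
function over the stored support vectors so a model reloaded from its JSON
archive (vocabulary, idf weights, support vectors, dual coefficients,
config) behaves identically to the freshly trained one.

## Evaluation protocol

For a drug panel (the original comparison used the ten drugs with the most
known SEs) each drug's known pairs are split per drug into halves
(deterministically seeded per `(seed, drug)`, so the partition is
independent of panel order); unlisted drugs' pairs remain entirely on the
train side.  Both methods see the same input sentences — those containing
at least one panel drug and at least one SE term.  The KD prior is the
train split; the SVM is trained with the test split excluded from labeling.
Extracted pairs for drug d are scored against the held-out half on pair
identity only, after removing train-split pairs (the "additional pairs"
semantics).  Reported aggregates are unweighted column means; the average
F1 is the mean of per-drug F1s, and the harmonic mean of the average
precision and recall is emitted separately, labeled, because the two
summaries differ in general.  The mean F1 increase is the mean of per-drug
increases, not the increase of the means; a drug with zero SVM F1
contributes no increase (the ratio is undefined) rather than infinity.

## Correlation analysis

From an extracted pair set, each drug's SE set is formed and every
unordered drug pair receives a shared-SE count (zero allowed; self-pairs
excluded).  For a cutoff grid (default {0, 1, 10, 50, 100}; cutoff 0 means
all pairs) the module reports, per cutoff, the number of qualifying pairs
and the mean of a drug-pair property: attribute-set overlap for
drug→attribute tables (both drugs must be present in the table to qualify)
or a pairwise score for drug-pair score tables (pairs missing from the
score table score 0 by default, `missing="skip"` drops them).  A cutoff
with no qualifying pairs records an undefined mean, never 0.  Qualifying
counts are non-increasing in the cutoff and this is asserted structurally.

## Synthetic data: what it emulates and what it does not

The generator plants a ground truth and emits a corpus realizing it:

- **lexicons** — pseudo-word drug and SE names (a quarter of SEs two-word),
  globally unique with unique head words, so no term embeds another;
- **latent classes** — drugs are assigned round-robin to classes (default
  3) that partition the SE lexicon into pools; a per-drug *fidelity*
  f_d ~ U(0.5, 1) controls how much of the drug's SE set (default density
  0.2 of the lexicon; 0.25 in the correlation studies) comes from its class
  pool.  The same fidelity drives the attribute tables and the class-linked
  score tables, so shared SEs, shared attributes and class-linked scores
  co-vary, while the "experimental" score table is drawn independently of
  class as a flat control;
- **abstracts** — a title naming the drug, SE-reporting sentences that
  enumerate the drug's true SEs in chunks of `ses_per_sentence` (≥ 2 per
  sentence, and every true pair is emitted somewhere), confounding
  sentences pairing a random drug with SE-lexicon terms that are *not* its
  side effects (fraction `confound_rate` of body sentences), and a few
  term-free filler sentences that stand in for the bulk of ordinary
  literature and provide the negative pool for distant supervision.
  SE-reporting and confounding sentences draw from one shared template
  pool, so surface wording carries no signal about which co-mentions are
  genuine — only the prior knowledge separates them, which is the regime
  where knowledge gating beats a trained sentence classifier and is how
  the precision/recall pattern of the evaluation (KD precise, SVM
  high-recall/low-precision) arises here.  Gold NP spans cover every
  emitted term;
- **prior** — a deterministic nested subset of the truth (ranked by a
  seed-independent per-pair hash, take the top `prior_coverage` fraction),
  so priors at increasing coverage are supersets of one another and recall
  monotonicity in coverage is a property of the experiment design.

Features of real literature deliberately *not* modeled: linguistic
variation and negation/speculation, synonymy and abbreviation, mixed
multi-drug reporting sentences (the n × m failure case appears only in the
packaged fixtures), publication-date structure, and knowledge-base errors
(again fixtures only).  Consequently, sentence-level gating on this
generator yields perfect precision by construction — confounders never
contain a true pair, so they are never gated — and passing synthetic tests
demonstrates the mechanics and the relative ordering of methods, not
absolute performance on real text.

## Numerical and procedural choices

- Coordinates are 0-based half-open character offsets everywhere.
- Splits round the train share with banker's rounding and clamp so both
  halves are non-empty; at fraction 0.5 the halves differ by at most one.
- All randomness (splits, negative sampling, cross-validation folds,
  generation) is seeded; the library default seed is 17.
- The per-drug comparison table is written with 3-decimal formatting to
  match the conventional presentation; computations keep full precision.
- Problem sizes in the tests and the acceptance script (15–60 drugs,
  36–60 SE terms, 40–200 abstracts) were chosen as the smallest corpora at
  which every studied effect is stable across seeds; the correlation study
  uses 60 drugs at density 0.25 specifically so that every shared-SE
  cutoff bin keeps enough qualifying pairs for stable means.
- The flatness of the control score curve is tested against a 3-standard-
  error band; the permutation-null check averages 30 attribute shuffles
  and compares the high-cutoff/all-pairs gap to a 3-SEM interval.

## Known limitations

- The base-NP fallback chunker is a heuristic; supply parse-derived
  `np_spans` in the corpus JSONL for faithful NP restriction.
- Abstract-level extraction with `np_mode=require` silently drops
  unannotated sentences, which can make the abstract channel sparser than
  intended on partially annotated corpora.
- The SVM archive stores dense support vectors; it is meant for
  desk-scale models, not literature-scale ones.
- Knowledge-base errors are faithfully propagated by design; no filtering
  or ranking of novel pairs is attempted.
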