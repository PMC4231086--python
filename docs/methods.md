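# Methods

This note records the models, conventions, and design choices behind
`clinneg`, in the order data flows through the toolkit.

## Data model and formats

The unit of classification is one named entity (NE): a half-open, 0-based
token span in a sentence, with a coarse semantic group and a polarity
label (−1 negated, +1 not negated; −1 is the positive class in every
metric). Sentences optionally carry a dependency tree (one head per
token, `ROOT = -1`) and a constituency parse (Penn-style brackets).
Documents group sentences and are the exchangeable unit for significance
testing.

Two file formats are supported. The standoff format is JSON lines — a
header record, then one document per line — chosen over a columnar format
so that parses, POS tags, and NEs round-trip exactly
(`write_standoff ∘ read_standoff` is the identity). The tab-delimited
reader for NegEx-Test-Set-style files tokenizes by whitespace and then
splits trailing punctuation; that distribution ships pre-simplified
sentence text, and window features need stable token counts. When a
concept phrase occurs more than once in its sentence the first
(case-insensitive) occurrence is annotated, matching that set's
one-annotation-per-sentence design; records whose phrase cannot be
located are excluded with a logged warning and counted in `meta`, and
sentence and NE counts are reported independently (they need not be
equal). Because that format has no document IDs but the randomization
test needs exchangeable units, consecutive records are grouped into
pseudo-documents (default 20 records; recorded in `meta`).

Constituency brackets are read and written by a small in-package parser
rather than an external NLP toolkit; the subset of Penn notation used
here (including childless `(LABEL )` stubs for pruned nodes) is ~40
lines to support exactly.

## Rule baseline

`negex_classify` marks an NE negated iff a non-pseudo pre-negation
trigger precedes it, or a post-negation trigger follows it, within
`max_scope` tokens (default 5, the classic window; distance is counted
between the trigger's and the NE's nearest edges, multi-token triggers
consuming their full span) with no termination phrase in between. Pseudo
phrases are matched longest-first and suppress any pre-negation trigger
they overlap, so "no increase in edema" does not negate "edema". If both
a pre- and a post-trigger are in scope the NE is negated — either
condition suffices. The shipped four-section lexicon is data, not code,
because per-corpus rule customization is almost always needed in
practice; it follows the publicly distributed NegEx trigger lists but
parity with any particular derivative implementation is not claimed.

## Feature families

All features are binary and local to the NE's sentence.

- **BOW** — distinct lowercased tokens in a directional window of 3, 5,
  or 10 tokens (preceding/following), clipped at sentence boundaries;
  NE-internal tokens excluded. Windows never cross sentences.
- **POS_CTX** — (offset, token) pairs for offsets 0..w−1 on each side,
  w ∈ {4, 5}. Offset 0 is the token adjacent to the NE edge, counting
  outward; the 0-based convention is fixed and documented because "N
  words preceding" is ambiguous between 0- and 1-based.
- **CUE** — the nearest in-scope cue phrase (surface form and normalized
  category) plus an "any cue present" indicator. Scope = same sentence,
  uninterrupted by a termination phrase; nearest by token distance, ties
  preferring the preceding side. The default cue lexicon covers the
  categories that dominate clinical negation (no / deny / negative /
  without / absent / ruled_out) and is extensible data.
- **DEPPATH** — 12 declarative path patterns, each anchored at a
  negation word class (negation determiners, negation verbs, negation
  adjectives, "without") and walking typed dependency steps
  (up to head / down to dependent); a rule fires when a path ends at the
  NE head (the rightmost NE token governed from outside the span). The
  inventory is a reconstruction in the spirit of dependency-rule negation
  systems, serialized as JSON and replaceable wholesale.
- **TREEFRAG** — position-tagged partial constituency trees around the
  NE's covering node: every subtree of each sibling (pruned to 2 levels;
  nodes at the limit render as `(LABEL )`), plus up to 2 ancestor
  fragments with the NE subtree replaced by `(CONCEPT )` and siblings
  pruned to one level — yielding fragments like `(DT no)` and
  `(NP (DT no) (CONCEPT ))` tagged above-left/above-right. The inventory
  is extracted from training data with an occurrence threshold
  (default 2), which bounds feature-space growth.

Tokens are lowercased but not stemmed, so "denies" and "deny" remain
distinct features. Sentences without dependency or constituency
annotations simply contribute no DEPPATH/TREEFRAG features; nothing
errors.

## Classifier and domain adaptation

The classifier is a linear-kernel SVM (liblinear via scikit-learn,
tolerance 1e-4, bounded iterations). Its one tunable parameter C is
selected from a grid (default {0.01, 0.1, 1, 10, 100}) by
cross-validation whose folds are split by document ID — NEs of one
document never straddle a fold boundary — scored by F1 of the negated
class; ties prefer the smallest C, and the seed controls only fold
assignment. A single-value grid skips the search. No class weighting by
default (prevalence varies widely across corpora, so it is exposed as
configuration). A score of exactly 0 maps to +1, favoring precision on
the rarer negated class. Unseen test-time features are ignored (frozen
feature space). Models serialize to a versioned JSON file (weights, bias,
feature space, block layout) and round-trip exactly.

FEDA is implemented as pure feature augmentation: block 0 is the shared
space, blocks 1..K follow the domain order, and the column of
(block b, feature f) is `b·V + column(f)` for base vocabulary size V.
Every training vector is logged in the general block and its own domain
block — exactly doubling its nonzeros — and the full space is exactly
(K+1)× the pooled space. At test time a known domain activates blocks
{0, k}; an unknown or unspecified domain uses block 0 alone. Any
weighting between general and domain-specific knowledge emerges from
training; no extra test-time weighting is applied.

χ² feature scoring uses the uncorrected Pearson statistic of the 2×2
(negated × feature-present) table, 0 when a margin is empty; continuity
correction is deliberately omitted since the statistic is used for
ranking at corpus scale. `chi2_filter` retains features at or above a
threshold.

## Evaluation methodology

Precision, recall, and F1 are computed over the negated class; when a
denominator is 0 the quantity is defined as 0, and the all-negative
degenerate case warns. Macro-average = arithmetic mean of per-corpus F1;
micro-average = F1 recomputed from summed confusion counts (asserted
equal to pooled-count F1, not to lie between per-corpus extremes, which
is false in general).

The significance test is paired approximate randomization on |ΔF1|,
aggregated by document: each shuffle swaps the two systems' outputs for
whole documents independently with probability ½, and the p-value is
(r+1)/(n+1) over 9,999 shuffles by default (1,000 in the calibration
benchmark). Whole-document swapping — rather than per-NE resampling — is
the implemented reading of document aggregation, and fewer than two
documents is an error. The estimator is slightly conservative, which the
null-calibration benchmark makes visible (rejection rates near but at or
below the nominal level).

Learning curves sample training instances without replacement, fresh per
run, and rerun the full pipeline (fragment extraction on the subsample,
feature extraction, training, evaluation) at each proportion, averaging
F1 over runs (default 5) per point.

## Synthetic corpus generator

The generator exists because the major annotated clinical corpora are
restricted; it emulates the statistics that matter for cross-domain
negation experiments, not clinical prose. Sentences come from a small
set of templates (plain assertion; determiner/verb/adjective/preposition
cues before the NE; passive "was ruled out" after it; a "has
resolved"-style post-verb; a pseudo-negation lookalike; a
termination-clause pattern "denies X but reports NE"; and a
morphologically negated predicate "the patient is afebrile"). Each
template emits tokens together with a consistent dependency tree and
constituency parse, so parses are gold by construction and parser error
is removed as a confound. Gold polarity follows the generative rule —
cue in scope ⇒ negated, morphologically negated token ⇒ negated,
otherwise affirmed — and `generative_oracle` repackages that rule as a
classifier that reproduces the labels with accuracy 1.0, the sanity
ceiling for everything downstream.

Per-domain parameters: negation prevalence, weighted cue inventory,
pseudo-cue rate (default 0.08), termination-pattern rate (default 0.08),
NE length distribution over 1–5 tokens (default mass concentrated on
short NEs), semantic-group mix, content vocabulary (validated disjoint
from cue words), and a morphological-negation rate. Presets:

- `paper_like` — four domains at prevalences 0.087 / 0.212 / 0.072 /
  0.207, the range reported across published clinical corpora, with the
  i2b2-style domain realizing ≈8% of its negated NEs as single
  inherently negated tokens (the "afebrile" pattern, echoing the
  published 8.3% figure) and group mixes patterned on the published
  per-corpus distributions.
- `conflict` — two domains sharing core cues but disagreeing on "the
  \<NE\> has resolved" (negated in `alpha`, affirmed in `beta`, 35% of
  `beta`'s affirmed NEs): the designed stress test for FEDA. Because
  morphological negation would only add label noise that context features
  cannot see, these two presets leave it at 0.
- `shared_core` — two domains sharing the high-value cues ("no",
  "denies", "without") with disjoint domain-specific cues beyond the
  core, used for out-of-domain learning-curve experiments.

Determinism: one master seed; each domain's stream is
`default_rng((seed, domain_index))`, so a config reproduces byte-identical
standoff files.

What passing tests on this generator do *not* show: robustness to real
clinical prose (abbreviations, telegraphic style, misspellings, parser
errors, sentence-boundary noise), to NE recognition errors (gold NEs
only, by design), or to negation phenomena outside the template
inventory (uncertainty, experiencer, conditional contexts). The
generator's conclusions are about the *machinery* — that the learners,
the adaptation scheme, and the evaluation statistics behave as designed
when the signal is known.

## Benchmark problem sizes

The benchmark experiments (`clinneg.benchmarks`) fix C = 1 — the
synthetic problems are nearly separable, where the grid search is inert —
and use 2,000 NEs per domain for training (50 documents × 40 sentences),
600 per domain held out, 5 seeds for the FEDA-benefit and
generalizability comparisons, and 500 replicates × 1,000 shuffles × 30
documents for the null calibration of the randomization test.

## Known limitations

- The dependency-path rule inventory and cue list are reconstructions;
  both are data files and should be replaced when a vetted inventory is
  available.
- The rule baseline implements the negation dimension only (no
  uncertainty or experiencer handling) and does not split sentences.
- Fragment extraction limits context to two ancestor levels and
  immediate siblings; deeper syntactic context is out of scope.
- Readers for restricted-corpus native formats are future adapters; the
  toolkit exchanges data via its standoff format.
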