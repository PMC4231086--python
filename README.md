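# clinneg

Negation detection for named entities in clinical text — and the tooling
to ask whether a negation detector actually *generalizes* across corpora,
or merely optimizes for one.

## The problem

Clinical narrative asserts absence constantly ("no wheezing", "denies
chest pain", "pneumonia was ruled out"), and any practical use of
clinical NLP must set each named entity's **polarity**: −1 (negated, the
condition is asserted absent) or +1 (not negated). Rule-based systems in
the NegEx tradition handle the common cases well on the data they were
developed for, but corpora differ in annotation guidelines, cue
vocabulary, entity definitions, and negation prevalence (roughly 4%–21%
of NEs across published corpora), so performance transfers poorly between
domains. `clinneg` provides both kinds of system and the full evaluation
methodology for cross-domain experiments:

- **Rule baseline** (`clinneg.negex`): trigger/scope classification with
  pre-negation, post-negation, pseudo-negation, and termination phrase
  lists shipped as editable data, and a bounded scope window
  (`max_scope`, default 5 tokens).
- **Feature extraction** (`clinneg.features`): five binary feature
  families per NE — bag-of-words windows (3/5/10 tokens, each side),
  exact-position context (windows 4/5), nearest in-scope cue word and
  category, dependency-path negation rules (12 declarative patterns), and
  constituency tree fragments with the NE replaced by a `CONCEPT`
  placeholder.
- **Classifier** (`clinneg.model`): a linear-kernel SVM (liblinear) over
  the sparse binary feature space; the single regularization constant C
  is tuned by document-grouped cross-validation. The decision rule is
  sign(w·v + b), ties mapped to +1.
- **Domain adaptation**: frustratingly easy domain adaptation (FEDA).
  With K domains the feature space becomes K+1 blocks
  v = [v_all, v_1, …, v_K]; an instance from domain k populates v_all
  and v_k only, so every vector carries exactly 2× its features and the
  space is (K+1)× the pooled one. At test time a known domain activates
  its block; an unknown domain falls back to the general block.
- **Evaluation** (`clinneg.evaluation`): precision/recall/F1 with −1 as
  the positive class, micro/macro averages over test corpora,
  document-aggregated approximate randomization significance tests, χ²
  feature ranking on the 2×2 (negated × feature-present) table, learning
  curves over training proportions, and breakdowns by NE length or
  semantic group.
- **Synthetic corpora** (`clinneg.synthetic`): a template-based generator
  of multi-domain gold corpora (tokens, dependency and constituency
  parses, NEs, polarity) with controllable prevalence, cue inventories,
  pseudo-negation rate, morphologically negated tokens ("afebrile"), and
  designed cross-domain conflicts — because the major annotated clinical
  corpora are restricted by data-use agreements.

## Worked example

Train pooled and FEDA models on a two-domain synthetic suite in which the
construction "the \<NE\> has resolved" is annotated *negated* in domain
`alpha` but *affirmed* in domain `beta` — the kind of guideline conflict
that defeats a single pooled model:

```python
import dataclasses
import clinneg as cn
from clinneg.synthetic import preset_suite, generate

cfg = dataclasses.replace(preset_suite("conflict"), n_documents=30, seed=42)
train_suite = generate(cfg)
test_suite = generate(dataclasses.replace(cfg, seed=10042, n_documents=10))

merged = cn.concat_corpora(train_suite.values())
fc = cn.FeatureConfig()
fc.fragment_inventory = cn.extract_fragments(merged, threshold=2)
instances = [i for c in train_suite.values() for i in cn.make_instances(c, fc)]
print(f"training instances: {len(instances)}; feature space: "
      f"{len({f for i in instances for f in i.vector})} features")

pooled = cn.train(instances, cn.TrainConfig(regularization_grid=(1.0,)))
feda = cn.train(instances, cn.TrainConfig(regularization_grid=(1.0,), feda=True,
                                          domains=("alpha", "beta")))
for name, corpus in test_suite.items():
    p_pool = cn.predict_corpus(pooled, corpus, fc, test_domain=name)
    p_feda = cn.predict_corpus(feda, corpus, fc, test_domain=name)
    sig = cn.approx_randomization(p_pool, p_feda, corpus, n_shuffles=9999, seed=0)
    print(f"{name}: pooled F1 = {cn.prf(p_pool, corpus).f1:.3f}, "
          f"FEDA F1 = {cn.prf(p_feda, corpus).f1:.3f}, "
          f"randomization p = {sig.p_value:.4f}")

print("top chi2 features:")
for row in cn.chi2_rank(instances)[:5]:
    print(f"  {row.chi2:8.1f}  {row.feature}")
```

Output:

```
training instances: 2400; feature space: 396 features
alpha: pooled F1 = 0.780, FEDA F1 = 1.000, randomization p = 0.0036
beta: pooled F1 = 1.000, FEDA F1 = 1.000, randomization p = 1.0000
top chi2 features:
  1183.1  DEPPATH:rule:1
  1183.1  TREEFRAG:above_left:(DT no)
   908.1  CUE:any
   600.4  BOW:prec:10:no
   600.4  BOW:prec:3:no
```

Reading this: the pooled model is torn on `alpha`, where "resolved"
contexts carry labels that contradict what it learned from `beta`
(F1 = 0.780); FEDA's domain blocks absorb the conflict and recover
perfect held-out F1, and the document-aggregated randomization test calls
the difference significant (p ≈ 0.004). On `beta` the two models agree,
so the observed ΔF1 is 0 and p = 1. The top-ranked features are the
"easy cases" of negation — a dependency path from a negation determiner
to the NE head, the `(DT no)` tree-fragment context, and "no" in the
preceding bag-of-words windows.

A command-line interface covers the same pipeline (`clinneg generate`,
`stats`, `negex`, `train`, `predict`, `evaluate`, `compare`,
`chi2-rank`, `learning-curve`); corpora travel in a JSON-lines standoff
format, and the freely downloadable NegEx Test Set's tab-delimited format
can be converted with `clinneg convert`.

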