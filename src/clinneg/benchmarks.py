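"""Reproducible benchmark experiments on the synthetic corpus suites.

These drive the full pipeline — generation, fragment extraction, feature
extraction, training, evaluation — under fixed study conditions, and back
both the test suite and the reproduction script.  All randomness flows
from the ``seed`` arguments.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .corpus import Corpus
from .evaluation import approx_randomization, learning_curve, prf
from .features import FeatureConfig, extract_fragments
from .model import PolarityModel, TrainConfig, make_instances, predict_corpus, train
from .synthetic import generate, preset_suite

#: The benchmarks fix C = 1 (no grid search) so that every training run is
#: a single liblinear fit; the cue/window design makes the problem nearly
#: separable, where C barely matters.
_BENCH_TRAIN = TrainConfig(regularization_grid=(1.0,))


def _feature_config(train_corpus: Corpus, threshold: int = 2) -> FeatureConfig:
    fc = FeatureConfig()
    fc.fragment_inventory = extract_fragments(train_corpus, threshold)
    return fc


def _suite(preset: str, seed: int, n_documents: Optional[int] = None,
           sentences_per_document: Optional[int] = None) -> dict[str, Corpus]:
    cfg = preset_suite(preset)
    kw: dict = {"seed": seed}
    if n_documents is not None:
        kw["n_documents"] = n_documents
    if sentences_per_document is not None:
        kw["sentences_per_document"] = sentences_per_document
    return generate(dataclasses.replace(cfg, **kw))


def feda_benefit(seed: int, n_documents: int = 50, test_documents: int = 15):
    """Pooled vs FEDA training on the "conflict" suite.

    Trains both models on the union of both domains' training corpora and
    evaluates accuracy on held-out corpora from both domains (generated
    with an independent seed).  Returns (pooled accuracy, FEDA accuracy).
    """
    tr = _suite("conflict", seed, n_documents=n_documents)
    te = _suite("conflict", seed + 10_000, n_documents=test_documents)
    from .corpus import concat_corpora

    merged = concat_corpora(tr.values())
    fc = _feature_config(merged)
    instances = [i for c in tr.values() for i in make_instances(c, fc)]
    domains = tuple(tr)
    pooled = train(instances, _BENCH_TRAIN)
    feda = train(instances, dataclasses.replace(_BENCH_TRAIN, feda=True, domains=domains))

    def accuracy(model: PolarityModel) -> float:
        correct = total = 0
        for name, c in te.items():
            preds = predict_corpus(model, c, fc, test_domain=name)
            gold = [ne.polarity for ne in c.entities]
            correct += sum(p == g for p, g in zip(preds, gold))
            total += len(gold)
        return correct / total

    return accuracy(pooled), accuracy(feda)


def generalizability(seed: int, n_documents: int = 50, test_documents: int = 15):
    """Mean in-domain vs mean out-of-domain F1 on the "conflict" suite
    (two domains whose cue inventories conflict on one construction).

    Returns (mean in-domain F1, mean out-of-domain F1).
    """
    tr = _suite("conflict", seed, n_documents=n_documents)
    te = _suite("conflict", seed + 10_000, n_documents=test_documents)
    names = list(tr)
    in_f1, out_f1 = [], []
    for a in names:
        fc = _feature_config(tr[a])
        model = train(make_instances(tr[a], fc), _BENCH_TRAIN)
        for b in names:
            f1 = prf(predict_corpus(model, te[b], fc), te[b]).f1
            (in_f1 if a == b else out_f1).append(f1)
    return float(np.mean(in_f1)), float(np.mean(out_f1))


def learning_curve_plateau(seed: int, n_documents: int = 50, test_documents: int = 15,
                           runs: int = 5):
    """Out-of-domain learning curve on the "shared_core" suite (train on
    the source domain, test on the target domain whose cue vocabulary is
    disjoint beyond the shared core).

    Returns (mean F1 at 20% of the training data, mean F1 at 100%).
    """
    tr = _suite("shared_core", seed, n_documents=n_documents)
    te = _suite("shared_core", seed + 10_000, n_documents=test_documents)
    curves = learning_curve(
        tr["source"],
        [te["target"]],
        train_config=_BENCH_TRAIN,
        proportions=(0.2, 1.0),
        runs=runs,
        seed=seed,
    )
    pts = {p.proportion: p.mean_f1 for p in curves["target"]}
    return pts[0.2], pts[1.0]


def randomization_null_calibration(
    seed: int,
    replicates: int = 500,
    n_shuffles: int = 1000,
    n_documents: int = 30,
    nes_per_document: int = 10,
    flip_rate: float = 0.15,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the randomization test under an exchangeable null.

    Two systems are noise-equivalent: each flips every gold label
    independently with the same probability.  Returns the fraction of
    replicates with p <= alpha (should be close to alpha).
    """
    rejections = 0
    doc_ids = [f"d{i}" for i in range(n_documents) for _ in range(nes_per_document)]
    for rep in range(replicates):
        rng = np.random.default_rng((seed, rep))
        gold = list(rng.choice([-1, 1], p=[0.2, 0.8], size=len(doc_ids)))

        def noisy():
            flips = rng.random(len(gold)) < flip_rate
            return [-g if fl else g for g, fl in zip(gold, flips)]

        res = approx_randomization(
            noisy(), noisy(), gold, n_shuffles=n_shuffles, seed=int(rng.integers(2**31)),
            doc_ids=doc_ids,
        )
        rejections += res.p_value <= alpha
    return rejections / replicates
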