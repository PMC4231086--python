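"""Evaluation methodology for cross-corpus negation experiments.

Covers precision/recall/F1 on the negated class, micro and macro averages
over test corpora, document-aggregated approximate randomization
significance tests, learning curves over training-data proportions, χ²
feature ranking, and breakdowns by NE length or semantic group.

Conventions: −1 (negated) is the positive class for every metric; F1 is
the harmonic mean of precision and recall, with the degenerate
no-positives case defined as 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .corpus import NEGATED, Corpus, NamedEntity
from .features import FeatureConfig, FeatureName, extract_fragments
from .model import TrainConfig, TrainingInstance, make_instances, predict_corpus, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts over the negated (−1) class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    doc_id: Optional[str] = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def _prf_from_counts(c: ConfusionCounts) -> tuple[float, float, float]:
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    per_document: tuple[ConfusionCounts, ...] = ()


GoldLike = Union[Corpus, Sequence[int]]


def _gold(gold: GoldLike, doc_ids: Optional[Sequence[str]]) -> tuple[list[int], list[str]]:
    if isinstance(gold, Corpus):
        labels = []
        docs = []
        for ne in gold.entities:
            if ne.polarity is None:
                raise ValueError("gold corpus has NEs without polarity")
            labels.append(ne.polarity)
            docs.append(gold.doc_of(ne))
        return labels, docs
    labels = list(gold)
    if doc_ids is None:
        docs = [""] * len(labels)
    else:
        docs = list(doc_ids)
        if len(docs) != len(labels):
            raise ValueError("doc_ids and gold have different lengths")
    return labels, docs


def prf(
    predictions: Sequence[int],
    gold: GoldLike,
    doc_ids: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Precision, recall, and F1 of the negated class, with per-document
    confusion counts.  ``gold`` is a gold-labelled corpus or an aligned
    label sequence (optionally with ``doc_ids``)."""
    gold_labels, docs = _gold(gold, doc_ids)
    if len(predictions) != len(gold_labels):
        raise ValueError(
            f"predictions ({len(predictions)}) and gold ({len(gold_labels)}) differ in length"
        )
    per_doc: dict[str, list[int]] = {}
    for pred, g, d in zip(predictions, gold_labels, docs):
        cell = per_doc.setdefault(d, [0, 0, 0, 0])
        if g == NEGATED and pred == NEGATED:
            cell[0] += 1
        elif g != NEGATED and pred == NEGATED:
            cell[1] += 1
        elif g == NEGATED and pred != NEGATED:
            cell[2] += 1
        else:
            cell[3] += 1
    doc_counts = tuple(
        ConfusionCounts(tp, fp, fn, tn, doc_id=d) for d, (tp, fp, fn, tn) in per_doc.items()
    )
    total = sum(doc_counts, ConfusionCounts())
    if total.tp + total.fn == 0 and total.fp == 0:
        warnings.warn("no gold or predicted negated NEs; recall and F1 defined as 0")
    p, r, f = _prf_from_counts(total)
    return EvalResult(p, r, f, total, per_document=doc_counts)


def micro_macro(results: Sequence[EvalResult]) -> tuple[float, float]:
    """(micro F1, macro F1) over per-corpus results: micro recomputes F1
    from the summed confusion counts; macro is the arithmetic mean of the
    per-corpus F1 scores."""
    if not results:
        raise ValueError("micro_macro needs at least one result")
    macro = float(np.mean([r.f1 for r in results]))
    pooled = ConfusionCounts()
    for r in results:
        pooled = pooled + r.counts
    _, _, micro = _prf_from_counts(pooled)
    return micro, macro


# ---------------------------------------------------------------------------
# Approximate randomization significance testing


@dataclass(frozen=True)
class SignificanceResult:
    f1_a: float
    f1_b: float
    p_value: float
    n_shuffles: int
    seed: int


def _f1_from_triplets(counts: np.ndarray) -> np.ndarray:
    """F1 from rows of (tp, fp, fn); vectorized, 0-safe."""
    counts = np.atleast_2d(counts)
    tp, fp, fn = counts[:, 0], counts[:, 1], counts[:, 2]
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / np.where(denom > 0, denom, 1), 0.0)
    return f1


def approx_randomization(
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    gold: GoldLike,
    n_shuffles: int = 9999,
    seed: int = 0,
    doc_ids: Optional[Sequence[str]] = None,
) -> SignificanceResult:
    """Paired approximate randomization test for an F1 difference,
    aggregated by document.

    The statistic is |F1_a − F1_b|.  Each shuffle swaps the two systems'
    outputs for a random subset of whole documents (each document with
    probability ½) and recomputes both F1 scores from the pooled
    per-document counts; the p-value uses the (r+1)/(n+1) estimator.
    """
    gold_labels, docs = _gold(gold, doc_ids)
    if not (len(pred_a) == len(pred_b) == len(gold_labels)):
        raise ValueError("predictions and gold must be aligned one-to-one")
    uniq_docs = sorted(set(docs))
    if len(uniq_docs) < 2:
        raise ValueError("randomization test needs at least 2 documents as exchangeable units")
    doc_index = {d: i for i, d in enumerate(uniq_docs)}
    counts_a = np.zeros((len(uniq_docs), 3))
    counts_b = np.zeros((len(uniq_docs), 3))
    for pa, pb, g, d in zip(pred_a, pred_b, gold_labels, docs):
        row = doc_index[d]
        for counts, pred in ((counts_a, pa), (counts_b, pb)):
            if g == NEGATED and pred == NEGATED:
                counts[row, 0] += 1
            elif g != NEGATED and pred == NEGATED:
                counts[row, 1] += 1
            elif g == NEGATED and pred != NEGATED:
                counts[row, 2] += 1
    f1_a = float(_f1_from_triplets(counts_a.sum(axis=0))[0])
    f1_b = float(_f1_from_triplets(counts_b.sum(axis=0))[0])
    observed = abs(f1_a - f1_b)

    rng = np.random.default_rng(seed)
    flips = rng.random((n_shuffles, len(uniq_docs))) < 0.5
    keep = ~flips
    shuf_a = flips.astype(float) @ counts_b + keep.astype(float) @ counts_a
    shuf_b = flips.astype(float) @ counts_a + keep.astype(float) @ counts_b
    deltas = np.abs(_f1_from_triplets(shuf_a) - _f1_from_triplets(shuf_b))
    r = int(np.sum(deltas >= observed - 1e-12))
    p = (r + 1) / (n_shuffles + 1)
    return SignificanceResult(f1_a=f1_a, f1_b=f1_b, p_value=p, n_shuffles=n_shuffles, seed=seed)


# ---------------------------------------------------------------------------
# Learning curves


@dataclass(frozen=True)
class LearningCurvePoint:
    proportion: float
    mean_f1: float
    n_runs: int
    per_run_f1: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(self.mean_f1 - float(np.mean(self.per_run_f1))) > 1e-9:
            raise ValueError("mean_f1 must equal the mean of per_run_f1")


def _subset_entities(corpus: Corpus, indices: Sequence[int]) -> Corpus:
    return Corpus(
        name=corpus.name,
        domain=corpus.domain,
        sentences=corpus.sentences,
        entities=[corpus.entities[i] for i in indices],
        meta=dict(corpus.meta),
    )


def learning_curve(
    train_corpus: Corpus,
    test_corpora: Sequence[Corpus],
    feature_config: Optional[FeatureConfig] = None,
    train_config: Optional[TrainConfig] = None,
    proportions: Sequence[float] = tuple(p / 10 for p in range(1, 11)),
    runs: int = 5,
    seed: int = 0,
    fragment_threshold: int = 2,
) -> dict[str, list[LearningCurvePoint]]:
    """F1 on each test corpus as a function of the training proportion.

    For each proportion, training instances are sampled without
    replacement (fresh per run), the full pipeline (fragment extraction →
    feature extraction → training → evaluation) is run, and F1 scores are
    averaged over ``runs`` runs.
    """
    if not train_corpus.entities:
        raise ValueError("training corpus is empty")
    feature_config = feature_config or FeatureConfig()
    train_config = train_config or TrainConfig()
    n = len(train_corpus.entities)
    per_run: dict[str, dict[float, list[float]]] = {
        c.name: {p: [] for p in proportions} for c in test_corpora
    }
    for run in range(runs):
        rng = np.random.default_rng((seed, run))
        for p in proportions:
            k = max(2, int(round(p * n)))
            idx = rng.choice(n, size=min(k, n), replace=False)
            sub = _subset_entities(train_corpus, sorted(int(i) for i in idx))
            fc = FeatureConfig(**{**feature_config.__dict__})
            if fc.treefrag and fc.fragment_inventory is None:
                fc.fragment_inventory = extract_fragments(sub, fragment_threshold)
            instances = make_instances(sub, fc)
            if len({i.label for i in instances}) < 2:
                for c in test_corpora:
                    per_run[c.name][p].append(0.0)
                continue
            model = train(instances, train_config)
            for c in test_corpora:
                preds = predict_corpus(model, c, fc)
                per_run[c.name][p].append(prf(preds, c).f1)
    out: dict[str, list[LearningCurvePoint]] = {}
    for c in test_corpora:
        out[c.name] = [
            LearningCurvePoint(
                proportion=p,
                mean_f1=float(np.mean(per_run[c.name][p])),
                n_runs=runs,
                per_run_f1=tuple(per_run[c.name][p]),
            )
            for p in proportions
        ]
    return out


# ---------------------------------------------------------------------------
# χ² feature ranking


def chi2_statistic(a: int, b: int, c: int, d: int) -> float:
    """Pearson χ² of a 2×2 table, no continuity correction.

    Cells: a = negated & feature present, b = not-negated & present,
    c = negated & absent, d = not-negated & absent.  Zero when any margin
    is empty.
    """
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    num = n * (a * d - b * c) ** 2
    return num / (r1 * r2 * c1 * c2)


@dataclass(frozen=True)
class FeatureRankRow:
    feature: FeatureName
    chi2: float
    rank_by_model: Mapping[str, int] = field(default_factory=dict)


def chi2_rank(instances: Sequence[TrainingInstance]) -> list[FeatureRankRow]:
    """Features ranked by descending χ² of the 2×2 (negated ×
    feature-present) table; ties broken lexicographically by feature key.
    Invariant to feature and instance order."""
    labels = {i.label for i in instances}
    if len(labels) < 2:
        raise ValueError("chi2_rank requires both classes present")
    n = len(instances)
    n_neg = sum(1 for i in instances if i.label == NEGATED)
    present_neg: dict[FeatureName, int] = {}
    present_all: dict[FeatureName, int] = {}
    for inst in instances:
        for f in inst.vector:
            present_all[f] = present_all.get(f, 0) + 1
            if inst.label == NEGATED:
                present_neg[f] = present_neg.get(f, 0) + 1
    rows = []
    for f, tot in present_all.items():
        a = present_neg.get(f, 0)
        b = tot - a
        c = n_neg - a
        d = n - n_neg - b
        rows.append(FeatureRankRow(feature=f, chi2=chi2_statistic(a, b, c, d)))
    rows.sort(key=lambda r: (-r.chi2, str(r.feature)))
    return rows


def feature_rank_table(
    instances_by_model: Mapping[str, Sequence[TrainingInstance]],
    reference: str = "all",
) -> list[FeatureRankRow]:
    """Rank features by χ² in the ``reference`` model and attach each
    feature's 1-based rank in every model (features a model never saw are
    omitted from its ranking)."""
    if reference not in instances_by_model:
        raise ValueError(f"reference model {reference!r} not among {sorted(instances_by_model)}")
    ranks: dict[str, dict[FeatureName, int]] = {}
    for name, instances in instances_by_model.items():
        ranks[name] = {row.feature: i + 1 for i, row in enumerate(chi2_rank(instances))}
    out = []
    for row in chi2_rank(instances_by_model[reference]):
        out.append(
            FeatureRankRow(
                feature=row.feature,
                chi2=row.chi2,
                rank_by_model={
                    m: r[row.feature] for m, r in ranks.items() if row.feature in r
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stratified breakdowns


def stratified_eval(
    predictions: Sequence[int],
    gold: Corpus,
    stratifier: str,
) -> dict[object, EvalResult]:
    """Per-stratum evaluation: ``ne_length`` (span token count) or
    ``semantic_group``.  Strata without gold NEs do not appear."""
    if stratifier not in ("ne_length", "semantic_group"):
        raise ValueError("stratifier must be 'ne_length' or 'semantic_group'")
    if len(predictions) != len(gold.entities):
        raise ValueError("predictions and gold must be aligned one-to-one")

    def key(ne: NamedEntity) -> object:
        return ne.length if stratifier == "ne_length" else ne.semantic_group

    strata: dict[object, tuple[list[int], list[int], list[str]]] = {}
    for pred, ne in zip(predictions, gold.entities):
        preds, golds, docs = strata.setdefault(key(ne), ([], [], []))
        preds.append(pred)
        golds.append(ne.polarity)  # type: ignore[arg-type]
        docs.append(gold.doc_of(ne))
    return {
        k: prf(preds, golds, doc_ids=docs) for k, (preds, golds, docs) in sorted(
            strata.items(), key=lambda kv: str(kv[0])
        )
    }
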