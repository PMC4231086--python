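"""Linear max-margin polarity classifier with optional FEDA domain
adaptation and χ² feature filtering.

The classifier is a linear-kernel SVM (liblinear, via scikit-learn's
``LinearSVC``) over sparse binary feature vectors.  One parameter — the
regularization constant C — is tuned by cross-validation with folds split
by document ID, so NEs from one document never straddle a fold boundary.

FEDA ("frustratingly easy domain adaptation") multiplies the feature space
into K+1 blocks for K domains: every feature of an instance from domain
*a* is logged twice, once in the shared general block and once in the
block for *a*.  At test time a known domain activates its block alongside
the general one; an unknown domain falls back to the general block alone.
The decision rule is sign(w·v + b), with a tie (score exactly 0) mapped to
+1 (not negated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from .corpus import NEGATED, NOT_NEGATED, Corpus, NamedEntity, Sentence
from .features import FeatureConfig, FeatureName, FeatureSpace, FeatureVector, assemble

#: Label of the shared FEDA block.
GENERAL_BLOCK = "*"


@dataclass(frozen=True)
class TrainConfig:
    regularization_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    cv_folds: int = 5
    seed: int = 0
    feda: bool = False
    domains: tuple[str, ...] = ()
    class_weight: Optional[str] = None  # passed through to liblinear, e.g. "balanced"
    tol: float = 1e-4
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not self.regularization_grid or any(c <= 0 for c in self.regularization_grid):
            raise ValueError("regularization grid must be non-empty and positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.feda and not self.domains:
            raise ValueError("FEDA training requires an ordered list of domains")


@dataclass(frozen=True)
class TrainingInstance:
    vector: FeatureVector
    label: int
    domain: str = ""
    doc_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in (NEGATED, NOT_NEGATED):
            raise ValueError(f"label must be -1 or +1, got {self.label}")


def feda_augment(
    vector: FeatureVector, domain: str, domains: Sequence[str]
) -> frozenset:
    """Augmented vector: every feature appears exactly twice — once tagged
    with the general block, once with the instance's own domain block."""
    if domain not in domains:
        raise ValueError(f"unknown domain {domain!r}; known domains: {list(domains)}")
    return frozenset(
        {(GENERAL_BLOCK, f) for f in vector} | {(domain, f) for f in vector}
    )


class FedaSpace:
    """Block feature space for FEDA: block 0 is the general block, blocks
    1..K follow the domain order; the column of (block b, feature f) is
    ``b * len(base) + base.column(f)``."""

    def __init__(self, base: FeatureSpace, domains: Sequence[str]):
        self.base = base
        self.domains = tuple(domains)

    @property
    def n_blocks(self) -> int:
        return len(self.domains) + 1

    def __len__(self) -> int:
        return self.n_blocks * len(self.base)

    def block_index(self, block: str) -> Optional[int]:
        if block == GENERAL_BLOCK:
            return 0
        try:
            return self.domains.index(block) + 1
        except ValueError:
            return None

    def column(self, block: str, name: FeatureName) -> Optional[int]:
        b = self.block_index(block)
        c = self.base.column(name)
        if b is None or c is None:
            return None
        return b * len(self.base) + c

    def columns_of(self, vector: FeatureVector, domain: Optional[str]) -> list[int]:
        """Columns activated by a raw vector for a (possibly unknown)
        test-time domain: general block always; domain block if known."""
        blocks = [GENERAL_BLOCK]
        if domain is not None and self.block_index(domain) is not None:
            blocks.append(domain)
        out = []
        for blk in blocks:
            for f in vector:
                col = self.column(blk, f)
                if col is not None:
                    out.append(col)
        return out


@dataclass
class PolarityModel:
    weights: np.ndarray
    bias: float
    space: FeatureSpace
    feda: bool = False
    domains: tuple[str, ...] = ()
    best_c: float = 1.0
    config: Optional[TrainConfig] = None

    def _feda_space(self) -> FedaSpace:
        return FedaSpace(self.space, self.domains)

    def score(self, vector: FeatureVector, domain: Optional[str] = None) -> float:
        """Raw decision value w·v + b for one (un-augmented) vector."""
        if self.feda:
            cols = self._feda_space().columns_of(vector, domain)
        else:
            cols = [c for c in (self.space.column(f) for f in vector) if c is not None]
        return float(sum(self.weights[c] for c in cols) + self.bias)

    def predict_vector(self, vector: FeatureVector, domain: Optional[str] = None) -> int:
        s = self.score(vector, domain)
        return NEGATED if s < 0 else NOT_NEGATED

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "clinneg-model",
                    "version": 1,
                    "weights": self.weights.tolist(),
                    "bias": self.bias,
                    "space": self.space.to_dict(),
                    "feda": self.feda,
                    "domains": list(self.domains),
                    "best_c": self.best_c,
                },
            ),
            encoding="utf-8",
        )

    @staticmethod
    def load(path: str | Path) -> "PolarityModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        if d.get("format") != "clinneg-model":
            raise ValueError(f"{path}: not a clinneg model file")
        return PolarityModel(
            weights=np.asarray(d["weights"], dtype=np.float64),
            bias=float(d["bias"]),
            space=FeatureSpace.from_dict(d["space"]),
            feda=bool(d["feda"]),
            domains=tuple(d["domains"]),
            best_c=float(d["best_c"]),
        )


def _f1_negated(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == NEGATED) & (y_pred == NEGATED)))
    fp = int(np.sum((y_true != NEGATED) & (y_pred == NEGATED)))
    fn = int(np.sum((y_true == NEGATED) & (y_pred != NEGATED)))
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def _design_matrix(
    instances: Sequence[TrainingInstance], space: FeatureSpace, config: TrainConfig
) -> sparse.csr_matrix:
    if config.feda:
        fs = FedaSpace(space, config.domains)
        rows, cols = [], []
        for i, inst in enumerate(instances):
            for blk in (GENERAL_BLOCK, inst.domain):
                for f in inst.vector:
                    c = fs.column(blk, f)
                    if c is not None:
                        rows.append(i)
                        cols.append(c)
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(instances), len(fs))
        )
    return space.transform([inst.vector for inst in instances])


def _fit_svc(X: sparse.csr_matrix, y: np.ndarray, c: float, config: TrainConfig) -> LinearSVC:
    clf = LinearSVC(
        C=c,
        tol=config.tol,
        max_iter=config.max_iter,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    clf.fit(X, y)
    return clf


def train(instances: Sequence[TrainingInstance], config: TrainConfig) -> PolarityModel:
    """Train a polarity model; the regularization constant is the grid
    value maximizing mean cross-validated F1 of the negated class, with
    folds grouped by doc_id (ties prefer the smallest C).  Deterministic
    given the seed."""
    labels = {inst.label for inst in instances}
    if labels != {NEGATED, NOT_NEGATED}:
        raise ValueError("training needs at least one instance of each class")
    if config.feda:
        unknown = {inst.domain for inst in instances} - set(config.domains)
        if unknown:
            raise ValueError(f"instances from domains not in config: {sorted(unknown)}")
    space = FeatureSpace.from_vectors([inst.vector for inst in instances])
    if len(space) == 0:
        raise ValueError("empty feature space: no instance has any feature")
    X = _design_matrix(instances, space, config)
    y = np.array([inst.label for inst in instances])

    grid = tuple(sorted(config.regularization_grid))
    if len(grid) == 1:
        best_c = grid[0]
    else:
        doc_ids = sorted({inst.doc_id for inst in instances})
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(doc_ids))
        n_folds = min(config.cv_folds, len(doc_ids))
        fold_of_doc = {doc_ids[j]: i % n_folds for i, j in enumerate(order)}
        fold = np.array([fold_of_doc[inst.doc_id] for inst in instances])
        best_c, best_score = grid[0], -1.0
        for c in grid:
            scores = []
            for k in range(n_folds):
                tr, va = fold != k, fold == k
                if len(set(y[tr])) < 2 or not va.any():
                    continue
                clf = _fit_svc(X[tr], y[tr], c, config)
                scores.append(_f1_negated(y[va], np.asarray(clf.predict(X[va]))))
            mean = float(np.mean(scores)) if scores else 0.0
            if mean > best_score:
                best_c, best_score = c, mean

    clf = _fit_svc(X, y, best_c, config)
    # liblinear orders classes as [-1, +1]: positive decision values mean +1,
    # which matches the sign(w·v+b) -> polarity convention directly.
    assert list(clf.classes_) == [NEGATED, NOT_NEGATED]
    return PolarityModel(
        weights=clf.coef_.ravel().astype(np.float64),
        bias=float(clf.intercept_[0]),
        space=space,
        feda=config.feda,
        domains=config.domains,
        best_c=best_c,
        config=config,
    )


def predict(
    model: PolarityModel,
    sentence: Sentence,
    ne: NamedEntity,
    feature_config: FeatureConfig,
    test_domain: Optional[str] = None,
) -> int:
    """Polarity of one NE under a trained model.

    For a FEDA model the test domain (if given and seen in training)
    activates its block in addition to the general block; otherwise only
    the general block is populated.
    """
    return model.predict_vector(assemble(sentence, ne, feature_config), test_domain)


def chi2_filter(instances: Sequence[TrainingInstance], min_chi2: float) -> FeatureSpace:
    """Feature space retaining exactly the features whose χ² statistic
    (negated × feature-present 2×2 table) is at least ``min_chi2``."""
    from .evaluation import chi2_rank

    rows = chi2_rank(instances)
    kept = [r.feature for r in rows if r.chi2 >= min_chi2]
    return FeatureSpace.from_vectors([frozenset(kept)])


# ---------------------------------------------------------------------------
# Corpus-level pipeline helpers


def make_instances(corpus: Corpus, feature_config: FeatureConfig) -> list[TrainingInstance]:
    """Feature-extract every gold-labelled NE of a corpus."""
    out = []
    for ne in corpus.entities:
        if ne.polarity is None:
            raise ValueError("make_instances requires gold polarity on every NE")
        sent = corpus.sentence_of(ne)
        out.append(
            TrainingInstance(
                vector=assemble(sent, ne, feature_config),
                label=ne.polarity,
                domain=corpus.domain,
                doc_id=sent.doc_id,
            )
        )
    return out


def predict_corpus(
    model: PolarityModel,
    corpus: Corpus,
    feature_config: FeatureConfig,
    test_domain: Optional[str] = None,
) -> list[int]:
    """Predicted polarity for every NE of a corpus, in corpus order."""
    domain = test_domain if test_domain is not None else corpus.domain
    return [
        predict(model, corpus.sentence_of(ne), ne, feature_config, domain)
        for ne in corpus.entities
    ]
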