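"""Synthetic multi-domain corpus generator.

Real multi-corpus negation data is mostly restricted by data-use
agreements, so the toolkit ships a generator whose controllable statistics
emulate the salient cross-corpus phenomena: negation prevalence in the
4%–21% range, domain-specific cue vocabularies, NE length and
semantic-group mixes, morphologically negated single tokens with no
external cue ("afebrile"), pseudo-negation lookalikes, and
annotation-guideline conflicts where the same surface construction is
negated in one domain and affirmed in another.

Sentences are built from templates with slots (optional cue phrase,
optional termination clause, NE, distractors), so every sentence carries a
*gold* dependency tree and constituency tree derived from its template —
no parser is run, removing parser error as a confound.  Gold polarity
follows the generative rule (cue in scope ⇒ negated; morphologically
negated token ⇒ negated; else affirmed) and is therefore recoverable in
principle from the features; :func:`generative_oracle` packages that rule
for sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import (
    NEGATED,
    NOT_NEGATED,
    ROOT,
    ConstituencyNode,
    Corpus,
    DependencyEdge,
    NamedEntity,
    Sentence,
    Token,
)
from .negex import RuleConfig, TriggerLexicon, negex_classify

CUE_KINDS = ("det", "verb", "adj", "prep", "post", "postverb")


@dataclass(frozen=True)
class CueSpec:
    """One negation cue of a domain: the phrase, its normalized category,
    the syntactic kind deciding which sentence template realizes it, and a
    sampling weight."""

    phrase: str
    category: str
    kind: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in CUE_KINDS:
            raise ValueError(f"cue kind must be one of {CUE_KINDS}, got {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("cue weight must be positive")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(self.phrase.lower().split())


def _check_dist(name: str, probs: Sequence[float]) -> None:
    if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability distribution summing to 1")


@dataclass(frozen=True)
class DomainSpec:
    """Generative parameters for one synthetic domain."""

    name: str
    prevalence: float
    cues: tuple[CueSpec, ...]
    vocab: tuple[str, ...]
    adjectives: tuple[str, ...] = ("acute", "mild", "chronic", "focal")
    subjects: tuple[str, ...] = ("patient", "pt")
    #: distribution over NE lengths 1..5 (tokens)
    ne_length_dist: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    group_mix: tuple[tuple[str, float], ...] = (
        ("DiseaseDisorder", 0.5),
        ("SignSymptom", 0.5),
    )
    pseudo_cue_rate: float = 0.08
    #: three-token "X Y in" lookalikes, e.g. "no increase in <NE>"
    pseudo_phrases: tuple[str, ...] = ("no increase in", "no change in")
    termination_rate: float = 0.08
    morph_neg_rate: float = 0.0
    morph_neg_vocab: tuple[str, ...] = ("afebrile", "anicteric", "nontender")
    #: a verb realized post-NE in *affirmed* sentences ("the <NE> has
    #: resolved") — the guideline-conflict device: give another domain the
    #: same verb as a negating "postverb" cue.
    affirmed_postverb: Optional[str] = None
    affirmed_postverb_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 <= self.morph_neg_rate <= 1.0):
            raise ValueError("morph_neg_rate must be in [0, 1]")
        if len(self.ne_length_dist) != 5:
            raise ValueError("ne_length_dist must give probabilities for lengths 1..5")
        _check_dist("ne_length_dist", self.ne_length_dist)
        _check_dist("group_mix", [p for _, p in self.group_mix])
        if self.prevalence > 0 and self.morph_neg_rate < 1 and not self.cues:
            raise ValueError("a domain with negations needs at least one cue")
        cue_words = {w for c in self.cues for w in c.tokens}
        clash = cue_words & (set(self.vocab) | set(self.adjectives))
        if clash:
            raise ValueError(f"cue words also in vocab/adjectives: {sorted(clash)}")
        if self.affirmed_postverb_rate > 0 and self.affirmed_postverb is None:
            raise ValueError("affirmed_postverb_rate needs affirmed_postverb")


@dataclass(frozen=True)
class GeneratorConfig:
    domains: tuple[DomainSpec, ...]
    n_documents: int = 50
    sentences_per_document: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError("at least one domain is required")
        if self.n_documents < 0 or self.sentences_per_document < 1:
            raise ValueError("invalid document/sentence counts")


# ---------------------------------------------------------------------------
# Sentence templates.  Each builder returns (Sentence, ne_span); dependency
# trees and bracketed parses are constructed jointly with the tokens.


def _ne_node(ne_words: Sequence[str], tag: str = "NN") -> ConstituencyNode:
    return ConstituencyNode(
        "NML", children=[ConstituencyNode(tag, word=w) for w in ne_words]
    )


def _mk_sentence(
    words_pos: Sequence[tuple[str, str]],
    edges: Sequence[tuple[int, int, str]],
    parse: ConstituencyNode,
    doc_id: str,
) -> Sentence:
    return Sentence(
        tokens=[Token(w, i, p) for i, (w, p) in enumerate(words_pos)],
        dependencies=[DependencyEdge(h, d, r) for h, d, r in edges],
        parse=parse,
        doc_id=doc_id,
    )


def _object_template(
    subject: str,
    verb: str,
    cue_tokens: Sequence[str],
    cue_rel: str,
    fillers: Sequence[str],
    ne_words: Sequence[str],
    doc_id: str,
) -> tuple[Sentence, tuple[int, int]]:
    """``the <subject> <verb> [cue] [fillers] <NE> .`` — covers the plain
    affirmed template (no cue), the determiner cue ("no"), and the verb
    cue ("denies", where the cue *is* the verb)."""
    words: list[tuple[str, str]] = [("the", "DT"), (subject, "NN"), (verb, "VBZ")]
    cue_start = len(words)
    words += [(c, "DT" if i == 0 else "IN") for i, c in enumerate(cue_tokens)]
    filler_start = len(words)
    words += [(f, "JJ") for f in fillers]
    ne_start = len(words)
    words += [(w, "NN") for w in ne_words]
    ne_end = len(words)
    words.append((".", "."))
    head = ne_end - 1
    edges = [(1, 0, "det"), (2, 1, "nsubj"), (ROOT, 2, "root"), (2, len(words) - 1, "punct")]
    for i, _ in enumerate(cue_tokens):
        if i == 0:
            edges.append((head, cue_start, cue_rel))
        else:
            edges.append((cue_start, cue_start + i, "fixed"))
    for i, _ in enumerate(fillers):
        edges.append((head, filler_start + i, "amod"))
    for i in range(ne_start, ne_end - 1):
        edges.append((head, i, "nn"))
    edges.append((2, head, "dobj"))
    obj_children: list[ConstituencyNode] = []
    for i, c in enumerate(cue_tokens):
        obj_children.append(ConstituencyNode("DT" if i == 0 else "IN", word=c))
    obj_children += [ConstituencyNode("JJ", word=f) for f in fillers]
    obj_children.append(_ne_node(ne_words))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode(
                "NP",
                children=[ConstituencyNode("DT", word="the"), ConstituencyNode("NN", word=subject)],
            ),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode("VBZ", word=verb),
                    ConstituencyNode("NP", children=obj_children),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (ne_start, ne_end)


def _adj_template(
    subject: str, cue_tokens: Sequence[str], ne_words: Sequence[str], doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``the <subject> was negative for <NE> .`` (two-token adjective cue)."""
    adj, prep = cue_tokens[0], cue_tokens[1]
    words = [("the", "DT"), (subject, "NN"), ("was", "VBD"), (adj, "JJ"), (prep, "IN")]
    ne_start = len(words)
    words += [(w, "NN") for w in ne_words]
    ne_end = len(words)
    words.append((".", "."))
    head = ne_end - 1
    edges = [
        (1, 0, "det"),
        (2, 1, "nsubj"),
        (ROOT, 2, "root"),
        (2, 3, "acomp"),
        (3, 4, "prep"),
        (3, head, f"prep_{prep}"),
        (2, len(words) - 1, "punct"),
    ]
    for i in range(ne_start, ne_end - 1):
        edges.append((head, i, "nn"))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode(
                "NP",
                children=[ConstituencyNode("DT", word="the"), ConstituencyNode("NN", word=subject)],
            ),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode("VBD", word="was"),
                    ConstituencyNode(
                        "ADJP",
                        children=[
                            ConstituencyNode("JJ", word=adj),
                            ConstituencyNode(
                                "PP",
                                children=[
                                    ConstituencyNode("IN", word=prep),
                                    ConstituencyNode("NP", children=[_ne_node(ne_words)]),
                                ],
                            ),
                        ],
                    ),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (ne_start, ne_end)


def _prep_template(
    cue_word: str, ne_words: Sequence[str], doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``the procedure was completed without <NE> .``"""
    words = [("the", "DT"), ("procedure", "NN"), ("was", "VBD"), ("completed", "VBN"), (cue_word, "IN")]
    ne_start = len(words)
    words += [(w, "NN") for w in ne_words]
    ne_end = len(words)
    words.append((".", "."))
    head = ne_end - 1
    edges = [
        (1, 0, "det"),
        (3, 1, "nsubjpass"),
        (3, 2, "auxpass"),
        (ROOT, 3, "root"),
        (3, 4, "prep"),
        (4, head, "pobj"),
        (3, len(words) - 1, "punct"),
    ]
    for i in range(ne_start, ne_end - 1):
        edges.append((head, i, "nn"))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode(
                "NP",
                children=[ConstituencyNode("DT", word="the"), ConstituencyNode("NN", word="procedure")],
            ),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode("VBD", word="was"),
                    ConstituencyNode("VBN", word="completed"),
                    ConstituencyNode(
                        "PP",
                        children=[
                            ConstituencyNode("IN", word=cue_word),
                            ConstituencyNode("NP", children=[_ne_node(ne_words)]),
                        ],
                    ),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (ne_start, ne_end)


def _post_template(
    cue_tokens: Sequence[str], ne_words: Sequence[str], doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``<NE> was ruled out .`` (three-token post-NE cue)."""
    aux, verb, prt = cue_tokens
    words = [(w, "NN") for w in ne_words]
    ne_end = len(words)
    head = ne_end - 1
    words += [(aux, "VBD"), (verb, "VBN"), (prt, "RP"), (".", ".")]
    v = ne_end + 1
    edges = [(v, head, "nsubjpass"), (v, ne_end, "auxpass"), (ROOT, v, "root"), (v, v + 1, "prt"), (v, len(words) - 1, "punct")]
    for i in range(0, ne_end - 1):
        edges.append((head, i, "nn"))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode("NP", children=[_ne_node(ne_words)]),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode("VBD", word=aux),
                    ConstituencyNode("VBN", word=verb),
                    ConstituencyNode("RP", word=prt),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (0, ne_end)


def _postverb_template(
    verb: str, ne_words: Sequence[str], doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``the <NE> has <verb> .`` — the guideline-conflict construction."""
    words = [("the", "DT")]
    ne_start = 1
    words += [(w, "NN") for w in ne_words]
    ne_end = len(words)
    head = ne_end - 1
    words += [("has", "VBZ"), (verb, "VBN"), (".", ".")]
    v = ne_end + 1
    edges = [(head, 0, "det"), (v, head, "nsubj"), (v, ne_end, "aux"), (ROOT, v, "root"), (v, len(words) - 1, "punct")]
    for i in range(ne_start, ne_end - 1):
        edges.append((head, i, "nn"))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode("NP", children=[ConstituencyNode("DT", word="the"), _ne_node(ne_words)]),
            ConstituencyNode(
                "VP",
                children=[ConstituencyNode("VBZ", word="has"), ConstituencyNode("VBN", word=verb)],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (ne_start, ne_end)


def _pseudo_template(
    subject: str, pseudo_tokens: Sequence[str], ne_words: Sequence[str], doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``the <subject> has no increase in <NE> .`` — the trigger-lookalike
    does not negate the NE."""
    p0, p1, p2 = pseudo_tokens
    words = [("the", "DT"), (subject, "NN"), ("has", "VBZ"), (p0, "DT"), (p1, "NN"), (p2, "IN")]
    ne_start = len(words)
    words += [(w, "NN") for w in ne_words]
    ne_end = len(words)
    words.append((".", "."))
    head = ne_end - 1
    edges = [
        (1, 0, "det"),
        (2, 1, "nsubj"),
        (ROOT, 2, "root"),
        (4, 3, "neg"),
        (2, 4, "dobj"),
        (4, 5, "prep"),
        (4, head, f"prep_{p2}"),
        (2, len(words) - 1, "punct"),
    ]
    for i in range(ne_start, ne_end - 1):
        edges.append((head, i, "nn"))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode(
                "NP",
                children=[ConstituencyNode("DT", word="the"), ConstituencyNode("NN", word=subject)],
            ),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode("VBZ", word="has"),
                    ConstituencyNode(
                        "NP",
                        children=[
                            ConstituencyNode(
                                "NP",
                                children=[
                                    ConstituencyNode("DT", word=p0),
                                    ConstituencyNode("NN", word=p1),
                                ],
                            ),
                            ConstituencyNode(
                                "PP",
                                children=[
                                    ConstituencyNode("IN", word=p2),
                                    ConstituencyNode("NP", children=[_ne_node(ne_words)]),
                                ],
                            ),
                        ],
                    ),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (ne_start, ne_end)


def _termination_template(
    subject: str, distractor: str, ne_words: Sequence[str], doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``the <subject> denies <distractor> but reports <NE> .`` — the
    trigger's scope ends at the termination word, so the NE is affirmed."""
    words = [("the", "DT"), (subject, "NN"), ("denies", "VBZ"), (distractor, "NN"), ("but", "CC"), ("reports", "VBZ")]
    ne_start = len(words)
    words += [(w, "NN") for w in ne_words]
    ne_end = len(words)
    words.append((".", "."))
    head = ne_end - 1
    edges = [
        (1, 0, "det"),
        (2, 1, "nsubj"),
        (ROOT, 2, "root"),
        (2, 3, "dobj"),
        (2, 4, "cc"),
        (2, 5, "conj"),
        (5, head, "dobj"),
        (2, len(words) - 1, "punct"),
    ]
    for i in range(ne_start, ne_end - 1):
        edges.append((head, i, "nn"))
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode(
                "NP",
                children=[ConstituencyNode("DT", word="the"), ConstituencyNode("NN", word=subject)],
            ),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode(
                        "VP",
                        children=[
                            ConstituencyNode("VBZ", word="denies"),
                            ConstituencyNode("NP", children=[ConstituencyNode("NN", word=distractor)]),
                        ],
                    ),
                    ConstituencyNode("CC", word="but"),
                    ConstituencyNode(
                        "VP",
                        children=[
                            ConstituencyNode("VBZ", word="reports"),
                            ConstituencyNode("NP", children=[_ne_node(ne_words)]),
                        ],
                    ),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (ne_start, ne_end)


def _morph_template(
    subject: str, word: str, doc_id: str
) -> tuple[Sentence, tuple[int, int]]:
    """``the <subject> is afebrile .`` — inherent (morphological) negation,
    no external cue."""
    words = [("the", "DT"), (subject, "NN"), ("is", "VBZ"), (word, "JJ"), (".", ".")]
    edges = [(1, 0, "det"), (2, 1, "nsubj"), (ROOT, 2, "root"), (2, 3, "acomp"), (2, 4, "punct")]
    parse = ConstituencyNode(
        "S",
        children=[
            ConstituencyNode(
                "NP",
                children=[ConstituencyNode("DT", word="the"), ConstituencyNode("NN", word=subject)],
            ),
            ConstituencyNode(
                "VP",
                children=[
                    ConstituencyNode("VBZ", word="is"),
                    ConstituencyNode("ADJP", children=[_ne_node([word], tag="JJ")]),
                ],
            ),
            ConstituencyNode(".", word="."),
        ],
    )
    return _mk_sentence(words, edges, parse, doc_id), (3, 4)


# ---------------------------------------------------------------------------
# Generation


def _sample_ne(spec: DomainSpec, rng: np.random.Generator) -> list[str]:
    length = int(rng.choice(5, p=spec.ne_length_dist)) + 1
    replace_words = length > len(spec.vocab)
    return [str(w) for w in rng.choice(spec.vocab, size=length, replace=replace_words)]


def _sample_group(spec: DomainSpec, rng: np.random.Generator) -> str:
    groups = [g for g, _ in spec.group_mix]
    probs = [p for _, p in spec.group_mix]
    return str(groups[int(rng.choice(len(groups), p=probs))])


def _build_sentence(
    spec: DomainSpec, rng: np.random.Generator, doc_id: str
) -> tuple[Sentence, tuple[int, int], int]:
    negated = rng.random() < spec.prevalence
    subject = str(rng.choice(spec.subjects))
    if negated:
        if spec.morph_neg_rate > 0 and rng.random() < spec.morph_neg_rate:
            word = str(rng.choice(spec.morph_neg_vocab))
            sent, span = _morph_template(subject, word, doc_id)
            return sent, span, NEGATED
        weights = np.array([c.weight for c in spec.cues])
        cue = spec.cues[int(rng.choice(len(spec.cues), p=weights / weights.sum()))]
        ne_words = _sample_ne(spec, rng)
        n_fillers = int(rng.integers(0, 3))
        fillers = [str(a) for a in rng.choice(spec.adjectives, size=n_fillers, replace=False)] if n_fillers else []
        if cue.kind == "det":
            sent, span = _object_template(subject, "has", cue.tokens, "neg", fillers, ne_words, doc_id)
        elif cue.kind == "verb":
            sent, span = _object_template(subject, cue.tokens[0], (), "neg", fillers, ne_words, doc_id)
        elif cue.kind == "adj":
            sent, span = _adj_template(subject, cue.tokens, ne_words, doc_id)
        elif cue.kind == "prep":
            sent, span = _prep_template(cue.tokens[0], ne_words, doc_id)
        elif cue.kind == "post":
            sent, span = _post_template(cue.tokens, ne_words, doc_id)
        else:  # postverb
            sent, span = _postverb_template(cue.tokens[0], ne_words, doc_id)
        return sent, span, NEGATED
    # affirmed
    ne_words = _sample_ne(spec, rng)
    u = rng.random()
    if u < spec.pseudo_cue_rate:
        pseudo = tuple(str(rng.choice(spec.pseudo_phrases)).split())
        sent, span = _pseudo_template(subject, pseudo, ne_words, doc_id)
    elif u < spec.pseudo_cue_rate + spec.termination_rate:
        distractor = str(rng.choice(spec.vocab))
        sent, span = _termination_template(subject, distractor, ne_words, doc_id)
    elif u < spec.pseudo_cue_rate + spec.termination_rate + spec.affirmed_postverb_rate:
        sent, span = _postverb_template(spec.affirmed_postverb, ne_words, doc_id)  # type: ignore[arg-type]
    else:
        n_fillers = int(rng.integers(0, 3))
        fillers = [str(a) for a in rng.choice(spec.adjectives, size=n_fillers, replace=False)] if n_fillers else []
        sent, span = _object_template(subject, "has", (), "neg", fillers, ne_words, doc_id)
    return sent, span, NOT_NEGATED


def generate(config: GeneratorConfig) -> dict[str, Corpus]:
    """Generate one gold-annotated corpus per domain.

    Deterministic: per-domain random streams are derived from the master
    seed and the domain's position, so the same config yields
    byte-identical standoff files.
    """
    out: dict[str, Corpus] = {}
    for di, spec in enumerate(config.domains):
        rng = np.random.default_rng((config.seed, di))
        sentences: list[Sentence] = []
        entities: list[NamedEntity] = []
        for d in range(config.n_documents):
            doc_id = f"{spec.name}-doc-{d:04d}"
            for _ in range(config.sentences_per_document):
                sent, span, polarity = _build_sentence(spec, rng, doc_id)
                sentences.append(sent)
                entities.append(
                    NamedEntity(
                        sentence_ref=len(sentences) - 1,
                        span=span,
                        semantic_group=_sample_group(spec, rng),
                        polarity=polarity,
                    )
                )
        out[spec.name] = Corpus(
            name=spec.name,
            domain=spec.name,
            sentences=sentences,
            entities=entities,
            meta={"generator_seed": config.seed, "prevalence": spec.prevalence},
        )
    return out


def generative_oracle(spec: DomainSpec):
    """The rule that assigned gold polarity, as a classifier.

    Applied to this domain's generated text it reproduces the gold labels
    exactly (a sanity ceiling for the toolkit's learners).
    """
    pre, post = [], []
    for c in spec.cues:
        if c.kind in ("det", "verb", "adj", "prep"):
            pre.append(c.phrase)
        elif c.kind == "post":
            post.append(c.phrase)
        else:  # postverb
            post.append(c.tokens[0])
    lexicon = TriggerLexicon.from_phrases(
        pre=pre, post=post, pseudo=spec.pseudo_phrases, termination=["but"]
    )
    config = RuleConfig(max_scope=5)
    morph = set(spec.morph_neg_vocab)

    def classify(sentence: Sentence, ne: NamedEntity) -> int:
        ne_tokens = {t.text.lower() for t in sentence.tokens[ne.span[0] : ne.span[1]]}
        if ne_tokens & morph:
            return NEGATED
        return negex_classify(sentence, ne, lexicon, config)

    return classify


# ---------------------------------------------------------------------------
# Preset suites

_SHARED_ADJ = ("acute", "mild", "chronic", "focal", "diffuse", "severe")

_RAD_VOCAB = (
    "stenosis", "plaque", "occlusion", "lesion", "mass", "calcification",
    "aneurysm", "thrombus", "ulceration", "narrowing", "dissection", "embolus",
)
_DISCHARGE_VOCAB = (
    "pain", "fever", "cough", "nausea", "vomiting", "edema", "dyspnea",
    "chills", "bleeding", "infection", "rash", "diarrhea", "headache",
    "wheezing", "distress", "tenderness",
)
_MIXED_VOCAB = (
    "fracture", "tumor", "cyst", "polyp", "inflammation", "effusion",
    "abscess", "nodule", "hernia", "obstruction", "swelling", "erythema",
)
_GENERIC_VOCAB = (
    "pneumonia", "failure", "murmur", "ischemia", "hypertension", "anemia",
    "sepsis", "hematoma", "atelectasis", "consolidation", "emphysema", "cardiomegaly",
)


def preset_suite(name: str) -> GeneratorConfig:
    """Named generator configurations.

    * ``paper_like`` — four domains whose negation prevalences mirror the
      published train-side corpus statistics (8.7%, 21.2%, 7.2%, 20.7%),
      with an i2b2-style domain where ≈8% of negated NEs are
      morphologically negated single tokens.
    * ``conflict`` — two domains where the same construction
      ("the <NE> has resolved") is annotated negated in one and affirmed
      in the other: the stress test for domain adaptation.
    * ``shared_core`` — two domains sharing the high-value core cues but
      with domain-specific cue vocabulary beyond the core.
    """
    no, denies, without = (
        CueSpec("no", "no", "det", 3.0),
        CueSpec("denies", "deny", "verb", 1.5),
        CueSpec("without", "without", "prep", 1.0),
    )
    if name == "paper_like":
        domains = (
            DomainSpec(
                name="sharp_like",
                prevalence=0.087,
                cues=(no, without, CueSpec("negative for", "negative", "adj", 1.0)),
                vocab=_RAD_VOCAB,
                adjectives=_SHARED_ADJ,
                group_mix=(
                    ("AnatomicalSite", 0.204),
                    ("DiseaseDisorder", 0.265),
                    ("Medication", 0.147),
                    ("Procedure", 0.196),
                    ("SignSymptom", 0.163),
                    ("Entity", 0.004),
                    ("Event", 0.021),
                ),
            ),
            DomainSpec(
                name="i2b2_like",
                prevalence=0.212,
                cues=(no, denies, without, CueSpec("was ruled out", "ruled_out", "post", 0.8)),
                vocab=_DISCHARGE_VOCAB,
                adjectives=_SHARED_ADJ,
                group_mix=(("DiseaseDisorder", 0.6), ("SignSymptom", 0.4)),
                morph_neg_rate=0.08,
            ),
            DomainSpec(
                name="mipacq_like",
                prevalence=0.072,
                cues=(no, denies, CueSpec("absence of", "absent", "det", 0.8)),
                vocab=_MIXED_VOCAB,
                adjectives=_SHARED_ADJ,
                group_mix=(
                    ("AnatomicalSite", 0.399),
                    ("DiseaseDisorder", 0.275),
                    ("Lab", 0.019),
                    ("Medication", 0.030),
                    ("Procedure", 0.166),
                    ("SignSymptom", 0.057),
                    ("Entity", 0.030),
                    ("Event", 0.024),
                ),
            ),
            DomainSpec(
                name="negexts_like",
                prevalence=0.207,
                cues=(no, denies, CueSpec("negative for", "negative", "adj", 1.0),
                      CueSpec("was ruled out", "ruled_out", "post", 0.8)),
                vocab=_GENERIC_VOCAB,
                adjectives=_SHARED_ADJ,
                group_mix=(("Unknown", 1.0),),
            ),
        )
        return GeneratorConfig(domains=domains, n_documents=30, sentences_per_document=30)
    if name == "conflict":
        domains = (
            DomainSpec(
                name="alpha",
                prevalence=0.2,
                cues=(no, denies, CueSpec("resolved", "resolved", "postverb", 2.0)),
                vocab=_DISCHARGE_VOCAB,
                adjectives=_SHARED_ADJ,
            ),
            DomainSpec(
                name="beta",
                prevalence=0.2,
                cues=(no, denies),
                vocab=_GENERIC_VOCAB,
                adjectives=_SHARED_ADJ,
                affirmed_postverb="resolved",
                affirmed_postverb_rate=0.35,
            ),
        )
        return GeneratorConfig(domains=domains, n_documents=50, sentences_per_document=40)
    if name == "shared_core":
        domains = (
            DomainSpec(
                name="source",
                prevalence=0.2,
                cues=(no, denies, without,
                      CueSpec("negative for", "negative", "adj", 1.0),
                      CueSpec("was ruled out", "ruled_out", "post", 0.8)),
                vocab=_RAD_VOCAB,
                adjectives=_SHARED_ADJ,
            ),
            DomainSpec(
                name="target",
                prevalence=0.2,
                cues=(no, denies, without,
                      CueSpec("absence of", "absent", "det", 1.0),
                      CueSpec("free of", "negative", "adj", 1.0)),
                vocab=_GENERIC_VOCAB,
                adjectives=_SHARED_ADJ,
            ),
        )
        return GeneratorConfig(domains=domains, n_documents=50, sentences_per_document=40)
    raise ValueError(
        f"unknown preset {name!r}; available presets: paper_like, conflict, shared_core"
    )
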