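"""Data model for annotated clinical corpora.

The unit of classification throughout the toolkit is one *named entity*
(NE): a token span inside a sentence carrying a coarse semantic group and a
gold or predicted *polarity* (−1 = negated, i.e. the condition is asserted
absent; +1 = not negated).  A :class:`Corpus` groups sentences into
documents (the exchangeable unit for significance testing) and carries one
domain label, because cross-corpus experiments treat each corpus as its own
domain.

Two concrete file formats are supported:

* the public NegEx Test Set tab-delimited dialect (one annotated concept
  phrase per sentence, ``Affirmed``/``Negated`` labels);
* a toolkit-defined standoff format — JSON lines, one document per line,
  carrying tokens, optional POS tags, dependency triples, Penn-bracketed
  constituency strings, and NEs by token offsets.  ``write`` then ``read``
  is the identity on the data model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

NEGATED = -1
NOT_NEGATED = +1

#: Coarse UMLS-style semantic groups used across the supported corpora.
SEMANTIC_GROUPS = (
    "AnatomicalSite",
    "DiseaseDisorder",
    "Lab",
    "Medication",
    "Procedure",
    "SignSymptom",
    "Entity",
    "Event",
    "Unknown",
)

#: Sentinel head index for the root of a dependency tree.
ROOT = -1


@dataclass(frozen=True)
class Token:
    text: str
    index: int
    pos: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("token text must be non-empty")
        if self.index < 0:
            raise ValueError("token index must be >= 0")


@dataclass(frozen=True)
class DependencyEdge:
    """One edge of a dependency tree: ``head -> dependent`` with a relation
    label.  ``head`` is a token index or :data:`ROOT`."""

    head: int
    dependent: int
    relation: str


@dataclass
class ConstituencyNode:
    """A node of a constituency parse.

    Internal nodes have ``children``; preterminals have a single ``word``.
    ``span`` is the half-open token range of the node's yield, assigned by
    :func:`assign_spans` (leaves are numbered left to right).
    """

    label: str
    children: list["ConstituencyNode"] = field(default_factory=list)
    word: Optional[str] = None
    span: Optional[tuple[int, int]] = None

    def is_leaf(self) -> bool:
        return self.word is not None

    def leaves(self) -> Iterator["ConstituencyNode"]:
        if self.is_leaf():
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def yield_words(self) -> list[str]:
        return [leaf.word for leaf in self.leaves()]  # type: ignore[misc]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConstituencyNode):
            return NotImplemented
        return (
            self.label == other.label
            and self.word == other.word
            and self.children == other.children
        )


def parse_penn(text: str) -> ConstituencyNode:
    """Parse a Penn-style bracketed string into a :class:`ConstituencyNode`.

    Handles the subset used by this toolkit: ``(LABEL child ...)`` with
    preterminals written ``(POS word)``.
    """
    tokens: list[str] = []
    for piece in text.replace("(", " ( ").replace(")", " ) ").split():
        tokens.append(piece)
    pos = 0

    def parse_node() -> ConstituencyNode:
        nonlocal pos
        if tokens[pos] != "(":
            raise ValueError(f"expected '(' at position {pos} in parse string")
        pos += 1
        label = tokens[pos]
        pos += 1
        children: list[ConstituencyNode] = []
        word: Optional[str] = None
        while tokens[pos] != ")":
            if tokens[pos] == "(":
                children.append(parse_node())
            else:
                if word is not None or children:
                    raise ValueError("mixed word/children in constituency node")
                word = tokens[pos]
                pos += 1
        pos += 1
        return ConstituencyNode(label=label, children=children, word=word)

    node = parse_node()
    if pos != len(tokens):
        raise ValueError("trailing material after constituency tree")
    assign_spans(node)
    return node


def to_penn(node: ConstituencyNode) -> str:
    if node.is_leaf():
        return f"({node.label} {node.word})"
    inner = " ".join(to_penn(c) for c in node.children)
    return f"({node.label} {inner})"


def assign_spans(node: ConstituencyNode, start: int = 0) -> int:
    """Assign half-open token spans bottom-up; returns the end index."""
    if node.is_leaf():
        node.span = (start, start + 1)
        return start + 1
    pos = start
    for c in node.children:
        pos = assign_spans(c, pos)
    node.span = (start, pos)
    return pos


@dataclass
class Sentence:
    tokens: list[Token]
    dependencies: Optional[list[DependencyEdge]] = None
    parse: Optional[ConstituencyNode] = None
    doc_id: str = ""

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise ValueError(
                    f"token indices must be contiguous from 0; saw {tok.index} at {i}"
                )
        if self.dependencies is not None:
            heads = {e.dependent for e in self.dependencies}
            if heads != set(range(len(self.tokens))):
                raise ValueError("dependency edges must cover every token exactly once")
        if self.parse is not None:
            if self.parse.yield_words() != [t.text for t in self.tokens]:
                raise ValueError("constituency yield does not match token sequence")
            assign_spans(self.parse)

    def __len__(self) -> int:
        return len(self.tokens)

    def words(self) -> list[str]:
        return [t.text for t in self.tokens]

    def head_of(self, index: int) -> Optional[tuple[int, str]]:
        """Return (head index, relation) for a token, or None without a parse."""
        if self.dependencies is None:
            return None
        for e in self.dependencies:
            if e.dependent == index:
                return e.head, e.relation
        return None


@dataclass
class NamedEntity:
    sentence_ref: int
    span: tuple[int, int]
    semantic_group: str = "Unknown"
    polarity: Optional[int] = None

    def __post_init__(self) -> None:
        start, end = self.span
        if not (0 <= start < end):
            raise ValueError(f"NE span must satisfy 0 <= start < end, got {self.span}")
        if self.semantic_group not in SEMANTIC_GROUPS:
            raise ValueError(f"unknown semantic group {self.semantic_group!r}")
        if self.polarity is not None and self.polarity not in (NEGATED, NOT_NEGATED):
            raise ValueError(f"polarity must be -1 or +1, got {self.polarity}")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class Corpus:
    name: str
    domain: str
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[NamedEntity] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.domain:
            raise ValueError("domain label must be non-empty")
        for ne in self.entities:
            self._check_entity(ne)

    def _check_entity(self, ne: NamedEntity) -> None:
        if not (0 <= ne.sentence_ref < len(self.sentences)):
            raise ValueError(f"NE references missing sentence {ne.sentence_ref}")
        sent = self.sentences[ne.sentence_ref]
        if ne.span[1] > len(sent):
            raise ValueError(
                f"NE span {ne.span} outside sentence {ne.sentence_ref} "
                f"(doc {sent.doc_id!r}, length {len(sent)})"
            )

    def sentence_of(self, ne: NamedEntity) -> Sentence:
        return self.sentences[ne.sentence_ref]

    def ne_text(self, ne: NamedEntity) -> str:
        sent = self.sentence_of(ne)
        return " ".join(t.text for t in sent.tokens[ne.span[0] : ne.span[1]])

    def documents(self) -> dict[str, list[int]]:
        """Map doc_id -> sentence indices, in corpus order."""
        docs: dict[str, list[int]] = {}
        for i, s in enumerate(self.sentences):
            docs.setdefault(s.doc_id, []).append(i)
        return docs

    def doc_of(self, ne: NamedEntity) -> str:
        return self.sentence_of(ne).doc_id

    def __len__(self) -> int:
        return len(self.entities)


@dataclass(frozen=True)
class CorpusStats:
    n_documents: int
    n_sentences: int
    n_entities: int
    n_negated: int

    @property
    def pct_negated(self) -> float:
        if self.n_entities == 0:
            return 0.0
        return 100.0 * self.n_negated / self.n_entities

    def __add__(self, other: "CorpusStats") -> "CorpusStats":
        return CorpusStats(
            self.n_documents + other.n_documents,
            self.n_sentences + other.n_sentences,
            self.n_entities + other.n_entities,
            self.n_negated + other.n_negated,
        )


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Descriptive statistics in the style of a corpus-characteristics table."""
    n_neg = sum(1 for ne in corpus.entities if ne.polarity == NEGATED)
    return CorpusStats(
        n_documents=len(corpus.documents()) if corpus.sentences else 0,
        n_sentences=len(corpus.sentences),
        n_entities=len(corpus.entities),
        n_negated=n_neg,
    )


# ---------------------------------------------------------------------------
# Tokenization for pre-simplified sentence text (NegEx Test Set dialect)

_TRAILING_PUNCT = ".,;:!?"


def simple_tokenize(text: str) -> list[str]:
    """Whitespace split, then separate trailing sentence punctuation.

    The NegEx Test Set distributes pre-simplified sentence text; window
    features need stable token counts, so this is deliberately minimal.
    """
    out: list[str] = []
    for raw in text.split():
        tail: list[str] = []
        while len(raw) > 1 and raw[-1] in _TRAILING_PUNCT:
            tail.append(raw[-1])
            raw = raw[:-1]
        out.append(raw)
        out.extend(reversed(tail))
    return out


class RecordError(ValueError):
    """A malformed record in a corpus file, carrying its line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _find_sublist(haystack: Sequence[str], needle: Sequence[str]) -> Optional[int]:
    n = len(needle)
    for i in range(len(haystack) - n + 1):
        if list(haystack[i : i + n]) == list(needle):
            return i
    return None


def read_negex_testset(
    path: str | Path,
    *,
    columns: Optional[tuple[int, int, int]] = None,
    pseudo_doc_size: int = 20,
    domain: str = "negexts",
    name: Optional[str] = None,
) -> Corpus:
    """Read a tab-delimited annotated test set (NegEx Test Set dialect).

    Each record holds a sentence, one annotated concept phrase, and a gold
    label mapping ``Affirmed`` -> +1 and ``Negated`` -> −1.  ``columns``
    gives 0-based (sentence, concept, label) field positions; by default a
    3-field record is read as (sentence, concept, label) and a 4-field
    record as (id, sentence, concept, label).

    The distribution carries no document IDs, but document-aggregated
    significance tests need an exchangeable unit, so consecutive records
    are grouped into pseudo-documents of ``pseudo_doc_size`` records; the
    choice is recorded in ``corpus.meta``.

    Records whose concept phrase cannot be located in the tokenized
    sentence (case-insensitive, first occurrence) are excluded with a
    logged warning and counted in ``meta['n_flagged']``.
    """
    path = Path(path)
    sentences: list[Sentence] = []
    entities: list[NamedEntity] = []
    n_flagged = 0
    n_records = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if columns is not None:
                sc, cc, lc = columns
                if max(sc, cc, lc) >= len(fields):
                    raise RecordError(lineno, f"expected >= {max(sc, cc, lc) + 1} fields, got {len(fields)}")
            elif len(fields) == 3:
                sc, cc, lc = 0, 1, 2
            elif len(fields) == 4:
                sc, cc, lc = 1, 2, 3
            else:
                raise RecordError(lineno, f"expected 3 or 4 tab-delimited fields, got {len(fields)}")
            sent_text, concept, label = fields[sc], fields[cc], fields[lc]
            label = label.strip().lower()
            if label == "affirmed":
                polarity = NOT_NEGATED
            elif label == "negated":
                polarity = NEGATED
            else:
                raise RecordError(lineno, f"unknown gold label {fields[lc]!r}")
            words = simple_tokenize(sent_text)
            concept_words = simple_tokenize(concept)
            start = _find_sublist([w.lower() for w in words], [w.lower() for w in concept_words])
            n_records += 1
            if start is None or not words:
                n_flagged += 1
                logger.warning(
                    "line %d: concept %r not found in sentence; record excluded", lineno, concept
                )
                continue
            doc_id = f"pseudo-doc-{(len(sentences)) // pseudo_doc_size:04d}"
            sent = Sentence(
                tokens=[Token(w, i) for i, w in enumerate(words)], doc_id=doc_id
            )
            sentences.append(sent)
            entities.append(
                NamedEntity(
                    sentence_ref=len(sentences) - 1,
                    span=(start, start + len(concept_words)),
                    semantic_group="Unknown",
                    polarity=polarity,
                )
            )
    return Corpus(
        name=name or path.stem,
        domain=domain,
        sentences=sentences,
        entities=entities,
        meta={
            "n_records": n_records,
            "n_flagged": n_flagged,
            "pseudo_doc_size": pseudo_doc_size,
        },
    )


# ---------------------------------------------------------------------------
# Standoff format: JSON lines, one header line then one document per line.

_FORMAT = "clinneg-standoff"
_VERSION = 1


def write_standoff(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus to the toolkit standoff format (JSON lines, UTF-8)."""
    path = Path(path)
    docs = corpus.documents()
    # sentence index -> position within its document
    with path.open("w", encoding="utf-8") as fh:
        header = {
            "format": _FORMAT,
            "version": _VERSION,
            "corpus": corpus.name,
            "domain": corpus.domain,
            "meta": corpus.meta,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        ents_by_sent: dict[int, list[NamedEntity]] = {}
        for ne in corpus.entities:
            ents_by_sent.setdefault(ne.sentence_ref, []).append(ne)
        for doc_id, sent_idxs in docs.items():
            sent_records = []
            ent_records = []
            for local, si in enumerate(sent_idxs):
                s = corpus.sentences[si]
                rec: dict = {"tokens": [t.text for t in s.tokens]}
                if any(t.pos is not None for t in s.tokens):
                    rec["pos"] = [t.pos for t in s.tokens]
                if s.dependencies is not None:
                    rec["deps"] = [[e.head, e.dependent, e.relation] for e in s.dependencies]
                if s.parse is not None:
                    rec["parse"] = to_penn(s.parse)
                sent_records.append(rec)
                for ne in ents_by_sent.get(si, []):
                    ent_records.append(
                        {
                            "sentence": local,
                            "start": ne.span[0],
                            "end": ne.span[1],
                            "group": ne.semantic_group,
                            "polarity": ne.polarity,
                        }
                    )
            fh.write(
                json.dumps(
                    {"doc_id": doc_id, "sentences": sent_records, "entities": ent_records},
                    sort_keys=True,
                )
                + "\n"
            )


def read_standoff(path: str | Path) -> Corpus:
    """Read a corpus written by :func:`write_standoff`."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != _FORMAT:
            raise ValueError(f"{path}: not a {_FORMAT} file")
        sentences: list[Sentence] = []
        entities: list[NamedEntity] = []
        for line in fh:
            if not line.strip():
                continue
            doc = json.loads(line)
            doc_id = doc["doc_id"]
            base = len(sentences)
            for rec in doc["sentences"]:
                words = rec["tokens"]
                pos = rec.get("pos", [None] * len(words))
                deps = rec.get("deps")
                parse = rec.get("parse")
                sentences.append(
                    Sentence(
                        tokens=[Token(w, i, p) for i, (w, p) in enumerate(zip(words, pos))],
                        dependencies=(
                            [DependencyEdge(h, d, r) for h, d, r in deps] if deps else None
                        ),
                        parse=parse_penn(parse) if parse else None,
                        doc_id=doc_id,
                    )
                )
            for ent in doc["entities"]:
                local = ent["sentence"]
                if not (0 <= local < len(doc["sentences"])):
                    raise ValueError(
                        f"{path}: NE references sentence {local} outside document {doc_id!r}"
                    )
                si = base + local
                if ent["end"] > len(sentences[si]):
                    raise ValueError(
                        f"{path}: NE span [{ent['start']}, {ent['end']}) outside "
                        f"sentence {local} of document {doc_id!r}"
                    )
                group = ent["group"]
                if group not in SEMANTIC_GROUPS:
                    logger.warning("unknown semantic group %r mapped to Unknown", group)
                    group = "Unknown"
                entities.append(
                    NamedEntity(
                        sentence_ref=si,
                        span=(ent["start"], ent["end"]),
                        semantic_group=group,
                        polarity=ent["polarity"],
                    )
                )
    return Corpus(
        name=header.get("corpus", path.stem),
        domain=header.get("domain", "unknown"),
        sentences=sentences,
        entities=entities,
        meta=header.get("meta", {}),
    )


def concat_corpora(corpora: Iterable[Corpus], name: str = "all", domain: str = "all") -> Corpus:
    """Concatenate corpora, re-basing sentence references.

    Document IDs are prefixed with the source corpus name to keep them
    unique across sources.
    """
    sentences: list[Sentence] = []
    entities: list[NamedEntity] = []
    for c in corpora:
        base = len(sentences)
        for s in c.sentences:
            sentences.append(replace(s, doc_id=f"{c.name}/{s.doc_id}"))
        for ne in c.entities:
            entities.append(replace(ne, sentence_ref=ne.sentence_ref + base))
    return Corpus(name=name, domain=domain, sentences=sentences, entities=entities)
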