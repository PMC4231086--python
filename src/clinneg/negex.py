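"""Rule-based negation baseline in the NegEx tradition.

Classifies one named entity at a time from trigger phrases and a bounded
scope window: a pre-negation trigger (``no``, ``denies``, ``without`` ...)
negates NEs that follow it within ``max_scope`` tokens; a post-negation
trigger (``was ruled out`` ...) negates NEs that precede it; a termination
phrase (``but`` ...) between trigger and NE ends the scope; pseudo-negation
phrases (``no increase`` ...) look like triggers but do not negate and
suppress any pre-negation trigger they overlap.

The shipped lexicon is plain data (``data/negex_triggers.txt``) because
rule customization per corpus is almost always necessary in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .corpus import NEGATED, NOT_NEGATED, Corpus, NamedEntity, Sentence

_SECTIONS = ("pre_negation", "post_negation", "pseudo_negation", "termination")


@dataclass(frozen=True)
class TriggerLexicon:
    pre_negation: frozenset[tuple[str, ...]]
    post_negation: frozenset[tuple[str, ...]]
    pseudo_negation: frozenset[tuple[str, ...]]
    termination: frozenset[tuple[str, ...]]

    def __post_init__(self) -> None:
        sets = [self.pre_negation, self.post_negation, self.pseudo_negation, self.termination]
        seen: dict[tuple[str, ...], str] = {}
        for name, phrases in zip(_SECTIONS, sets):
            for p in phrases:
                if not p or any(not w for w in p):
                    raise ValueError(f"empty phrase in section {name}")
                if p in seen:
                    raise ValueError(
                        f"phrase {' '.join(p)!r} appears in both {seen[p]} and {name}"
                    )
                seen[p] = name

    @staticmethod
    def from_phrases(
        pre: Iterable[str] = (),
        post: Iterable[str] = (),
        pseudo: Iterable[str] = (),
        termination: Iterable[str] = (),
    ) -> "TriggerLexicon":
        def prep(phrases: Iterable[str]) -> frozenset[tuple[str, ...]]:
            return frozenset(tuple(p.lower().split()) for p in phrases)

        return TriggerLexicon(prep(pre), prep(post), prep(pseudo), prep(termination))


@dataclass(frozen=True)
class RuleConfig:
    """``max_scope`` is the maximum number of tokens between the trigger's
    nearest edge and the NE's nearest edge (the classic NegEx window of 5)."""

    max_scope: int = 5
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.max_scope < 1:
            raise ValueError("max_scope must be >= 1")


def load_lexicon(path: str | Path) -> TriggerLexicon:
    """Load a four-section plain-text lexicon file.

    Sections are introduced by ``[pre_negation]``, ``[post_negation]``,
    ``[pseudo_negation]``, ``[termination]``; one phrase per line.
    """
    sections: dict[str, list[str]] = {s: [] for s in _SECTIONS}
    current: Optional[str] = None
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1]
            if name not in sections:
                raise ValueError(f"line {lineno}: unknown section {name!r}")
            current = name
            continue
        if current is None:
            raise ValueError(f"line {lineno}: phrase before any section header")
        sections[current].append(line)
    return TriggerLexicon.from_phrases(
        pre=sections["pre_negation"],
        post=sections["post_negation"],
        pseudo=sections["pseudo_negation"],
        termination=sections["termination"],
    )


def default_lexicon() -> TriggerLexicon:
    """The trigger lexicon shipped with the package."""
    with resources.as_file(
        resources.files("clinneg.data").joinpath("negex_triggers.txt")
    ) as p:
        return load_lexicon(p)


def _find_matches(
    words: list[str], phrases: frozenset[tuple[str, ...]]
) -> list[tuple[int, int]]:
    """All (start, end) spans where a phrase matches, longest-first per start."""
    if not phrases:
        return []
    by_len = sorted(phrases, key=len, reverse=True)
    out: list[tuple[int, int]] = []
    for i in range(len(words)):
        for phrase in by_len:
            n = len(phrase)
            if tuple(words[i : i + n]) == phrase:
                out.append((i, i + n))
                break  # longest match at this start position
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def negex_classify(
    sentence: Sentence,
    ne: NamedEntity,
    lexicon: TriggerLexicon,
    config: RuleConfig = RuleConfig(),
) -> int:
    """Return −1 (negated) or +1 (not negated) for one NE.

    −1 iff a non-pseudo pre-negation trigger precedes the NE within
    ``max_scope`` tokens with no intervening termination phrase, or a
    post-negation trigger follows it within ``max_scope`` tokens with no
    intervening termination phrase.  Deterministic; always returns.
    """
    ns, ne_end = ne.span
    if ne_end > len(sentence):
        raise ValueError("NE span outside sentence")
    words = [t.text for t in sentence.tokens]
    if not config.case_sensitive:
        words = [w.lower() for w in words]

    pseudo = _find_matches(words, lexicon.pseudo_negation)
    term = _find_matches(words, lexicon.termination)

    def scope_clear(gap: tuple[int, int]) -> bool:
        return not any(_overlaps(t, gap) for t in term)

    for ts, te in _find_matches(words, lexicon.pre_negation):
        if any(_overlaps((ts, te), p) for p in pseudo):
            continue
        if te <= ns and ns - te <= config.max_scope and scope_clear((te, ns)):
            return NEGATED
    for ts, te in _find_matches(words, lexicon.post_negation):
        if ts >= ne_end and ts - ne_end <= config.max_scope and scope_clear((ne_end, ts)):
            return NEGATED
    return NOT_NEGATED


def annotate_corpus(
    corpus: Corpus,
    lexicon: Optional[TriggerLexicon] = None,
    config: RuleConfig = RuleConfig(),
) -> list[int]:
    """Predicted polarity for every NE of a corpus, in corpus order."""
    lex = lexicon if lexicon is not None else default_lexicon()
    return [
        negex_classify(corpus.sentence_of(ne), ne, lex, config) for ne in corpus.entities
    ]
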