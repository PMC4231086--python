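"""Feature extraction for named-entity polarity classification.

Five engineered feature families describe the context of an NE:

* **BOW** — bag-of-words: a word occurred within a directional window
  (preceding or following the NE) of size 3, 5, or 10.
* **POS_CTX** — positional context: a word occurred at an exact offset
  from the NE edge (offset 0 = adjacent), windows of 4 and 5.
* **CUE** — the nearest negation cue phrase in scope, its normalized
  category, and an "any cue present" indicator.
* **DEPPATH** — the NE head lies on a dependency path that typically
  expresses negation (a fixed inventory of 12 declarative path rules).
* **TREEFRAG** — partial constituency trees (fragments) describing the
  parse context around the NE, with the NE subtree replaced by a
  ``CONCEPT`` placeholder; the fragment inventory is extracted from
  training data with an occurrence threshold.

All features are binary.  Parse-dependent families degrade to the empty
set when a sentence lacks dependency or constituency annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse

from .corpus import (
    ROOT,
    ConstituencyNode,
    Corpus,
    NamedEntity,
    Sentence,
    to_penn,
)

FAMILIES = ("BOW", "POS_CTX", "CUE", "DEPPATH", "TREEFRAG")


@dataclass(frozen=True, order=True)
class FeatureName:
    family: str
    key: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")

    def __str__(self) -> str:
        return f"{self.family}:{self.key}"


#: A sparse binary feature vector: the set of features that are present.
FeatureVector = frozenset


class FeatureSpace:
    """Bijection between feature names and contiguous column indices.

    Grows while unfrozen; once frozen, unseen features are ignored (the
    standard contract for deploying a linear model).
    """

    def __init__(self) -> None:
        self._index: dict[FeatureName, int] = {}
        self.frozen = False

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, name: FeatureName) -> bool:
        return name in self._index

    def column(self, name: FeatureName) -> Optional[int]:
        return self._index.get(name)

    @property
    def names(self) -> list[FeatureName]:
        out: list[Optional[FeatureName]] = [None] * len(self._index)
        for name, col in self._index.items():
            out[col] = name
        return out  # type: ignore[return-value]

    def add(self, name: FeatureName) -> int:
        col = self._index.get(name)
        if col is None:
            if self.frozen:
                raise ValueError("cannot add features to a frozen space")
            col = len(self._index)
            self._index[name] = col
        return col

    def freeze(self) -> "FeatureSpace":
        self.frozen = True
        return self

    @classmethod
    def from_vectors(cls, vectors: Iterable[FeatureVector]) -> "FeatureSpace":
        """Build a frozen space over all features seen, in sorted order
        (deterministic regardless of input order)."""
        names = sorted({f for v in vectors for f in v})
        space = cls()
        for n in names:
            space.add(n)
        return space.freeze()

    def transform(self, vectors: Sequence[FeatureVector]) -> sparse.csr_matrix:
        rows, cols = [], []
        for i, v in enumerate(vectors):
            for f in v:
                c = self._index.get(f)
                if c is not None:
                    rows.append(i)
                    cols.append(c)
        data = np.ones(len(rows), dtype=np.float64)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(vectors), len(self._index))
        )

    def to_dict(self) -> dict:
        return {str(k): v for k, v in self._index.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "FeatureSpace":
        space = cls()
        pairs = sorted(d.items(), key=lambda kv: kv[1])
        for key, col in pairs:
            fam, rest = key.split(":", 1)
            got = space.add(FeatureName(fam, rest))
            if got != col:
                raise ValueError("feature space indices are not contiguous from 0")
        return space.freeze()


# ---------------------------------------------------------------------------
# (A) Bag-of-words windows


def bow_features(
    sentence: Sentence, ne: NamedEntity, direction: str, size: int
) -> set[FeatureName]:
    """One feature per distinct lowercased token in a directional window.

    Windows are clipped at sentence boundaries; NE-internal tokens are
    never included.
    """
    if direction not in ("preceding", "following"):
        raise ValueError(f"direction must be 'preceding' or 'following', got {direction!r}")
    start, end = ne.span
    if direction == "preceding":
        window = sentence.tokens[max(0, start - size) : start]
        tag = "prec"
    else:
        window = sentence.tokens[end : end + size]
        tag = "foll"
    return {FeatureName("BOW", f"{tag}:{size}:{t.text.lower()}") for t in window}


# ---------------------------------------------------------------------------
# (B) Positional context


def positional_features(
    sentence: Sentence, ne: NamedEntity, window: int
) -> set[FeatureName]:
    """One feature per (offset, token) pair on each side of the NE.

    Offset 0 is the token adjacent to the NE edge, counting outward;
    offsets run 0..window−1 and are clipped at sentence boundaries.
    """
    start, end = ne.span
    out: set[FeatureName] = set()
    for off in range(window):
        i = start - 1 - off
        if i >= 0:
            out.add(FeatureName("POS_CTX", f"prec:{off}:{sentence.tokens[i].text.lower()}"))
        j = end + off
        if j < len(sentence):
            out.add(FeatureName("POS_CTX", f"foll:{off}:{sentence.tokens[j].text.lower()}"))
    return out


# ---------------------------------------------------------------------------
# (C) Cue words


@dataclass(frozen=True)
class CueLexicon:
    """Expert-curated negation cue phrases with normalized categories.

    ``phrases`` maps lowercased phrase token-tuples to a category string
    (e.g. ``("negative", "for")`` -> ``"negative"``).  ``termination``
    phrases bound a cue's scope: a cue separated from the NE by a
    termination phrase is out of scope.
    """

    phrases: Mapping[tuple[str, ...], str]
    termination: frozenset = frozenset()

    def __post_init__(self) -> None:
        for p in self.phrases:
            if not p or any(w != w.lower() or not w for w in p):
                raise ValueError(f"cue phrases must be lowercased and non-empty: {p!r}")

    @staticmethod
    def from_pairs(
        pairs: Iterable[tuple[str, str]], termination: Iterable[str] = ()
    ) -> "CueLexicon":
        return CueLexicon(
            phrases={tuple(p.lower().split()): cat for p, cat in pairs},
            termination=frozenset(tuple(t.lower().split()) for t in termination),
        )


def default_cue_lexicon() -> CueLexicon:
    """Cue lexicon shipped with the package (``data/cue_lexicon.tsv``),
    with the default rule lexicon's termination phrases as scope bounds."""
    from .negex import default_lexicon  # local import to avoid a cycle

    with resources.as_file(resources.files("clinneg.data").joinpath("cue_lexicon.tsv")) as p:
        pairs = []
        for line in Path(p).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            phrase, cat = line.split("\t")
            pairs.append((phrase, cat))
    return CueLexicon.from_pairs(pairs, termination=[" ".join(t) for t in default_lexicon().termination])


def _phrase_matches(
    words: list[str], phrases: Iterable[tuple[str, ...]]
) -> list[tuple[int, int, tuple[str, ...]]]:
    by_len = sorted(phrases, key=len, reverse=True)
    out = []
    for i in range(len(words)):
        for phrase in by_len:
            if tuple(words[i : i + len(phrase)]) == phrase:
                out.append((i, i + len(phrase), phrase))
                break
    return out


def cue_features(
    sentence: Sentence, ne: NamedEntity, lexicon: CueLexicon
) -> set[FeatureName]:
    """Features for the nearest in-scope cue: its surface phrase, its
    category, and an "any cue present" indicator.

    Scope is the NE's own sentence, not interrupted by a termination
    phrase between cue and NE.  Nearest is by token distance between
    nearest edges; ties prefer the preceding side.
    """
    ns, ne_end = ne.span
    words = [t.text.lower() for t in sentence.tokens]
    terms = _phrase_matches(words, lexicon.termination)

    def in_scope(gap: tuple[int, int]) -> bool:
        return not any(ts < gap[1] and gap[0] < te for ts, te, _ in terms)

    candidates: list[tuple[int, int, tuple[int, int, tuple[str, ...]]]] = []
    for ts, te, phrase in _phrase_matches(words, lexicon.phrases):
        if ts < ne_end and ns < te:  # overlaps the NE itself
            continue
        if te <= ns:  # preceding
            dist, side = ns - te, 0
            gap = (te, ns)
        else:  # following
            dist, side = ts - ne_end, 1
            gap = (ne_end, ts)
        if in_scope(gap):
            candidates.append((dist, side, (ts, te, phrase)))
    if not candidates:
        return set()
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, (_, _, phrase) = candidates[0]
    cat = lexicon.phrases[phrase]
    return {
        FeatureName("CUE", f"word:{'_'.join(phrase)}"),
        FeatureName("CUE", f"cat:{cat}"),
        FeatureName("CUE", "any"),
    }


# ---------------------------------------------------------------------------
# (D) Dependency path rules


@dataclass(frozen=True)
class DepPathRule:
    """One negation path pattern: starting from any token of ``word_class``,
    follow ``steps`` through the dependency tree; the rule fires if a path
    ends at the NE head.  A step is ``(direction, relation)`` with
    direction ``"up"`` (token to its head) or ``"down"`` (head to a
    dependent)."""

    rule_id: int
    word_class: str
    steps: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class DepPathRuleSet:
    rules: tuple[DepPathRule, ...]
    word_classes: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("dependency path rule IDs must be unique")
        for r in self.rules:
            if r.word_class not in self.word_classes:
                raise ValueError(f"rule {r.rule_id} uses unknown word class {r.word_class!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "word_classes": {k: sorted(v) for k, v in self.word_classes.items()},
                "rules": [
                    {"id": r.rule_id, "class": r.word_class, "steps": [list(s) for s in r.steps]}
                    for r in self.rules
                ],
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "DepPathRuleSet":
        d = json.loads(text)
        return DepPathRuleSet(
            rules=tuple(
                DepPathRule(r["id"], r["class"], tuple(tuple(s) for s in r["steps"]))
                for r in d["rules"]
            ),
            word_classes={k: frozenset(v) for k, v in d["word_classes"].items()},
        )


def default_deppath_rules() -> DepPathRuleSet:
    """The default inventory of 12 negation dependency-path patterns.

    Reconstructed declaratively around negation determiners, negation
    verbs, negation adjectives, and the preposition *without*; the set is
    replaceable data, not code.
    """
    wc = {
        "NEG_DET": frozenset({"no", "not", "n't", "never"}),
        "NEG_VERB": frozenset({"denies", "denied", "deny", "ruled", "rules", "excluded"}),
        "NEG_ADJ": frozenset({"negative", "absent", "free", "unremarkable"}),
        "WITHOUT": frozenset({"without"}),
    }
    mk = DepPathRule
    rules = (
        mk(1, "NEG_DET", (("up", "neg"),)),
        mk(2, "NEG_DET", (("up", "det"),)),
        mk(3, "NEG_DET", (("up", "neg"), ("down", "prep_of"))),
        mk(4, "NEG_DET", (("up", "neg"), ("down", "prep_of"), ("down", "conj"))),
        mk(5, "NEG_DET", (("up", "neg"), ("down", "conj"))),
        mk(6, "NEG_VERB", (("down", "dobj"),)),
        mk(7, "NEG_VERB", (("down", "dobj"), ("down", "conj"))),
        mk(8, "NEG_VERB", (("down", "nsubjpass"),)),
        mk(9, "NEG_VERB", (("down", "nsubjpass"), ("down", "conj"))),
        mk(10, "NEG_ADJ", (("down", "prep_for"),)),
        mk(11, "WITHOUT", (("down", "pobj"),)),
        mk(12, "WITHOUT", (("down", "pobj"), ("down", "conj"))),
    )
    return DepPathRuleSet(rules=rules, word_classes=wc)


def ne_head(sentence: Sentence, ne: NamedEntity) -> Optional[int]:
    """Head token of the NE: the rightmost NE token whose dependency head
    lies outside the NE span (or is the root).  None without a parse."""
    if sentence.dependencies is None:
        return None
    start, end = ne.span
    heads = {e.dependent: e.head for e in sentence.dependencies}
    candidates = [
        i for i in range(start, end) if heads.get(i, ROOT) == ROOT or not (start <= heads[i] < end)
    ]
    return candidates[-1] if candidates else end - 1


def deppath_features(
    sentence: Sentence, ne: NamedEntity, rules: DepPathRuleSet
) -> set[FeatureName]:
    """``DEPPATH:rule:k`` for every rule whose path pattern connects a
    negation word to the NE head.  Empty without dependency annotations."""
    if sentence.dependencies is None:
        return set()
    head = ne_head(sentence, ne)
    heads: dict[int, tuple[int, str]] = {
        e.dependent: (e.head, e.relation) for e in sentence.dependencies
    }
    children: dict[int, list[tuple[int, str]]] = {}
    for e in sentence.dependencies:
        children.setdefault(e.head, []).append((e.dependent, e.relation))
    words = [t.text.lower() for t in sentence.tokens]

    out: set[FeatureName] = set()
    for rule in rules.rules:
        cls = rules.word_classes[rule.word_class]
        anchors = [i for i, w in enumerate(words) if w in cls]
        for a in anchors:
            frontier = {a}
            for direction, rel in rule.steps:
                nxt: set[int] = set()
                for tok in frontier:
                    if direction == "up":
                        h = heads.get(tok)
                        if h is not None and h[1] == rel and h[0] != ROOT:
                            nxt.add(h[0])
                    else:
                        for dep, r in children.get(tok, []):
                            if r == rel:
                                nxt.add(dep)
                frontier = nxt
                if not frontier:
                    break
            if head in frontier:
                out.add(FeatureName("DEPPATH", f"rule:{rule.rule_id}"))
                break
    return out


# ---------------------------------------------------------------------------
# (E) Constituency tree fragments


def _prune(node: ConstituencyNode, depth: int) -> ConstituencyNode:
    """Copy of a subtree limited to ``depth`` levels; nodes at the limit
    are rendered with empty children, e.g. ``(NML )``."""
    if node.is_leaf():
        return ConstituencyNode(node.label, word=node.word)
    if depth <= 1:
        return ConstituencyNode(node.label)
    return ConstituencyNode(node.label, children=[_prune(c, depth - 1) for c in node.children])


def _subtrees(node: ConstituencyNode):
    yield node
    for c in node.children:
        yield from _subtrees(c)


def _covering_node(root: ConstituencyNode, span: tuple[int, int]) -> Optional[ConstituencyNode]:
    """Smallest node whose span covers the NE span (exact match preferred
    implicitly: an exact-span node is the smallest cover)."""
    best: Optional[ConstituencyNode] = None
    for node in _subtrees(root):
        s = node.span
        if s is None:
            continue
        if s[0] <= span[0] and span[1] <= s[1]:
            if best is None or (s[1] - s[0]) < (best.span[1] - best.span[0]):  # type: ignore[index]
                best = node
    return best


def _parent_chain(root: ConstituencyNode, target: ConstituencyNode) -> list[ConstituencyNode]:
    """Ancestors of ``target`` from immediate parent upward."""

    def walk(node: ConstituencyNode) -> Optional[list[ConstituencyNode]]:
        for c in node.children:
            if c is target:
                return [node]
            deeper = walk(c)
            if deeper is not None:
                return deeper + [node]
        return None

    return walk(root) or []


MAX_FRAGMENT_DEPTH = 2
ANCESTOR_LEVELS = 2


def context_fragments(sentence: Sentence, ne: NamedEntity) -> set[tuple[str, str]]:
    """Position-tagged constituency fragments describing the NE's parse
    context.

    The NE's covering node is located; its sibling subtrees contribute
    ``above_left`` / ``above_right`` fragments (every subtree, pruned to
    ``MAX_FRAGMENT_DEPTH`` levels), and each of up to ``ANCESTOR_LEVELS``
    ancestors contributes one fragment with the NE subtree replaced by
    ``(CONCEPT )`` and siblings pruned.  Empty without a parse.
    """
    if sentence.parse is None:
        return set()
    node = _covering_node(sentence.parse, ne.span)
    if node is None:
        return set()
    chain = _parent_chain(sentence.parse, node)
    out: set[tuple[str, str]] = set()
    if not chain:
        return out
    parent = chain[0]
    ne_pos = parent.children.index(node)
    for sib in parent.children[:ne_pos]:
        for t in _subtrees(sib):
            out.add(("above_left", to_penn(_prune(t, MAX_FRAGMENT_DEPTH))))
    for sib in parent.children[ne_pos + 1 :]:
        for t in _subtrees(sib):
            out.add(("above_right", to_penn(_prune(t, MAX_FRAGMENT_DEPTH))))

    # ancestor fragments with the NE replaced by a CONCEPT placeholder
    placeholder = ConstituencyNode("CONCEPT")
    inner: ConstituencyNode = placeholder
    for level, anc in enumerate(chain[:ANCESTOR_LEVELS]):
        replaced = chain[level - 1] if level > 0 else node
        kids = [
            inner if c is replaced else _prune(c, MAX_FRAGMENT_DEPTH - 1)
            for c in anc.children
        ]
        frag = ConstituencyNode(anc.label, children=kids)
        idx = anc.children.index(replaced)
        pos = "above_left" if idx > 0 else ("above_right" if len(anc.children) > 1 else "above")
        out.add((pos, to_penn(frag)))
        inner = frag
    return out


@dataclass(frozen=True)
class TreeFragmentInventory:
    fragments: frozenset  # of (position, penn) pairs
    threshold: int = 2

    def __len__(self) -> int:
        return len(self.fragments)

    def to_json(self) -> str:
        return json.dumps(
            {"threshold": self.threshold, "fragments": sorted(self.fragments)}, indent=2
        )

    @staticmethod
    def from_json(text: str) -> "TreeFragmentInventory":
        d = json.loads(text)
        return TreeFragmentInventory(
            fragments=frozenset(tuple(f) for f in d["fragments"]), threshold=d["threshold"]
        )


def extract_fragments(corpus: Corpus, threshold: int = 2) -> TreeFragmentInventory:
    """Inventory of context fragments occurring at least ``threshold``
    times around gold NEs of the corpus."""
    counts: dict[tuple[str, str], int] = {}
    any_parse = False
    for ent in corpus.entities:
        sent = corpus.sentence_of(ent)
        if sent.parse is None:
            continue
        any_parse = True
        for frag in context_fragments(sent, ent):
            counts[frag] = counts.get(frag, 0) + 1
    if not any_parse and corpus.entities:
        import logging

        logging.getLogger(__name__).warning(
            "corpus %r has no constituency parses; fragment inventory is empty", corpus.name
        )
    kept = frozenset(f for f, c in counts.items() if c >= threshold)
    return TreeFragmentInventory(fragments=kept, threshold=threshold)


def treefrag_features(
    sentence: Sentence, ne: NamedEntity, inventory: TreeFragmentInventory
) -> set[FeatureName]:
    """``TREEFRAG:{position}:{fragment}`` for every inventory fragment
    found in the NE's parse context.  Empty without a parse."""
    if sentence.parse is None or not inventory.fragments:
        return set()
    found = context_fragments(sentence, ne)
    return {
        FeatureName("TREEFRAG", f"{pos}:{frag}")
        for pos, frag in found & inventory.fragments
    }


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class FeatureConfig:
    """Which feature families are active, and the resources they use."""

    bow: bool = True
    positional: bool = True
    cue: bool = True
    deppath: bool = True
    treefrag: bool = True
    bow_sizes: tuple[int, ...] = (3, 5, 10)
    positional_windows: tuple[int, ...] = (4, 5)
    cue_lexicon: Optional[CueLexicon] = None
    deppath_rules: Optional[DepPathRuleSet] = None
    fragment_inventory: Optional[TreeFragmentInventory] = None

    def resolved(self) -> "FeatureConfig":
        """Fill lazy defaults (shipped lexicon and rule set)."""
        if self.cue and self.cue_lexicon is None:
            self.cue_lexicon = default_cue_lexicon()
        if self.deppath and self.deppath_rules is None:
            self.deppath_rules = default_deppath_rules()
        return self


def assemble(sentence: Sentence, ne: NamedEntity, config: FeatureConfig) -> FeatureVector:
    """Union of the active families' feature sets for one NE."""
    config.resolved()
    out: set[FeatureName] = set()
    if config.bow:
        for direction in ("preceding", "following"):
            for size in config.bow_sizes:
                out |= bow_features(sentence, ne, direction, size)
    if config.positional:
        for w in config.positional_windows:
            out |= positional_features(sentence, ne, w)
    if config.cue:
        out |= cue_features(sentence, ne, config.cue_lexicon)  # type: ignore[arg-type]
    if config.deppath:
        out |= deppath_features(sentence, ne, config.deppath_rules)  # type: ignore[arg-type]
    if config.treefrag and config.fragment_inventory is not None:
        out |= treefrag_features(sentence, ne, config.fragment_inventory)
    return frozenset(out)
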