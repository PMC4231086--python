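import numpy as np
import pytest

from clinneg.corpus import NamedEntity, to_penn
from clinneg.features import (
    CueLexicon,
    FeatureConfig,
    FeatureName,
    FeatureSpace,
    assemble,
    bow_features,
    context_fragments,
    cue_features,
    default_cue_lexicon,
    default_deppath_rules,
    deppath_features,
    extract_fragments,
    positional_features,
    treefrag_features,
    TreeFragmentInventory,
)
from clinneg.synthetic import (
    _adj_template,
    _object_template,
    _post_template,
    _pseudo_template,
)

from .conftest import make_sentence

WORDS = ["no", "cough", "fever", "denies", "the", "patient", "mild", "without", "or", "and"]


def random_case(rng: np.random.Generator):
    n = int(rng.integers(5, 13))
    words = [WORDS[int(i)] for i in rng.integers(0, len(WORDS), size=n)]
    start = int(rng.integers(0, n))
    end = int(rng.integers(start + 1, n + 1))
    return make_sentence(" ".join(words)), NamedEntity(0, (start, end))


class TestBagOfWords:
    def test_cue_in_preceding_window(self):
        sent = make_sentence("patient has no cough today")
        ne = NamedEntity(0, (3, 4))
        feats = bow_features(sent, ne, "preceding", 5)
        assert FeatureName("BOW", "prec:5:no") in feats
        assert FeatureName("BOW", "prec:5:patient") in feats

    def test_ne_at_sentence_start_has_empty_preceding_window(self):
        sent = make_sentence("cough was noted")
        ne = NamedEntity(0, (0, 1))
        for size in (3, 5, 10):
            assert bow_features(sent, ne, "preceding", size) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_window_enumeration(self, seed):
        """Independent oracle: enumerate token positions directly."""
        rng = np.random.default_rng(seed)
        sent, ne = random_case(rng)
        words = [t.text.lower() for t in sent.tokens]
        start, end = ne.span
        for size in (3, 5, 10):
            expected_prec = {
                FeatureName("BOW", f"prec:{size}:{words[i]}")
                for i in range(len(words))
                if 0 <= i < start and start - i <= size
            }
            expected_foll = {
                FeatureName("BOW", f"foll:{size}:{words[i]}")
                for i in range(len(words))
                if end <= i < end + size
            }
            assert bow_features(sent, ne, "preceding", size) == expected_prec
            assert bow_features(sent, ne, "following", size) == expected_foll

    @pytest.mark.parametrize("seed", range(10))
    def test_window_monotonicity(self, seed):
        rng = np.random.default_rng(100 + seed)
        sent, ne = random_case(rng)
        for direction in ("preceding", "following"):
            f3 = bow_features(sent, ne, direction, 3)
            f5 = bow_features(sent, ne, direction, 5)
            f10 = bow_features(sent, ne, direction, 10)

            def keys(fs):
                return {f.key.split(":", 2)[2] for f in fs}

            assert keys(f3) <= keys(f5) <= keys(f10)

    def test_unknown_direction_rejected(self):
        sent = make_sentence("a b c")
        with pytest.raises(ValueError):
            bow_features(sent, NamedEntity(0, (0, 1)), "sideways", 5)


class TestPositional:
    def test_adjacent_token_is_offset_zero(self):
        sent = make_sentence("admitted without complication")
        feats = positional_features(sent, NamedEntity(0, (2, 3)), 4)
        assert FeatureName("POS_CTX", "prec:0:without") in feats

    def test_token_four_positions_before_ne(self):
        sent = make_sentence("without a b c d complication")
        feats = positional_features(sent, NamedEntity(0, (5, 6)), 5)
        assert FeatureName("POS_CTX", "prec:4:without") in feats
        # window 4 stops at offset 3
        assert FeatureName("POS_CTX", "prec:4:without") not in positional_features(
            sent, NamedEntity(0, (5, 6)), 4
        )

    def test_positions_beyond_sentence_boundaries_yield_nothing(self):
        sent = make_sentence("cough")
        assert positional_features(sent, NamedEntity(0, (0, 1)), 5) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_offset_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        sent, ne = random_case(rng)
        words = [t.text.lower() for t in sent.tokens]
        start, end = ne.span
        for window in (4, 5):
            expected = set()
            for off in range(window):
                if start - 1 - off >= 0:
                    expected.add(FeatureName("POS_CTX", f"prec:{off}:{words[start - 1 - off]}"))
                if end + off < len(words):
                    expected.add(FeatureName("POS_CTX", f"foll:{off}:{words[end + off]}"))
            assert positional_features(sent, ne, window) == expected


class TestCue:
    def test_cue_word_and_category(self):
        sent = make_sentence("negative for pneumonia")
        feats = cue_features(sent, NamedEntity(0, (2, 3)), default_cue_lexicon())
        assert FeatureName("CUE", "word:negative_for") in feats
        assert FeatureName("CUE", "cat:negative") in feats
        assert FeatureName("CUE", "any") in feats

    def test_no_cue_no_features(self):
        sent = make_sentence("ambulating well today")
        assert cue_features(sent, NamedEntity(0, (0, 1)), default_cue_lexicon()) == set()

    def test_nearest_cue_wins(self):
        """Two cues at distances 2 and 0: only the nearer one's features."""
        lex = CueLexicon.from_pairs([("denies", "deny"), ("no", "no")])
        sent = make_sentence("denies x no cough")
        feats = cue_features(sent, NamedEntity(0, (3, 4)), lex)
        assert FeatureName("CUE", "word:no") in feats
        assert FeatureName("CUE", "word:denies") not in feats
        assert FeatureName("CUE", "cat:no") in feats

    def test_tie_prefers_preceding_side(self):
        lex = CueLexicon.from_pairs([("no", "no"), ("resolved", "resolved")])
        sent = make_sentence("no cough resolved")
        feats = cue_features(sent, NamedEntity(0, (1, 2)), lex)
        assert FeatureName("CUE", "word:no") in feats

    def test_termination_blocks_scope(self):
        lex = CueLexicon.from_pairs([("denies", "deny")], termination=["but"])
        sent = make_sentence("denies cough but has fever")
        assert cue_features(sent, NamedEntity(0, (4, 5)), lex) == set()
        assert FeatureName("CUE", "word:denies") in cue_features(sent, NamedEntity(0, (1, 2)), lex)


class TestDepPath:
    def test_neg_determiner_path_fires(self):
        sent, span = _object_template("patient", "has", ("no",), "neg", [], ["cough"], "d")
        feats = deppath_features(sent, NamedEntity(0, span), default_deppath_rules())
        assert FeatureName("DEPPATH", "rule:1") in feats

    def test_neg_verb_object_path_fires(self):
        sent, span = _object_template("patient", "denies", (), "neg", [], ["cough"], "d")
        feats = deppath_features(sent, NamedEntity(0, span), default_deppath_rules())
        assert FeatureName("DEPPATH", "rule:6") in feats

    def test_passive_ruled_out_path_fires(self):
        sent, span = _post_template(("was", "ruled", "out"), ["pneumonia"], "d")
        feats = deppath_features(sent, NamedEntity(0, span), default_deppath_rules())
        assert FeatureName("DEPPATH", "rule:8") in feats

    def test_pseudo_negation_attaches_elsewhere_no_fire(self):
        """In "no increase in <NE>" the negation modifies "increase", so no
        path from the negation word reaches the NE head."""
        sent, span = _pseudo_template("patient", ("no", "increase", "in"), ["edema"], "d")
        assert deppath_features(sent, NamedEntity(0, span), default_deppath_rules()) == set()

    def test_no_dependencies_degrades_to_empty(self):
        sent = make_sentence("no cough")
        assert deppath_features(sent, NamedEntity(0, (1, 2)), default_deppath_rules()) == set()

    def test_no_negation_token_no_features(self):
        sent, span = _object_template("patient", "has", (), "neg", ["mild"], ["cough"], "d")
        assert deppath_features(sent, NamedEntity(0, span), default_deppath_rules()) == set()

    def test_default_ruleset_has_twelve_rules(self):
        rules = default_deppath_rules()
        assert len(rules.rules) == 12
        assert sorted(r.rule_id for r in rules.rules) == list(range(1, 13))

    def test_ruleset_serialization_round_trip(self):
        from clinneg.features import DepPathRuleSet

        rules = default_deppath_rules()
        back = DepPathRuleSet.from_json(rules.to_json())
        assert back == rules


def brute_force_context(sentence, ne):
    """Independent fragment oracle for shallow (≤ 2-level) trees: enumerate
    every subtree of each sibling of the NE node, plus the
    ancestor-with-CONCEPT fragments, directly."""
    def subtrees(n):
        yield n
        for c in n.children:
            yield from subtrees(c)

    root = sentence.parse
    node = min(
        (
            n
            for n in subtrees(root)
            if n.span and n.span[0] <= ne.span[0] and ne.span[1] <= n.span[1]
        ),
        key=lambda n: n.span[1] - n.span[0],
    )
    chain = []
    cur = root

    def find_parent(n, target):
        for c in n.children:
            if c is target:
                return n
            got = find_parent(c, target)
            if got is not None:
                return got
        return None

    target = node
    while True:
        p = find_parent(root, target)
        if p is None:
            break
        chain.append(p)
        target = p
    out = set()
    parent = chain[0]
    i = parent.children.index(node)
    for sib in parent.children[:i]:
        for t in subtrees(sib):
            out.add(("above_left", to_penn(t)))
    for sib in parent.children[i + 1 :]:
        for t in subtrees(sib):
            out.add(("above_right", to_penn(t)))
    def prune1(n):
        # siblings in ancestor fragments keep one level: preterminals
        # survive, internal nodes collapse to "(LABEL )"
        if n.word is not None:
            return to_penn(n)
        return f"({n.label} )"

    inner = "(CONCEPT )"
    replaced = node
    for anc in chain[:2]:
        parts = []
        for c in anc.children:
            parts.append(inner if c is replaced else prune1(c))
        frag = f"({anc.label} {' '.join(parts)})"
        idx = anc.children.index(replaced)
        pos = "above_left" if idx > 0 else ("above_right" if len(anc.children) > 1 else "above")
        out.add((pos, frag))
        inner = frag
        replaced = anc
    return out


class TestTreeFragments:
    def test_dt_no_fragment_above_left(self):
        sent, span = _object_template("patient", "has", ("no",), "neg", [], ["cough"], "d")
        inv = TreeFragmentInventory(frozenset({("above_left", "(DT no)")}), threshold=1)
        feats = treefrag_features(sent, NamedEntity(0, span), inv)
        assert FeatureName("TREEFRAG", "above_left:(DT no)") in feats

    def test_empty_inventory_no_features(self):
        sent, span = _object_template("patient", "has", ("no",), "neg", [], ["cough"], "d")
        inv = TreeFragmentInventory(frozenset(), threshold=1)
        assert treefrag_features(sent, NamedEntity(0, span), inv) == set()

    def test_no_parse_degrades_to_empty(self):
        sent = make_sentence("no cough")
        inv = TreeFragmentInventory(frozenset({("above_left", "(DT no)")}), threshold=1)
        assert treefrag_features(sent, NamedEntity(0, (1, 2)), inv) == set()

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: _object_template("patient", "has", ("no",), "neg", [], ["cough"], "d"),
            lambda: _object_template("patient", "denies", (), "neg", [], ["pain", "cough"], "d"),
            lambda: _adj_template("exam", ("negative", "for"), ["pneumonia"], "d"),
            lambda: _post_template(("was", "ruled", "out"), ["sepsis"], "d"),
        ],
    )
    def test_matches_brute_force_enumeration_on_shallow_trees(self, builder):
        sent, span = builder()
        ne = NamedEntity(0, span)
        assert context_fragments(sent, ne) == brute_force_context(sent, ne)

    def test_extraction_equals_hand_enumeration(self):
        from clinneg.corpus import Corpus

        sents, ents = [], []
        for _ in range(3):
            s, span = _object_template("patient", "has", ("no",), "neg", [], ["cough"], "d")
            sents.append(s)
            ents.append(NamedEntity(len(sents) - 1, span, polarity=-1))
        corpus = Corpus("c", "d", sents, ents)
        inv = extract_fragments(corpus, threshold=3)
        expected = {
            ("above_left", "(DT no)"),
            ("above_left", "(NP (DT no) (CONCEPT ))"),
            ("above_left", "(VP (VBZ has) (NP (DT no) (CONCEPT )))"),
        }
        assert inv.fragments == frozenset(expected)

    def test_threshold_monotonicity(self, small_paper_like):
        _, corpora = small_paper_like
        c = corpora["i2b2_like"]
        inv1 = extract_fragments(c, threshold=1)
        inv2 = extract_fragments(c, threshold=2)
        assert inv2.fragments <= inv1.fragments

    def test_inventory_serialization_round_trip(self, small_paper_like):
        _, corpora = small_paper_like
        inv = extract_fragments(corpora["sharp_like"], threshold=2)
        assert TreeFragmentInventory.from_json(inv.to_json()) == inv


class TestAssemble:
    def test_all_families_off_gives_empty_vector(self):
        sent = make_sentence("no cough")
        cfg = FeatureConfig(bow=False, positional=False, cue=False, deppath=False, treefrag=False)
        assert assemble(sent, NamedEntity(0, (1, 2)), cfg) == frozenset()

    def test_equals_union_of_family_outputs(self):
        sent, span = _object_template("patient", "has", ("no",), "neg", ["mild"], ["cough"], "d")
        ne = NamedEntity(0, span)
        cfg = FeatureConfig().resolved()
        cfg.fragment_inventory = TreeFragmentInventory(
            frozenset({("above_left", "(DT no)")}), threshold=1
        )
        expected = set()
        for d in ("preceding", "following"):
            for s in (3, 5, 10):
                expected |= bow_features(sent, ne, d, s)
        for w in (4, 5):
            expected |= positional_features(sent, ne, w)
        expected |= cue_features(sent, ne, cfg.cue_lexicon)
        expected |= deppath_features(sent, ne, cfg.deppath_rules)
        expected |= treefrag_features(sent, ne, cfg.fragment_inventory)
        assert assemble(sent, ne, cfg) == frozenset(expected)

    def test_deterministic(self):
        sent, span = _adj_template("exam", ("negative", "for"), ["pneumonia"], "d")
        cfg = FeatureConfig()
        v1 = assemble(sent, NamedEntity(0, span), cfg)
        v2 = assemble(sent, NamedEntity(0, span), cfg)
        assert v1 == v2


class TestFeatureSpace:
    def test_sorted_deterministic_indexing(self):
        v1 = frozenset({FeatureName("BOW", "prec:5:no"), FeatureName("CUE", "any")})
        v2 = frozenset({FeatureName("CUE", "any"), FeatureName("BOW", "prec:5:no")})
        s1 = FeatureSpace.from_vectors([v1])
        s2 = FeatureSpace.from_vectors([v2])
        assert s1.to_dict() == s2.to_dict()

    def test_frozen_space_ignores_unseen(self):
        v = frozenset({FeatureName("BOW", "prec:5:no")})
        space = FeatureSpace.from_vectors([v])
        unseen = frozenset({FeatureName("BOW", "prec:5:never_seen")})
        X = space.transform([unseen])
        assert X.nnz == 0

    def test_transform_shape_and_binary_values(self):
        vs = [
            frozenset({FeatureName("BOW", "prec:3:a"), FeatureName("CUE", "any")}),
            frozenset({FeatureName("BOW", "prec:3:a")}),
        ]
        space = FeatureSpace.from_vectors(vs)
        X = space.transform(vs)
        assert X.shape == (2, 2)
        assert set(X.data) == {1.0}
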