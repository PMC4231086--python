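import dataclasses

import pytest

from clinneg.corpus import Corpus, NamedEntity, Sentence, Token
from clinneg.synthetic import generate, preset_suite


def make_sentence(text: str, doc_id: str = "doc0") -> Sentence:
    """Plain sentence from whitespace-tokenized text (no parses)."""
    return Sentence([Token(w, i) for i, w in enumerate(text.split())], doc_id=doc_id)


def make_corpus(records, name="toy", domain="toy"):
    """Corpus from (text, (start, end), polarity[, doc_id]) records."""
    sentences, entities = [], []
    for rec in records:
        text, span, polarity = rec[0], rec[1], rec[2]
        doc_id = rec[3] if len(rec) > 3 else "doc0"
        sentences.append(make_sentence(text, doc_id))
        entities.append(NamedEntity(len(sentences) - 1, span, polarity=polarity))
    return Corpus(name=name, domain=domain, sentences=sentences, entities=entities)


@pytest.fixture(scope="session")
def small_paper_like():
    """A small four-domain suite with parses and gold labels."""
    cfg = dataclasses.replace(
        preset_suite("paper_like"), n_documents=8, sentences_per_document=10, seed=11
    )
    return cfg, generate(cfg)


@pytest.fixture(scope="session")
def small_conflict():
    cfg = dataclasses.replace(
        preset_suite("conflict"), n_documents=20, sentences_per_document=15, seed=13
    )
    return cfg, generate(cfg)
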