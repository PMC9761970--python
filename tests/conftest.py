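import numpy as np
import pytest

from spanrel.corpus import Corpus, EntityMention, RelationInstance, Sentence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_span_set(rng, n):
    """Random non-overlapping inclusive spans on n tokens."""
    spans = []
    i = 0
    while i < n:
        if rng.random() < 0.35:
            length = int(rng.integers(1, min(4, n - i) + 1))
            spans.append((i, i + length - 1))
            i += length + 1   # at least one gap token keeps spans separated
        else:
            i += 1
    return spans


@pytest.fixture
def tiny_corpus():
    """Three hand-built annotated sentences with two entity types."""
    sents, ments, rels = [], [], []
    data = [
        (("velastatin", "induced", "acute", "morinitis", "in", "patients"),
         [EntityMention(0, 0, "Drug", "T1"), EntityMention(2, 3, "Disease", "T2")],
         [RelationInstance("T1", "T2", "ADE")]),
        (("no", "adverse", "events", "were", "observed"), [], []),
        (("cadaprine", "and", "lunomycin", "were", "given"),
         [EntityMention(0, 0, "Drug", "T1"), EntityMention(2, 2, "Drug", "T2")],
         []),
    ]
    for tokens, mm, rr in data:
        sents.append(Sentence(tokens, corpus_name="tiny", sentence_id=f"s{len(sents)}"))
        ments.append(mm)
        rels.append(rr)
    return Corpus(name="tiny", sentences=sents, mentions=ments, relations=rels)
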