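"""Annotated-corpus data model, the BIOES span codec and label vocabularies.

A corpus is a list of pre-tokenized sentences, each carrying typed entity
mentions (token spans, inclusive on both ends) and binary relations between
mention pairs of the same sentence.  Span detection is supervised through
BIOES tag sequences: Beginning / Inside / Outside / End / Single, one tag
per token, which can represent any set of non-overlapping, non-nested spans
and nothing more — overlapping gold annotations are rejected at load time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Sentence", "EntityMention", "RelationInstance", "TagSequence", "Corpus",
    "LabelVocabulary", "bioes_encode", "bioes_decode", "normalize_labels",
    "expand_vocabulary", "BIOES_TAGS", "CorpusError",
]

BIOES_TAGS = ("B", "I", "O", "E", "S")

_MARKER_RE = re.compile(r"^\[[^\[\]]+_(start|end)\]$")


class CorpusError(ValueError):
    """Raised on structurally invalid annotations."""


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[str, ...]
    corpus_name: str = ""
    sentence_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if len(self.tokens) < 1:
            raise CorpusError("a sentence needs at least one token")
        for tok in self.tokens:
            if _MARKER_RE.match(tok):
                raise CorpusError(f"token {tok!r} collides with a reserved marker string")

    @property
    def n(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class EntityMention:
    start: int   # inclusive token index
    end: int     # inclusive token index
    type_label: str
    mention_id: str = ""

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise CorpusError(
                f"mention {self.mention_id or '?'}: invalid span ({self.start},{self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RelationInstance:
    mention_a: str
    mention_b: str
    label: str

    def __post_init__(self):
        if self.mention_a == self.mention_b:
            raise CorpusError("a relation needs two distinct mentions")


@dataclass(frozen=True)
class TagSequence:
    tags: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "tags", tuple(self.tags))
        bad = [t for t in self.tags if t not in BIOES_TAGS]
        if bad:
            raise CorpusError(f"tags outside the BIOES alphabet: {bad}")

    def __len__(self):
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)


def _check_overlaps(mentions: list[EntityMention]) -> None:
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start <= prev.end:
            raise CorpusError(
                "overlapping or nested mentions: "
                f"{prev.mention_id or prev.span} and {cur.mention_id or cur.span}")


@dataclass
class Corpus:
    name: str
    sentences: list[Sentence] = field(default_factory=list)
    mentions: list[list[EntityMention]] = field(default_factory=list)
    relations: list[list[RelationInstance]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (len(self.sentences) == len(self.mentions) == len(self.relations)):
            raise CorpusError("sentences, mentions and relations must be parallel lists")
        for sent, ments, rels in zip(self.sentences, self.mentions, self.relations):
            ids = set()
            for m in ments:
                if m.end >= sent.n:
                    raise CorpusError(
                        f"mention {m.mention_id or m.span} exceeds sentence "
                        f"{sent.sentence_id or '?'} of length {sent.n}")
                if m.mention_id:
                    if m.mention_id in ids:
                        raise CorpusError(f"duplicate mention id {m.mention_id}")
                    ids.add(m.mention_id)
            _check_overlaps(ments)
            for r in rels:
                for mid in (r.mention_a, r.mention_b):
                    if mid not in ids:
                        raise CorpusError(
                            f"relation references unknown mention id {mid!r}")

    def __len__(self) -> int:
        return len(self.sentences)

    def annotated(self):
        """Iterate (sentence, mentions, relations) triples."""
        return zip(self.sentences, self.mentions, self.relations)

    def mention_by_id(self, sent_idx: int, mention_id: str) -> EntityMention:
        for m in self.mentions[sent_idx]:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)

    def entity_type_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for ments in self.mentions:
            for m in ments:
                seen.setdefault(m.type_label)
        return list(seen)

    def relation_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for rels in self.relations:
            for r in rels:
                seen.setdefault(r.label)
        return list(seen)


class LabelVocabulary:
    """Ordered, append-only registries of entity types and relation labels.

    Indices assigned to a label never change once it is registered; growing
    the vocabulary only appends, which is what lets classifier banks expand
    across corpora without disturbing trained heads.
    """

    def __init__(self, entity_types=(), relation_types=()):
        self._entity_types: list[str] = []
        self._relation_types: list[str] = []
        self.add_entity_types(entity_types)
        self.add_relation_types(relation_types)

    @property
    def entity_types(self) -> tuple[str, ...]:
        return tuple(self._entity_types)

    @property
    def relation_types(self) -> tuple[str, ...]:
        return tuple(self._relation_types)

    @property
    def n_entity_types(self) -> int:
        return len(self._entity_types)

    @property
    def n_relation_types(self) -> int:
        return len(self._relation_types)

    def entity_index(self, label: str) -> int:
        return self._entity_types.index(label)

    def relation_index(self, label: str) -> int:
        return self._relation_types.index(label)

    def add_entity_types(self, labels) -> list[str]:
        added = []
        for lab in labels:
            if lab not in self._entity_types:
                self._entity_types.append(lab)
                added.append(lab)
        return added

    def add_relation_types(self, labels) -> list[str]:
        added = []
        for lab in labels:
            if lab not in self._relation_types:
                self._relation_types.append(lab)
                added.append(lab)
        return added

    def copy(self) -> "LabelVocabulary":
        return LabelVocabulary(self._entity_types, self._relation_types)

    def __repr__(self):
        return (f"LabelVocabulary(entity_types={self._entity_types}, "
                f"relation_types={self._relation_types})")


def expand_vocabulary(vocab: LabelVocabulary, new_entity_types=(),
                      new_relation_types=()) -> LabelVocabulary:
    """Append genuinely new labels; known labels are ignored, indices stable."""
    vocab.add_entity_types(new_entity_types)
    vocab.add_relation_types(new_relation_types)
    return vocab


def bioes_encode(sentence: Sentence, mentions: list[EntityMention]) -> TagSequence:
    """Encode non-overlapping mention spans as one BIOES tag per token."""
    for m in mentions:
        if m.end >= sentence.n:
            raise CorpusError(f"mention {m.span} outside sentence of length {sentence.n}")
    _check_overlaps(list(mentions))
    tags = ["O"] * sentence.n
    for m in mentions:
        if m.start == m.end:
            tags[m.start] = "S"
        else:
            tags[m.start] = "B"
            tags[m.end] = "E"
            for i in range(m.start + 1, m.end):
                tags[i] = "I"
    return TagSequence(tuple(tags))


def bioes_decode(tags: TagSequence) -> list[tuple[int, int]]:
    """Recover spans from tags, conservatively.

    Only well-formed segments produce spans: a lone S, or a B followed by
    zero or more I then an E.  Malformed fragments (I/E with no open B, a B
    that never closes) are dropped rather than repaired, so decoding never
    fabricates entity boundaries that downstream relation extraction would
    then consume.
    """
    spans: list[tuple[int, int]] = []
    open_b: int | None = None
    for i, t in enumerate(tags):
        if t == "S":
            spans.append((i, i))
            open_b = None
        elif t == "B":
            open_b = i
        elif t == "E":
            if open_b is not None:
                spans.append((open_b, i))
            open_b = None
        elif t == "O":
            open_b = None
        # "I" keeps an open segment open; with no open B it stays malformed
    return spans


def normalize_labels(corpus: Corpus, type_map: dict[str, str],
                     relation_map: dict[str, str]) -> Corpus:
    """Rewrite mention types and relation labels through total maps.

    Mirrors the corpus harmonization step used when merging annotation
    efforts (e.g. folding a "Drug_n" subtype into "Drug", or collapsing
    fine-grained interaction subtypes into a single relation label).
    """
    for lab in {m.type_label for ments in corpus.mentions for m in ments}:
        if lab not in type_map:
            raise CorpusError(f"entity type {lab!r} missing from the type map")
    for lab in {r.label for rels in corpus.relations for r in rels}:
        if lab not in relation_map:
            raise CorpusError(f"relation label {lab!r} missing from the relation map")
    new_mentions = [[replace(m, type_label=type_map[m.type_label]) for m in ments]
                    for ments in corpus.mentions]
    new_relations = [[replace(r, label=relation_map[r.label]) for r in rels]
                     for rels in corpus.relations]
    return Corpus(name=corpus.name, sentences=list(corpus.sentences),
                  mentions=new_mentions, relations=new_relations)
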